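"""Stage-1 training: joint EKF estimation of reservoir state and weights.

The reservoir state x is augmented with the trainable parameters — the
input matrix W_in, the state-feedback matrix W_fb and a provisional linear
readout row W_out — and a single Extended Kalman Filter tracks the joint
posterior over one pass (or several) through the training data.  The
weights follow a random-walk model (constant under prediction, drifting
only through their process noise), while the state block advances through
the reservoir update

    x+ = F((W + W_in W_fb) x + W_in u) = F(W x + W_in (W_fb x + u))

using the weight estimates held in the mean.  The measurement model is the
bilinear provisional readout y = W_out x, whose Jacobian row covers both
the state and readout blocks.  The fixed reservoir matrix W is never
touched; after training, W_in and W_fb are written back into the model and
the provisional readout is discarded — the second stage refits the readout
from scratch on re-simulated states.

Augmented mean layout: [x (N) | vec(W_in) (N*m, row-major) |
vec(W_fb) (m*N, row-major) | W_out (N)].

The transition Jacobian is analytic.  With pre-activation
s = W x + W_in v, v = W_fb x + u and D = diag(f'(s)):

    d x+ / d x          = D (W + W_in W_fb)
    d x+ / d (W_in)_aj  = D e_a v_j           (nonzero only in row a)
    d x+ / d (W_fb)_jb  = D W_in[:, j] x_b
    d x+ / d W_out      = 0

Only the first N rows of the full Jacobian are non-trivial (the weight
rows are identity), so the covariance propagation is done blockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reservoir import ESNModel

__all__ = [
    "EKFConfig",
    "AugmentedEKFState",
    "TrainingTrace",
    "EKFDivergenceError",
    "ekf_init",
    "ekf_predict",
    "ekf_update",
    "africo_stage1",
]


class EKFDivergenceError(RuntimeError):
    """Filter mean left the finite/bounded regime."""

    def __init__(self, step: int, detail: str = ""):
        self.step = step
        super().__init__(f"EKF diverged at step {step}{': ' + detail if detail else ''}")


@dataclass(frozen=True)
class EKFConfig:
    """Noise and schedule settings for stage-1 adaptation.

    alpha      initial covariance scale (P0 = alpha I); order-one values
               give stable convergence without task-specific tuning.
    q_state    process-noise variance on the reservoir-state block.
    q_weights  random-walk drift variance on the weight blocks.
    r          measurement-noise variance; when None it is derived from the
               (standardized) training signal as 1/snr if an SNR is given,
               else 1e-2.
    epochs     passes over the training data (state block re-zeroed at the
               start of each pass, covariance and weights carried over).
    standardize  filter on the mean/variance-normalised target; the
               provisional readout absorbs the scale and is discarded
               anyway, while alpha, q and r keep a signal-free meaning.
    rho_max    stability projection: whenever the estimated closed-loop
               matrix W + W_in W_fb exceeds this spectral radius, the
               feedback block of the mean is shrunk back onto the stability
               boundary (filtered one-step tracking alone does not penalise
               free-run instability).
    """

    alpha: float = 1.0
    q_state: float = 1e-4
    q_weights: float = 1e-6
    r: float | None = None
    snr: float | None = None
    epochs: int = 1
    standardize: bool = True
    rho_max: float = 0.98
    project_every: int = 5
    divergence_limit: float = 1e6

    def resolve_r(self, z: np.ndarray) -> float:
        if self.r is not None:
            return float(self.r)
        if self.snr is not None and np.isfinite(self.snr):
            z = np.asarray(z, dtype=float)
            var = 1.0 if self.standardize else float(np.var(z))
            return var / self.snr
        return 1e-2


@dataclass
class AugmentedEKFState:
    """Joint filter state over [x | vec(W_in) | vec(W_fb) | W_out]."""

    mean: np.ndarray
    P: np.ndarray
    Q: np.ndarray  # diagonal of the process-noise covariance
    R: float
    N: int
    m: int

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    # block slices -----------------------------------------------------
    @property
    def sl_x(self) -> slice:
        return slice(0, self.N)

    @property
    def sl_win(self) -> slice:
        return slice(self.N, self.N + self.N * self.m)

    @property
    def sl_wfb(self) -> slice:
        return slice(self.N + self.N * self.m, self.N + 2 * self.N * self.m)

    @property
    def sl_wout(self) -> slice:
        return slice(self.N + 2 * self.N * self.m, self.dim)

    def unpack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Views of (x, W_in, W_fb, W_out) reshaped from the mean."""
        N, m = self.N, self.m
        x = self.mean[self.sl_x]
        W_in = self.mean[self.sl_win].reshape(N, m)
        W_fb = self.mean[self.sl_wfb].reshape(m, N)
        W_out = self.mean[self.sl_wout]
        return x, W_in, W_fb, W_out


@dataclass
class TrainingTrace:
    """Per-step diagnostics of the stage-1 run."""

    innovation: list[float] = field(default_factory=list)
    innovation_var: list[float] = field(default_factory=list)
    param_norm: list[float] = field(default_factory=list)

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {
            "innovation": np.array(self.innovation),
            "S": np.array(self.innovation_var),
            "param_norm": np.array(self.param_norm),
        }

    def to_csv(self, path) -> None:
        """Write the per-step diagnostics as step,innovation,S,param_norm."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "step": np.arange(len(self.innovation)),
                "innovation": self.innovation,
                "S": self.innovation_var,
                "param_norm": self.param_norm,
            }
        )
        df.to_csv(path, index=False)


def ekf_init(
    model: ESNModel,
    alpha: float = 1.0,
    q_state: float = 1e-4,
    q_weights: float = 1e-6,
    r: float = 1e-2,
    w_out0: np.ndarray | None = None,
) -> AugmentedEKFState:
    """Initialise the augmented filter from the model's current weights.

    The state block starts at zero (zero-initial-state convention), the
    weight blocks at the model's current W_in / W_fb, the provisional
    readout at zero unless given, and P = alpha I.
    """
    if model.feedback_mode != "state":
        raise ValueError("stage-1 adaptation requires a state-feedback model")
    if not alpha > 0 or not r > 0:
        raise ValueError("alpha and r must be positive")
    N, m = model.N, model.m
    dim = N + 2 * N * m + N
    mean = np.zeros(dim)
    mean[N : N + N * m] = model.W_in.ravel()
    mean[N + N * m : N + 2 * N * m] = model.W_fb.ravel()
    if w_out0 is not None:
        mean[N + 2 * N * m :] = np.asarray(w_out0, dtype=float).ravel()
    Q = np.full(dim, q_weights)
    Q[:N] = q_state
    P = np.eye(dim) * alpha
    return AugmentedEKFState(mean=mean, P=P, Q=Q, R=float(r), N=N, m=m)


def _transition_jacobian_rows(
    state: AugmentedEKFState, model: ESNModel, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """New state mean and the first N rows M of the transition Jacobian."""
    N, m = state.N, state.m
    x, W_in, W_fb, _ = state.unpack()
    v = W_fb @ x + u                      # (m,)
    s = model.W @ x + W_in @ v            # pre-activation
    x_new = model.f(s)
    if model.activation == "tanh":
        d = 1.0 - np.tanh(s) ** 2
    else:
        d = np.ones(N)
    M = np.zeros((N, state.dim))
    M[:, state.sl_x] = d[:, None] * (model.W + W_in @ W_fb)
    # d s_a / d (W_in)_{aj} = v_j  (row-major vec: column a*m + j)
    rows = np.arange(N)
    for j in range(m):
        M[rows, N + rows * m + j] = d * v[j]
    # d s_a / d (W_fb)_{jb} = W_in[a, j] * x_b  (column N + N*m + j*N + b)
    base = N + N * m
    for j in range(m):
        M[:, base + j * N : base + (j + 1) * N] = (d * W_in[:, j])[:, None] * x[None, :]
    return x_new, M


def ekf_predict(
    state: AugmentedEKFState,
    model: ESNModel,
    u: np.ndarray | float,
    inplace: bool = False,
) -> AugmentedEKFState:
    """Time update: advance the state block, hold weights, propagate P.

    P <- J P J' + Q with J the analytic augmented-transition Jacobian; the
    identity structure of the weight rows is exploited so only the first N
    rows are formed explicitly.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float)).ravel()
    if not np.all(np.isfinite(state.mean)):
        raise EKFDivergenceError(-1, "non-finite mean entering prediction")
    N, m, dim = state.N, state.m, state.dim
    x, W_in, W_fb, _ = state.unpack()
    v = W_fb @ x + u
    s = model.W @ x + W_in @ v
    x_new = model.f(s)
    d = (1.0 - np.tanh(s) ** 2) if model.activation == "tanh" else np.ones(N)
    A_eff = d[:, None] * (model.W + W_in @ W_fb)  # dF/dx rows

    # T1 = M @ P computed blockwise: the W_in/W_fb columns of the Jacobian
    # are structured, so the dense (N, dim) x (dim, dim) product reduces to
    # contractions of cost O(N m dim); only the first N rows/columns of P
    # change, so the update is done in place on a copy (or the caller's
    # array when inplace=True).
    P = state.P if inplace else state.P.copy()
    mean = state.mean if inplace else state.mean.copy()
    i0, i1, i2 = N, N + N * m, N + 2 * N * m
    T1 = A_eff @ P[:N]
    # rows a*m+j of the W_in block contracted with v over j (batched gemv)
    T1 += d[:, None] * np.matmul(v[None, None, :], P[i0:i1].reshape(N, m, dim))[:, 0, :]
    # rows j*N+b of the W_fb block contracted with x over b
    tmp = np.matmul(x[None, None, :], P[i1:i2].reshape(m, N, dim))[:, 0, :]  # (m, dim)
    T1 += d[:, None] * (W_in @ tmp)

    # top-left block T1 @ M.T with the same structure
    TL = T1[:, :N] @ A_eff.T
    TL += (T1[:, i0:i1].reshape(N, N, m) @ v) * d[None, :]
    TL += ((T1[:, i1:i2].reshape(N, m, N) @ x) @ W_in.T) * d[None, :]

    P[:N, N:] = T1[:, N:]
    P[N:, :N] = T1[:, N:].T
    P[:N, :N] = 0.5 * (TL + TL.T)
    P[np.diag_indices(dim)] += state.Q
    mean[:N] = x_new  # after the Jacobian contractions, which need the old x
    if inplace:
        return state
    return AugmentedEKFState(mean=mean, P=P, Q=state.Q, R=state.R, N=N, m=state.m)


def measurement_row(state: AugmentedEKFState) -> tuple[float, np.ndarray]:
    """Predicted output and Jacobian row of y = W_out x (bilinear)."""
    x, _, _, W_out = state.unpack()
    c = np.zeros(state.dim)
    c[state.sl_x] = W_out
    c[state.sl_wout] = x
    return float(W_out @ x), c


def ekf_update(
    state: AugmentedEKFState, z: float, inplace: bool = False
) -> AugmentedEKFState:
    """Scalar-innovation Kalman update.

    The measurement row c = [W_out | 0 | 0 | x] is sparse, so P c is formed
    from two thin slices of P.  P <- P - (P c)(P c)'/S, which equals the
    textbook (I - K c) P for symmetric P and is exactly symmetric in
    floating point.
    """
    x, _, _, W_out = state.unpack()
    y_hat = float(W_out @ x)
    P = state.P if inplace else state.P.copy()
    sl_w = state.sl_wout
    Pc = P[:, : state.N] @ W_out + P[:, sl_w] @ x
    S = float(W_out @ Pc[: state.N] + x @ Pc[sl_w]) + state.R
    if not S > 0:
        raise EKFDivergenceError(-1, f"non-positive innovation variance S={S}")
    e = float(z) - y_hat
    mean = state.mean if inplace else state.mean.copy()
    mean += Pc * (e / S)
    Pcs = Pc / np.sqrt(S)  # exact bitwise symmetry of the rank-1 downdate
    P -= np.outer(Pcs, Pcs)
    if inplace:
        new = state
    else:
        new = AugmentedEKFState(
            mean=mean, P=P, Q=state.Q, R=state.R, N=state.N, m=state.m
        )
    new._last_innovation = (e, S)  # type: ignore[attr-defined]
    return new


def _rho(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def _project_stable(state: AugmentedEKFState, W: np.ndarray, rho_max: float) -> None:
    """Shrink the feedback block of the mean so rho(W + W_in W_fb) <= rho_max.

    Filtered one-step-ahead tracking is forgiving of free-run instability,
    so without this constraint the estimate can drift into closed-loop
    matrices with spectral radius well above one.  The projection rescales
    W_fb toward zero (where the closed loop equals the stable open-loop
    reservoir) by bisection on the scaling factor.
    """
    if not rho_max:
        return
    _, W_in, W_fb, _ = state.unpack()
    G = W_in @ W_fb
    if _rho(W + G) <= rho_max:
        return
    lo, hi = 0.0, 1.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if _rho(W + mid * G) > rho_max:
            hi = mid
        else:
            lo = mid
    state.mean[state.sl_wfb] *= lo


def africo_stage1(
    model: ESNModel,
    U: np.ndarray,
    Z: np.ndarray,
    config: EKFConfig | None = None,
) -> tuple[ESNModel, TrainingTrace]:
    """Run the joint EKF over the training data and install W_in, W_fb.

    Each step first assimilates the measurement z(k) (which observes x(k))
    and then predicts x(k+1) from u(k).  The provisional readout estimated
    alongside the weights is discarded; stage 2 refits the readout.
    Returns the updated model (same reservoir W) and the training trace.
    """
    cfg = config or EKFConfig()
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    Z = np.asarray(Z, dtype=float).ravel()
    if U.shape[0] != Z.shape[0]:
        raise ValueError("input and target sequences must have equal length")
    if U.shape[1] != model.m:
        raise ValueError("input dimension does not match the model")
    if cfg.standardize:
        z_std = float(np.std(Z))
        if z_std > 0:
            Z = (Z - float(np.mean(Z))) / z_std
    r = cfg.resolve_r(Z)
    state = ekf_init(
        model, alpha=cfg.alpha, q_state=cfg.q_state, q_weights=cfg.q_weights, r=r
    )
    trace = TrainingTrace()
    T = U.shape[0]
    for epoch in range(cfg.epochs):
        if epoch > 0:
            state.mean[state.sl_x] = 0.0
        for k in range(T):
            state = ekf_update(state, Z[k], inplace=True)
            e, S = state._last_innovation  # type: ignore[attr-defined]
            state = ekf_predict(state, model, U[k], inplace=True)
            bad = np.max(np.abs(state.mean))
            if not np.isfinite(bad) or bad > cfg.divergence_limit:
                raise EKFDivergenceError(epoch * T + k, f"|mean| reached {bad:.3g}")
            if k % cfg.project_every == 0:
                _project_stable(state, model.W, cfg.rho_max)
            _, W_in, W_fb, _ = state.unpack()
            trace.innovation.append(e)
            trace.innovation_var.append(S)
            trace.param_norm.append(
                float(np.sqrt(np.sum(W_in**2) + np.sum(W_fb**2)))
            )
    # the last measurement update can leave the closed loop marginally
    # outside the constraint; enforce it for the returned model
    _project_stable(state, model.W, cfg.rho_max)
    _, W_in, W_fb, _ = state.unpack()
    trained = ESNModel(
        W=model.W.copy(),
        W_in=W_in.copy(),
        W_fb=W_fb.copy(),
        activation=model.activation,
        feedback_mode="state",
        readout=None,
    )
    return trained, trace
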
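"""Echo state network models: construction, simulation and linear analysis.

An ESN is a fixed random recurrent reservoir with a trained readout.  Two
feedback architectures are supported:

* ``state`` feedback — the reservoir input includes a learned linear
  transform of the full state, so the effective transition matrix becomes
  W + W_in @ W_fb (the closed-loop matrix);
* ``output`` feedback — the scalar readout output is fed back through a
  fixed column W_fb, the architecture trained by FORCE.

Reservoir matrices are initialised dense with entries uniform on [-1, 1]
and rescaled to a spectral radius below one (echo state property).  The
"uniform eigenspectrum" initialisation draws eigenvalues uniformly on the
complex unit disk (conjugate-closed), embeds them in a real block-diagonal
matrix, conjugates by a random orthogonal matrix, and rescales into the
requested spectral-radius range.

Simulation always starts from the all-zero state; with the convention used
throughout, X[k] is the state after consuming inputs U[0..k-1] (so X[0] is
the zero state) and Y[k] is the readout applied to X[k].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any

import numpy as np
import scipy.linalg

__all__ = [
    "ESNModel",
    "ReservoirInitSpec",
    "Trajectory",
    "random_weight_matrix",
    "set_spectral_radius",
    "spectral_radius",
    "make_reservoir",
    "esn_step",
    "esn_simulate",
    "delay_embed",
    "closed_loop_matrix",
    "linear_frf",
    "model_to_json",
    "model_from_json",
]

_ACTIVATIONS = ("identity", "tanh")
_FEEDBACK_MODES = ("state", "output", "none")


def spectral_radius(W: np.ndarray) -> float:
    """Largest eigenvalue magnitude."""
    return float(np.max(np.abs(np.linalg.eigvals(np.atleast_2d(W)))))


def random_weight_matrix(
    rows: int,
    cols: int,
    weight_range: tuple[float, float] = (-1.0, 1.0),
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Dense matrix with i.i.d. uniform entries; reproducible for a fixed seed."""
    if rows < 1 or cols < 1:
        raise ValueError("matrix dimensions must be positive")
    lo, hi = weight_range
    if not hi >= lo:
        raise ValueError("invalid weight range")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(rows, cols))


def set_spectral_radius(W: np.ndarray, rho_target: float) -> np.ndarray:
    """Rescale ``W`` so its spectral radius equals ``rho_target``.

    Fails on (numerically) nilpotent matrices, whose spectral radius cannot
    be changed by scaling.
    """
    if not rho_target > 0:
        raise ValueError("rho_target must be positive")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    rho = spectral_radius(W)
    if rho < 1e-12:
        raise ValueError("matrix has (numerically) zero spectral radius; cannot rescale")
    return W * (rho_target / rho)


@dataclass(frozen=True)
class ReservoirInitSpec:
    """Reservoir construction settings.

    ``spectral_radius_range`` must sit inside (0, 1) so the echo state
    property holds; the realised radius is drawn uniformly from the range.
    """

    N: int
    spectral_radius_range: tuple[float, float] = (0.8, 0.9)
    eigenspectrum: str = "unconstrained"
    weight_range: tuple[float, float] = (-1.0, 1.0)
    seed: int | None = None

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be positive")
        lo, hi = self.spectral_radius_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("spectral_radius_range must lie inside (0, 1)")
        if self.eigenspectrum not in ("unconstrained", "uniform"):
            raise ValueError("eigenspectrum must be 'unconstrained' or 'uniform'")


def _uniform_spectrum_matrix(N: int, rng: np.random.Generator) -> np.ndarray:
    """Real matrix whose eigenvalues are ~uniform on the complex unit disk.

    Eigenvalues are drawn in conjugate pairs (plus real ones for odd counts),
    assembled into 2x2 rotation-scaling blocks, and conjugated by a random
    orthogonal matrix to produce a dense, asymmetric reservoir.
    """
    blocks = []
    remaining = N
    while remaining > 0:
        if remaining == 1:
            lam = rng.uniform(-1.0, 1.0)
            blocks.append(np.array([[lam]]))
            remaining -= 1
        else:
            # uniform on the disk: radius sqrt(U), angle in (0, pi)
            r = np.sqrt(rng.uniform())
            theta = rng.uniform(0.0, np.pi)
            a, b = r * np.cos(theta), r * np.sin(theta)
            blocks.append(np.array([[a, b], [-b, a]]))
            remaining -= 2
    D = scipy.linalg.block_diag(*blocks)
    Q = scipy.linalg.qr(rng.standard_normal((N, N)))[0]
    return Q @ D @ Q.T


def make_reservoir(spec: ReservoirInitSpec) -> np.ndarray:
    """Build an N x N reservoir matrix with spectral radius in the requested range."""
    rng = np.random.default_rng(spec.seed)
    rho_target = rng.uniform(*spec.spectral_radius_range)
    if spec.eigenspectrum == "uniform":
        W = _uniform_spectrum_matrix(spec.N, rng)
    else:
        W = rng.uniform(*spec.weight_range, size=(spec.N, spec.N))
    if spec.N == 1 and abs(W[0, 0]) < 1e-12:
        W = np.array([[1.0]])  # degenerate scalar draw; rescaled below
    return set_spectral_radius(W, rho_target)


@dataclass
class Trajectory:
    """Input/state/output record of one simulation run."""

    U: np.ndarray
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        if not (len(self.U) == len(self.X) == len(self.Y)):
            raise ValueError("U, X, Y must have equal lengths")


@dataclass
class ESNModel:
    """Echo state network with optional state or output feedback.

    Shapes: W is (N, N); W_in is (N, m); W_fb is (m, N) in state-feedback
    mode (so W_in @ W_fb is N x N) or (N, 1) in output-feedback mode.  The
    readout is either a linear row vector (1, N) or a sparse polynomial
    readout object exposing ``predict(X)``.
    """

    W: np.ndarray
    W_in: np.ndarray
    W_fb: np.ndarray | None = None
    activation: str = "tanh"
    feedback_mode: str = "state"
    readout: Any = None

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.W_in = np.atleast_2d(np.asarray(self.W_in, dtype=float))
        N = self.W.shape[0]
        if self.W.shape != (N, N):
            raise ValueError("W must be square")
        if self.W_in.shape[0] != N:
            raise ValueError("W_in must have N rows")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.feedback_mode not in _FEEDBACK_MODES:
            raise ValueError(f"feedback_mode must be one of {_FEEDBACK_MODES}")
        rho = spectral_radius(self.W)
        if rho >= 1.0:
            raise ValueError(f"echo state property violated: rho(W) = {rho:.4f} >= 1")
        if self.W_fb is not None:
            self.W_fb = np.atleast_2d(np.asarray(self.W_fb, dtype=float))
            if self.feedback_mode == "state" and self.W_fb.shape != (self.m, N):
                raise ValueError("state-feedback W_fb must be (m, N)")
            if self.feedback_mode == "output" and self.W_fb.shape != (N, 1):
                raise ValueError("output-feedback W_fb must be (N, 1)")
        elif self.feedback_mode != "none":
            raise ValueError("W_fb required unless feedback_mode='none'")

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W_in.shape[1]

    def f(self, s: np.ndarray) -> np.ndarray:
        return np.tanh(s) if self.activation == "tanh" else s

    def readout_eval(self, X: np.ndarray) -> np.ndarray:
        """Apply the installed readout to a (T, N) state sequence."""
        if self.readout is None:
            raise ValueError("model has no readout installed")
        X = np.atleast_2d(X)
        if hasattr(self.readout, "predict"):
            return self.readout.predict(X)
        w = np.asarray(self.readout, dtype=float).reshape(-1)
        return X @ w


def esn_step(
    model: ESNModel,
    x: np.ndarray,
    u: np.ndarray | float,
    y: float | None = None,
) -> np.ndarray:
    """One reservoir update.

    State feedback:  x+ = F((W + W_in W_fb) x + W_in u).
    Output feedback: x+ = F(W x + W_in u - W_fb y), y supplied by the caller
    (teacher-forced target during training, own readout when free-running).
    """
    x = np.asarray(x, dtype=float).ravel()
    u = np.atleast_1d(np.asarray(u, dtype=float)).ravel()
    if x.shape[0] != model.N or u.shape[0] != model.m:
        raise ValueError("state/input shape mismatch")
    s = model.W @ x + model.W_in @ u
    if model.feedback_mode == "state":
        s = s + model.W_in @ (model.W_fb @ x)
    elif model.feedback_mode == "output":
        if y is None:
            raise ValueError("output-feedback step requires the current output y")
        s = s - model.W_fb[:, 0] * y
    return model.f(s)


def esn_simulate(
    model: ESNModel,
    U: np.ndarray,
    teacher: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Iterate the reservoir over an input sequence from the zero state.

    ``teacher`` supplies the fed-back output signal for output-feedback
    models (teacher forcing); without it, the model's own readout output is
    fed back (free run).  ``x0`` overrides the zero initial state, e.g. to
    continue a validation run from the end of training.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    T = U.shape[0]
    if T == 0:
        raise ValueError("input sequence must be non-empty")
    N = model.N
    X = np.zeros((T, N))
    x = np.zeros(N) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()
    need_y = model.feedback_mode == "output"
    linear_readout = model.readout is not None and not hasattr(model.readout, "predict")
    w_lin = (
        np.asarray(model.readout, dtype=float).reshape(-1) if linear_readout else None
    )
    Y = np.zeros(T)
    for k in range(T):
        X[k] = x
        if need_y:
            if teacher is not None:
                y_k = float(teacher[k])
            elif w_lin is not None:
                y_k = float(w_lin @ x)
            elif model.readout is not None:
                y_k = float(model.readout.predict(x[None, :])[0])
            else:
                y_k = 0.0
            x = esn_step(model, x, U[k], y=y_k)
        else:
            x = esn_step(model, x, U[k])
    if model.readout is not None:
        Y = np.asarray(model.readout_eval(X), dtype=float).ravel()
    return Trajectory(U=U, X=X, Y=Y)


def delay_embed(u: np.ndarray, l: int) -> np.ndarray:
    """Delay-embed a scalar sequence into rows [u(k), u(k-1), ..., u(k-l)].

    Pre-history is zero-padded, consistent with the zero-initial-state
    convention; ``l=0`` returns the sequence as a single-column array.
    """
    if l < 0:
        raise ValueError("maximum lag must be non-negative")
    u = np.asarray(u, dtype=float).ravel()
    T = len(u)
    out = np.zeros((T, l + 1))
    for j in range(l + 1):
        out[j:, j] = u[: T - j]
    return out


def closed_loop_matrix(model: ESNModel) -> np.ndarray:
    """Effective transition matrix W + W_in @ W_fb of a state-feedback ESN."""
    if model.feedback_mode != "state":
        raise ValueError("closed-loop matrix is defined for state-feedback models")
    return model.W + model.W_in @ model.W_fb


def linear_frf(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    omegas: np.ndarray,
) -> np.ndarray:
    """Frequency response C (e^{i w} I - A)^{-1} B of a discrete linear system.

    Returns one complex response per frequency (radians/sample).  ``A`` must
    be stable (spectral radius < 1) so the resolvent exists on the unit
    circle.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[0]
    B = np.asarray(B, dtype=float).reshape(n, -1)
    C = np.asarray(C, dtype=float).reshape(-1, n)
    if spectral_radius(A) >= 1.0:
        raise ValueError("A must be stable (spectral radius < 1)")
    I = np.eye(n)
    out = np.empty(len(omegas), dtype=complex)
    for i, w in enumerate(np.asarray(omegas, dtype=float)):
        H = C @ np.linalg.solve(np.exp(1j * w) * I - A, B)
        out[i] = H[0, 0]
    return out


# --------------------------------------------------------------------------
# serialization

def model_to_json(model: ESNModel) -> str:
    """Serialize a model (matrices row-major, readout term list if sparse)."""
    doc: dict[str, Any] = {
        "N": model.N,
        "m": model.m,
        "activation": model.activation,
        "feedback_mode": model.feedback_mode,
        "W": model.W.ravel().tolist(),
        "W_in": model.W_in.ravel().tolist(),
        "W_fb": None if model.W_fb is None else model.W_fb.ravel().tolist(),
        "W_fb_shape": None if model.W_fb is None else list(model.W_fb.shape),
    }
    if model.readout is None:
        doc["readout"] = None
    elif hasattr(model.readout, "to_dict"):
        doc["readout"] = {"kind": "sparse", **model.readout.to_dict()}
    else:
        doc["readout"] = {
            "kind": "linear",
            "weights": np.asarray(model.readout, dtype=float).ravel().tolist(),
        }
    return json.dumps(doc)


def model_from_json(text: str) -> ESNModel:
    from .readout import SparseReadout

    doc = json.loads(text)
    N, m = doc["N"], doc["m"]
    W = np.array(doc["W"], dtype=float).reshape(N, N)
    W_in = np.array(doc["W_in"], dtype=float).reshape(N, m)
    W_fb = None
    if doc["W_fb"] is not None:
        W_fb = np.array(doc["W_fb"], dtype=float).reshape(doc["W_fb_shape"])
    readout = None
    if doc["readout"] is not None:
        if doc["readout"]["kind"] == "sparse":
            readout = SparseReadout.from_dict(doc["readout"])
        else:
            readout = np.array(doc["readout"]["weights"], dtype=float).reshape(1, -1)
    return ESNModel(
        W=W,
        W_in=W_in,
        W_fb=W_fb,
        activation=doc["activation"],
        feedback_mode=doc["feedback_mode"],
        readout=readout,
    )
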
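"""FORCE baseline: recursive least squares on the readout of an
output-feedback ESN.

The reservoir and the output-feedback column are fixed; only the linear
readout row is trained, updated at every step by RLS (forgetting factor 1)
while the true target is teacher-forced through the feedback path.  At
evaluation time the loop is closed on the model's own prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reservoir import ESNModel, esn_step

__all__ = ["RLSState", "RLSConfig", "rls_step", "force_train"]


@dataclass(frozen=True)
class RLSConfig:
    """``lam`` sets the inverse-correlation prior P0 = I / lam."""

    lam: float = 1.0


@dataclass
class RLSState:
    """Running RLS estimate: inverse correlation matrix and readout row."""

    P: np.ndarray
    w: np.ndarray

    @classmethod
    def init(cls, N: int, lam: float = 1.0) -> "RLSState":
        if not lam > 0:
            raise ValueError("lam must be positive")
        return cls(P=np.eye(N) / lam, w=np.zeros(N))


def rls_step(state: RLSState, phi: np.ndarray, target: float) -> RLSState:
    """One recursive least-squares update (forgetting factor 1).

    k = P phi / (1 + phi' P phi);  w += e k with e the prior error;
    P <- P - k (phi' P), symmetrized.
    """
    phi = np.asarray(phi, dtype=float).ravel()
    if not (np.all(np.isfinite(phi)) and np.isfinite(target)):
        raise FloatingPointError("non-finite RLS input (divergence)")
    Pphi = state.P @ phi
    denom = 1.0 + float(phi @ Pphi)
    k = Pphi / denom
    e = float(target) - float(state.w @ phi)
    w = state.w + e * k
    P = state.P - np.outer(k, Pphi)
    P = 0.5 * (P + P.T)
    return RLSState(P=P, w=w)


def force_train(
    model: ESNModel,
    U: np.ndarray,
    Z: np.ndarray,
    config: RLSConfig | None = None,
) -> tuple[ESNModel, np.ndarray]:
    """Train the readout of an output-feedback ESN with FORCE.

    Simulates the reservoir with the target ``Z`` teacher-forced through the
    feedback path, applying an RLS update on the readout at every step.
    Returns the model with the final readout installed and the per-step
    training error (prior innovation).  The final reservoir state is stored
    on the model as ``_x_final`` so evaluation can continue free-running
    from the end of training.
    """
    if model.feedback_mode != "output":
        raise ValueError("FORCE training requires an output-feedback model")
    cfg = config or RLSConfig()
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    Z = np.asarray(Z, dtype=float).ravel()
    if U.shape[0] != Z.shape[0]:
        raise ValueError("input and target sequences must have equal length")
    N = model.N
    rls = RLSState.init(N, cfg.lam)
    x = np.zeros(N)
    errors = np.empty(len(Z))
    for k in range(len(Z)):
        errors[k] = Z[k] - float(rls.w @ x)
        rls = rls_step(rls, x, Z[k])
        x = esn_step(model, x, U[k], y=Z[k])
    trained = ESNModel(
        W=model.W.copy(),
        W_in=model.W_in.copy(),
        W_fb=model.W_fb.copy(),
        activation=model.activation,
        feedback_mode="output",
        readout=rls.w.reshape(1, N),
    )
    trained._x_final = x  # type: ignore[attr-defined]
    return trained, errors
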
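"""Benchmark target systems and evaluation metrics.

Three families of synthetic targets are provided, each a discrete-time
input/output system driven by an i.i.d. input sequence:

* random stable linear state-space systems,
* a linear-dynamic system with a fixed sum-of-squares output nonlinearity
  (a linear--nonlinear cascade with a 40-dimensional internal state),
* the NARMA10 recursion, a tenth-order nonlinear benchmark with long
  temporal dependencies.

Measurement noise is injected at a prescribed linear signal-to-noise ratio
(variance ratio, not dB), and prediction quality is scored with the
normalised mean squared error (NMSE), for which predicting the reference
mean scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearTarget",
    "NARMA10Config",
    "NarmaDivergenceError",
    "random_stable_linear",
    "simulate_linear_target",
    "lnl_output",
    "narma10",
    "narma10_generate",
    "add_noise_snr",
    "nmse",
]


class NarmaDivergenceError(RuntimeError):
    """NARMA10 trajectory left the stable regime."""

    def __init__(self, step: int, value: float):
        self.step = step
        self.value = value
        super().__init__(f"NARMA10 diverged at step {step} (|y| = {value:.3g})")


@dataclass(frozen=True)
class LinearTarget:
    """Stable linear state-space target x+ = A x + B u, z = C x (+ noise)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    noise_var: float = 1.0

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValueError("A must be square")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float).reshape(n, 1))
        object.__setattr__(self, "C", np.asarray(self.C, dtype=float).reshape(1, n))

    @property
    def dim(self) -> int:
        return self.A.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))


@dataclass(frozen=True)
class NARMA10Config:
    """NARMA10 generation settings.

    ``input_range`` defaults to [0, 0.5], the standard benchmark convention:
    with inputs drawn from [0, 1] the recursion has no bounded mean and every
    realization diverges, so the wider range is only useful for exploratory
    runs with ``saturate=True``.
    """

    length: int = 4500
    input_range: tuple[float, float] = (0.0, 0.5)
    seed: int | None = None
    saturate: bool = False

    def __post_init__(self):
        if self.length <= 10:
            raise ValueError("length must exceed the model order (10)")


def random_stable_linear(
    N: int,
    rho_max: float,
    seed: int | np.random.Generator | None = None,
    weight_range: tuple[float, float] = (-1.0, 1.0),
) -> LinearTarget:
    """Draw a random linear target with spectral radius below ``rho_max``.

    Entries of A, B, C are uniform on ``weight_range``; A is then rescaled so
    its spectral radius is uniform on (0, rho_max), giving a family of
    systems that all satisfy the stated stability bound.
    """
    if not 0.0 < rho_max < 1.0:
        raise ValueError("rho_max must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = weight_range
    A = rng.uniform(lo, hi, size=(N, N))
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho == 0.0:  # pragma: no cover - measure-zero draw
        A = np.zeros((N, N))
    else:
        target_rho = rng.uniform(0.0, rho_max)
        A = A * (target_rho / rho)
    B = rng.uniform(lo, hi, size=(N, 1))
    C = rng.uniform(lo, hi, size=(1, N))
    return LinearTarget(A=A, B=B, C=C)


def simulate_linear_target(
    sys: LinearTarget,
    U: np.ndarray,
    snr: float | None = None,
    noise_seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the linear target from the zero state.

    Returns ``(z_clean, z_noisy)`` with z[k] = C x(k) and x(k) the state
    after consuming U[0..k-1].  When ``snr`` is None the noisy sequence
    equals the clean one.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim == 2:
        U = U[:, 0]
    T = len(U)
    if T == 0:
        raise ValueError("input sequence must be non-empty")
    n = sys.dim
    X = np.zeros((T, n))
    x = np.zeros(n)
    A, b = sys.A, sys.B[:, 0]
    for k in range(T):
        X[k] = x
        x = A @ x + b * U[k]
    z_clean = X @ sys.C[0]
    if snr is None:
        return z_clean, z_clean.copy()
    z_noisy = add_noise_snr(z_clean, snr, seed=noise_seed)
    return z_clean, z_noisy


def lnl_output(X: np.ndarray) -> np.ndarray:
    """Sum-of-squares output nonlinearity over a >=40-dimensional state.

    y(k) = sum_{i=1}^{39} [ 0.5 (x_{i+1} - x_i^2)^2 + (0.5 - x_i)^2 ],
    evaluated on the first 40 state components at every time step.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 40:
        raise ValueError("state dimension must be at least 40")
    x = X[:, :40]
    xi, xip1 = x[:, :39], x[:, 1:40]
    return np.sum(0.5 * (xip1 - xi**2) ** 2 + (0.5 - xi) ** 2, axis=1)


def narma10(
    U: np.ndarray,
    config: NARMA10Config | None = None,
    saturate: bool | None = None,
    divergence_limit: float = 1e3,
) -> np.ndarray:
    """Iterate the NARMA10 recursion over an input sequence.

    y(k+1) = 0.3 y(k) + 0.05 y(k) sum_{i=0}^{9} y(k-i)
             + 1.5 u(k) u(k-9) + 0.1

    with y(k<=0) = 0 and u(k<0) = 0.  Output y has the same length as U and
    y[0] = 0.  Raises :class:`NarmaDivergenceError` when |y| exceeds
    ``divergence_limit`` unless ``saturate`` applies tanh to each new output
    (an exploratory fix, never used for benchmark scoring).
    """
    U = np.asarray(U, dtype=float).ravel()
    T = len(U)
    if saturate is None:
        saturate = bool(config.saturate) if config is not None else False
    y = np.zeros(T)
    for k in range(T - 1):
        window = y[max(0, k - 9) : k + 1]
        u_lag = U[k - 9] if k - 9 >= 0 else 0.0
        val = 0.3 * y[k] + 0.05 * y[k] * window.sum() + 1.5 * U[k] * u_lag + 0.1
        if saturate:
            val = np.tanh(val)
        elif abs(val) > divergence_limit:
            raise NarmaDivergenceError(k + 1, abs(val))
        y[k + 1] = val
    return y


def narma10_generate(
    config: NARMA10Config,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the i.i.d. input sequence and run the recursion; returns (U, y)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.input_range
    U = rng.uniform(lo, hi, size=config.length)
    return U, narma10(U, config)


def add_noise_snr(
    z: np.ndarray,
    snr: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Add zero-mean Gaussian noise at a linear power SNR (var(z)/var(noise)).

    ``snr=np.inf`` returns a copy of the input.
    """
    z = np.asarray(z, dtype=float)
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return z.copy()
    var = float(np.var(z))
    if var == 0.0:
        raise ValueError("signal is constant; SNR is undefined")
    rng = np.random.default_rng(seed)
    return z + rng.normal(0.0, np.sqrt(var / snr), size=z.shape)


def nmse(pred: np.ndarray, ref: np.ndarray) -> float:
    """Normalised mean squared error: sum (pred-ref)^2 / sum (ref-mean)^2."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have the same length")
    denom = float(np.sum((ref - ref.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("reference signal is constant; NMSE is undefined")
    return float(np.sum((pred - ref) ** 2) / denom)
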
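"""Time-series CSV conventions shared by the library and the CLI.

Files carry a header ``t,u_1,...,u_m,z`` with one row per time step; ``z``
is the (possibly noisy) target output aligned with the state convention
used everywhere else (z[k] observes the state reached after inputs
U[0..k-1]).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_timeseries_csv", "read_timeseries_csv"]


def write_timeseries_csv(
    path: str | Path, U: np.ndarray, z: np.ndarray
) -> None:
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    z = np.asarray(z, dtype=float).ravel()
    if U.shape[0] != len(z):
        raise ValueError("input and output lengths differ")
    data = {"t": np.arange(len(z))}
    for j in range(U.shape[1]):
        data[f"u_{j + 1}"] = U[:, j]
    data["z"] = z
    pd.DataFrame(data).to_csv(path, index=False)


def read_timeseries_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (U, z) with U of shape (T, m)."""
    df = pd.read_csv(path)
    u_cols = sorted(
        (c for c in df.columns if c.startswith("u_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not u_cols or "z" not in df.columns:
        raise ValueError(f"{path}: expected columns t,u_1..u_m,z")
    return df[u_cols].to_numpy(dtype=float), df["z"].to_numpy(dtype=float)
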
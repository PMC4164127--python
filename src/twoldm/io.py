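"""One-column CSV reading/writing for likelihood and generic series."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coding import LikelihoodSeries

__all__ = ["read_series", "read_likelihood", "write_series"]


def read_series(path) -> np.ndarray:
    """Read a one-column series CSV (no header, or header 'value')."""
    path = Path(path)
    first = path.open().readline().strip().lower()
    header = 0 if first in {"value", '"value"'} else None
    df = pd.read_csv(path, header=header)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected a single column, found {df.shape[1]}")
    return df.iloc[:, 0].to_numpy(dtype=float)


def read_likelihood(path, dt: float = 0.05) -> LikelihoodSeries:
    return LikelihoodSeries(values=read_series(path), dt=dt)


def write_series(path, values, header: str = "value") -> None:
    pd.DataFrame({header: np.asarray(values)}).to_csv(path, index=False)
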
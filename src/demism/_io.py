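"""CSV helpers for labeled square matrices."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_matrix", "write_matrix"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled square numeric matrix (labels in first row/column)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, expected square")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row labels differ from column labels")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, decimals: int = 6) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=f"%.{decimals}f")
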
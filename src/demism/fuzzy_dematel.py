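"""Fuzzy DEMATEL: CFCS defuzzification, normalization, total relation, scores.

The panel of linguistic judgments is collapsed to a crisp direct-influence
matrix ``D`` by the CFCS method ("converting fuzzy data into crisp scores"):
per cell, each expert's TFN is standardized against the cell's support
``[min_k l, max_k r]``, left/right membership scores are formed, collapsed
to a single normalized score, rescaled into the original support, and
averaged over experts.

``D`` is normalized by the larger of its maximum row and column sum, and the
total relation matrix ``T = N (I - N)^{-1}`` accumulates all direct and
indirect influence paths.  Row sums ``D_i`` (influence dispatched) and
column sums ``R_i`` (influence received) of ``T`` give each factor's
centrality ``D_i + R_i`` and causality ``D_i - R_i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import ExpertPanel, TriangularFuzzyNumber

__all__ = [
    "InfluenceMatrices",
    "DematelScores",
    "cfcs_cell",
    "defuzzify_panel",
    "normalize",
    "total_relation",
    "prominence_causality",
]

#: condition-number guard for the (I - N) solve
_COND_LIMIT = 1e12


def _cfcs(L: np.ndarray, M: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Vectorized CFCS over the expert axis (axis 0).

    L, M, R have shape (k, ...); returns crisp values of shape (...).
    Cells whose support degenerates to a point (all experts give the same
    l = m = r) take that common value, the continuous limit of the method.
    """
    lmin = L.min(axis=0)
    rmax = R.max(axis=0)
    delta = rmax - lmin
    safe = np.where(delta == 0.0, 1.0, delta)
    xl = (L - lmin) / safe
    xm = (M - lmin) / safe
    xr = (R - lmin) / safe
    xls = xm / (1.0 + xm - xl)
    xrs = xr / (1.0 + xr - xm)
    x = (xls * (1.0 - xls) + xrs * xrs) / (1.0 - xls + xrs)
    z = lmin + x * delta
    z = np.where(delta == 0.0, L, z)
    return z.mean(axis=0)


def cfcs_cell(ratings: Sequence[TriangularFuzzyNumber]) -> float:
    """Defuzzify one cell's ratings (one TFN per expert) to a crisp value.

    The crisp value always lies within the cell's support
    ``[min_k l, max_k r]``.
    """
    if len(ratings) == 0:
        raise ValueError("cfcs_cell requires at least one rating")
    arr = np.array([t.as_tuple() for t in ratings], dtype=float)
    L, M, R = (a[:, None] for a in arr.T)
    return float(_cfcs(L, M, R)[0])


def defuzzify_panel(panel: ExpertPanel, zero_diagonal: bool = False) -> pd.DataFrame:
    """CFCS-defuzzify an expert panel into the crisp direct matrix ``D``.

    With ``zero_diagonal`` the diagonal is forced to exactly 0 instead of
    the small crisp value of the lowest term.
    """
    L, M, R = panel.tfn_arrays()
    D = _cfcs(L, M, R)
    if zero_diagonal:
        np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=panel.factors, columns=panel.factors)


def _as_array(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(c) for c in matrix.columns]
    arr = np.asarray(matrix, dtype=float)
    return arr, [f"x{i + 1}" for i in range(arr.shape[0])]


def normalize(D) -> pd.DataFrame:
    """Normalize ``D`` by s = max(max row sum, max column sum).

    After normalization the larger of the maximum row and column sum
    equals 1 exactly.
    """
    arr, labels = _as_array(D)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("direct matrix must be square")
    if (arr < 0).any():
        raise ValueError("direct matrix entries must be non-negative")
    s = max(arr.sum(axis=1).max(), arr.sum(axis=0).max())
    if s <= 0:
        raise ValueError("direct matrix is all-zero; cannot normalize")
    return pd.DataFrame(arr / s, index=labels, columns=labels)


def total_relation(N) -> pd.DataFrame:
    """Total relation matrix ``T = N (I - N)^{-1}`` by linear solve.

    Equivalent to the convergent series N + N^2 + ...; requires the
    spectral radius of N to be below 1, which holds for any normalized
    matrix whose row/column sums are not all tied at the maximum.
    """
    arr, labels = _as_array(N)
    n = arr.shape[0]
    eye = np.eye(n)
    A = eye - arr
    if np.linalg.cond(A) > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            "(I - N) is numerically singular; the normalized matrix does "
            "not converge — inspect the direct-influence input"
        )
    # T (I - N) = N  =>  solve on the right via transposes
    T = np.linalg.solve(A.T, arr.T).T
    return pd.DataFrame(T, index=labels, columns=labels)


@dataclass(frozen=True)
class InfluenceMatrices:
    """Crisp direct matrix D, normalized N and total relation T."""

    direct: pd.DataFrame
    normalized: pd.DataFrame
    total: pd.DataFrame

    @classmethod
    def from_direct(cls, D) -> "InfluenceMatrices":
        arr, labels = _as_array(D)
        Df = pd.DataFrame(arr, index=labels, columns=labels)
        N = normalize(Df)
        return cls(direct=Df, normalized=N, total=total_relation(N))

    @classmethod
    def from_panel(cls, panel: ExpertPanel, zero_diagonal: bool = False) -> "InfluenceMatrices":
        return cls.from_direct(defuzzify_panel(panel, zero_diagonal=zero_diagonal))

    @property
    def factors(self) -> list[str]:
        return [str(c) for c in self.total.columns]


@dataclass(frozen=True)
class DematelScores:
    """Per-factor influence (D), influenced (R), centrality and causality.

    ``table`` has one row per factor with columns D, R, ``D+R``, ``D-R``
    and dense ranks (1 = largest) for centrality and causality.
    """

    table: pd.DataFrame

    @property
    def influence(self) -> pd.Series:  # D_i
        return self.table["D"]

    @property
    def influenced(self) -> pd.Series:  # R_i
        return self.table["R"]

    @property
    def centrality(self) -> pd.Series:
        return self.table["D+R"]

    @property
    def causality(self) -> pd.Series:
        return self.table["D-R"]


def prominence_causality(T) -> DematelScores:
    """Row/column sums of the total relation matrix and derived scores."""
    arr, labels = _as_array(T)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("total relation matrix must be square")
    D = arr.sum(axis=1)
    R = arr.sum(axis=0)
    table = pd.DataFrame(
        {
            "D": D,
            "R": R,
            "D+R": D + R,
            "D-R": D - R,
        },
        index=labels,
    )
    table["centrality_rank"] = table["D+R"].rank(ascending=False, method="min").astype(int)
    table["causality_rank"] = table["D-R"].rank(ascending=False, method="min").astype(int)
    return DematelScores(table=table)
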
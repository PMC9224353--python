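"""Linguistic scale and expert-panel data model.

Group decision input for the influence analysis is a panel of ``k`` experts,
each rating the direct influence of factor ``i`` on factor ``j`` on a
five-term linguistic scale (No < VL < L < H < VH).  Every term maps to a
triangular fuzzy number (l, m, r) on [0, 1] encoding a conservative, median
and optimistic reading of the judgment.  Diagonal cells are recorded as
"No": a factor is not scored against itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TriangularFuzzyNumber",
    "LinguisticScale",
    "DEFAULT_SCALE",
    "ExpertPanel",
    "PanelValidationError",
    "term_to_tfn",
    "read_panel",
    "read_manifest",
    "write_panel",
]


class PanelValidationError(ValueError):
    """Raised when survey input violates the panel contract."""


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Triple (l, m, r) with l <= m <= r, all on [0, 1].

    ``l`` is the conservative value, ``m`` the median (most plausible)
    value and ``r`` the optimistic value of a vague judgment.
    """

    l: float
    m: float
    r: float

    def __post_init__(self) -> None:
        if not (self.l <= self.m <= self.r):
            raise ValueError(
                f"triangular fuzzy number requires l <= m <= r, got "
                f"({self.l}, {self.m}, {self.r})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.r)


@dataclass(frozen=True)
class LinguisticScale:
    """Ordered five-term scale with a TFN for each term.

    Terms are matched case-insensitively on their abbreviation.  The scale
    must be component-wise monotone: each of l, m, r is non-decreasing
    along the term order, so a "higher" term never encodes less influence.
    """

    terms: tuple[str, ...]
    tfns: Mapping[str, TriangularFuzzyNumber]

    def __post_init__(self) -> None:
        if len(self.terms) != len(set(t.lower() for t in self.terms)):
            raise ValueError("scale terms must be unique (case-insensitive)")
        missing = [t for t in self.terms if t not in self.tfns]
        if missing:
            raise ValueError(f"scale terms without a TFN: {missing}")
        prev = self.tfns[self.terms[0]]
        for term in self.terms[1:]:
            cur = self.tfns[term]
            if not (prev.l <= cur.l and prev.m <= cur.m and prev.r <= cur.r):
                raise ValueError(
                    f"scale is not component-wise monotone at term {term!r}"
                )
            prev = cur
        for term in self.terms:
            tfn = self.tfns[term]
            if not (0.0 <= tfn.l and tfn.r <= 1.0):
                raise ValueError(f"TFN for {term!r} must lie in [0, 1]")

    @property
    def lowest(self) -> str:
        return self.terms[0]

    def canonical(self, term: str) -> str:
        """Return the canonical spelling of ``term`` (case-insensitive)."""
        key = str(term).strip().lower()
        for t in self.terms:
            if t.lower() == key:
                return t
        raise PanelValidationError(
            f"unknown linguistic term {term!r}; expected one of {list(self.terms)}"
        )

    def tfn(self, term: str) -> TriangularFuzzyNumber:
        return self.tfns[self.canonical(term)]

    def index(self, term: str) -> int:
        return self.terms.index(self.canonical(term))


#: Five-term scale used throughout: no / very low / low / high / very high
#: influence, with TFN supports spanning [0, 1] in steps of 0.25.
DEFAULT_SCALE = LinguisticScale(
    terms=("No", "VL", "L", "H", "VH"),
    tfns={
        "No": TriangularFuzzyNumber(0.0, 0.0, 0.25),
        "VL": TriangularFuzzyNumber(0.0, 0.25, 0.5),
        "L": TriangularFuzzyNumber(0.25, 0.5, 0.75),
        "H": TriangularFuzzyNumber(0.5, 0.75, 1.0),
        "VH": TriangularFuzzyNumber(0.75, 1.0, 1.0),
    },
)


def term_to_tfn(term: str, scale: LinguisticScale = DEFAULT_SCALE) -> TriangularFuzzyNumber:
    """Map a linguistic term to its triangular fuzzy number.

    Raises :class:`PanelValidationError` for a term outside the scale.
    """
    return scale.tfn(term)


@dataclass
class ExpertPanel:
    """``k`` experts' complete n x n grids of linguistic terms.

    ``grids`` has shape (k, n, n) and holds canonical term strings.
    Diagonals are expected to be the lowest ("No") term; by default a
    deviation only warns, under ``strict`` validation it is an error.
    """

    factors: list[str]
    experts: list[str]
    grids: np.ndarray
    scale: LinguisticScale = field(default=DEFAULT_SCALE)

    def __post_init__(self) -> None:
        n, k = len(self.factors), len(self.experts)
        self.grids = np.asarray(self.grids, dtype=object)
        if self.grids.shape != (k, n, n):
            raise PanelValidationError(
                f"grids shape {self.grids.shape} does not match "
                f"{k} experts x {n}x{n} factors"
            )
        if len(set(self.factors)) != n:
            raise PanelValidationError("factor labels must be unique")

    @property
    def n(self) -> int:
        return len(self.factors)

    @property
    def k(self) -> int:
        return len(self.experts)

    def validate(self, strict_diagonal: bool = False) -> "ExpertPanel":
        """Canonicalize every cell and check the diagonal convention."""
        canon = np.empty_like(self.grids)
        for e in range(self.k):
            for i in range(self.n):
                for j in range(self.n):
                    cell = self.grids[e, i, j]
                    if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                            or str(cell).strip() == "":
                        raise PanelValidationError(
                            f"expert {self.experts[e]!r}: empty cell at "
                            f"row {self.factors[i]!r}, column {self.factors[j]!r}"
                        )
                    try:
                        canon[e, i, j] = self.scale.canonical(str(cell))
                    except PanelValidationError as err:
                        raise PanelValidationError(
                            f"expert {self.experts[e]!r}, row {self.factors[i]!r}, "
                            f"column {self.factors[j]!r}: {err}"
                        ) from None
        self.grids = canon
        low = self.scale.lowest
        bad = [
            (self.experts[e], self.factors[i])
            for e in range(self.k)
            for i in range(self.n)
            if canon[e, i, i] != low
        ]
        if bad:
            msg = (
                f"diagonal cells not rated {low!r} (factors do not influence "
                f"themselves): {bad[:5]}{'...' if len(bad) > 5 else ''}"
            )
            if strict_diagonal:
                raise PanelValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        return self

    def tfn_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return float arrays L, M, R of shape (k, n, n)."""
        lut = {t: self.scale.tfns[t].as_tuple() for t in self.scale.terms}
        L = np.empty((self.k, self.n, self.n))
        M = np.empty_like(L)
        R = np.empty_like(L)
        for e in range(self.k):
            for i in range(self.n):
                for j in range(self.n):
                    L[e, i, j], M[e, i, j], R[e, i, j] = lut[self.grids[e, i, j]]
        return L, M, R

    def grid_frame(self, expert: str) -> pd.DataFrame:
        e = self.experts.index(expert)
        return pd.DataFrame(self.grids[e], index=self.factors, columns=self.factors)


def _read_grid(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.shape[0] != df.shape[1]:
        raise PanelValidationError(
            f"{path}: grid is {df.shape[0]}x{df.shape[1]}, expected square"
        )
    if list(df.index) != list(df.columns):
        raise PanelValidationError(
            f"{path}: row labels differ from column labels"
        )
    return df


def read_panel(
    paths: Sequence[str | Path],
    scale: LinguisticScale = DEFAULT_SCALE,
    expert_names: Sequence[str] | None = None,
    strict_diagonal: bool = False,
) -> ExpertPanel:
    """Read one CSV per expert (factor labels as first row and column).

    All files must share the same factor labels in the same order.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise PanelValidationError("no expert files given")
    frames = [_read_grid(p) for p in paths]
    factors = list(frames[0].index)
    for p, df in zip(paths[1:], frames[1:]):
        if list(df.index) != factors:
            raise PanelValidationError(
                f"{p}: factor labels do not match {paths[0]}"
            )
    if expert_names is None:
        expert_names = [p.stem for p in paths]
    grids = np.stack([df.to_numpy(dtype=object) for df in frames])
    panel = ExpertPanel(factors=factors, experts=list(expert_names),
                        grids=grids, scale=scale)
    return panel.validate(strict_diagonal=strict_diagonal)


def read_manifest(path: str | Path) -> ExpertPanel:
    """Read a YAML manifest listing expert files and optional scale overrides.

    Schema::

        experts:            # required, file paths relative to the manifest
          - expert1.csv
          - expert2.csv
        scale:              # optional, term -> [l, m, r] overrides
          VH: [0.8, 1.0, 1.0]
        strict_diagonal: false
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "experts" not in cfg or not cfg["experts"]:
        raise PanelValidationError(f"{path}: manifest lists no expert files")
    scale = DEFAULT_SCALE
    if cfg.get("scale"):
        tfns = dict(DEFAULT_SCALE.tfns)
        for term, lmr in cfg["scale"].items():
            canon = DEFAULT_SCALE.canonical(term)
            tfns[canon] = TriangularFuzzyNumber(*map(float, lmr))
        scale = LinguisticScale(terms=DEFAULT_SCALE.terms, tfns=tfns)
    files = [path.parent / f for f in cfg["experts"]]
    return read_panel(files, scale=scale,
                      strict_diagonal=bool(cfg.get("strict_diagonal", False)))


def write_panel(panel: ExpertPanel, directory: str | Path) -> list[Path]:
    """Write one CSV per expert plus a ``manifest.yaml``; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for e, name in enumerate(panel.experts):
        df = pd.DataFrame(panel.grids[e], index=panel.factors,
                          columns=panel.factors)
        out = directory / f"{name}.csv"
        df.to_csv(out)
        written.append(out)
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"experts": [p.name for p in written]}, fh)
    written.append(manifest)
    return written
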
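"""Interpretive structural modelling: binarize, close, extract levels.

The total relation matrix is thresholded into an adjacency matrix ``H``
(entries >= the threshold become 1), closed reflexively and transitively
into the reachability matrix ``K``, and partitioned into levels: the
surface level collects the factors whose reachable set is contained in
their antecedent set (they influence nothing that does not already
influence them); those are removed and the rule is re-applied, so deeper
levels hold the progressively more upstream causes.  Level 1 is the
surface/direct layer; the largest level index is the deepest root cause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "binarize",
    "reachability_closure",
    "level_partition",
    "ism_hierarchy",
    "IsmResult",
    "to_dot",
]


def _as_frame(M, dtype=float) -> pd.DataFrame:
    if isinstance(M, pd.DataFrame):
        return M
    arr = np.asarray(M, dtype=dtype)
    labels = [f"x{i + 1}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=labels, columns=labels)


def binarize(T, threshold: float) -> pd.DataFrame:
    """Initial adjacency matrix: 1 where t_ij >= threshold (inclusive)."""
    df = _as_frame(T)
    arr = df.to_numpy(dtype=float)
    if not (arr.min() <= threshold <= arr.max()):
        warnings.warn(
            f"threshold {threshold} lies outside the matrix value range "
            f"[{arr.min():.4g}, {arr.max():.4g}]", stacklevel=2,
        )
    H = (arr >= threshold).astype(int)
    return pd.DataFrame(H, index=df.index, columns=df.columns)


def reachability_closure(H) -> pd.DataFrame:
    """Reflexive-transitive Boolean closure (Warshall) of ``H``."""
    df = _as_frame(H, dtype=int)
    K = df.to_numpy(dtype=bool)
    n = K.shape[0]
    if df.shape[0] != df.shape[1]:
        raise ValueError("adjacency matrix must be square")
    K = K | np.eye(n, dtype=bool)
    for p in range(n):
        K |= K[:, p:p + 1] & K[p:p + 1, :]
    return pd.DataFrame(K.astype(int), index=df.index, columns=df.columns)


@dataclass(frozen=True)
class IsmResult:
    """Level partition plus the sets and digraph behind it.

    ``levels[0]`` is the surface layer (level index 1).  ``digraph`` holds
    the retained direct edges (from ``H`` when available, else from ``K``)
    without self-loops.
    """

    levels: list[list[str]]
    level_of: dict[str, int]
    reachable: dict[str, frozenset]
    antecedent: dict[str, frozenset]
    digraph: nx.DiGraph

    @property
    def depth(self) -> int:
        return len(self.levels)

    def to_dict(self) -> dict:
        return {str(i + 1): list(level) for i, level in enumerate(self.levels)}


def level_partition(K, rule: str = "surface", H=None) -> IsmResult:
    """Partition factors into levels from the reachability matrix ``K``.

    ``rule="surface"`` (default) extracts, each round, the factors with
    R(s) ∩ A(s) = R(s) — the standard top-down reading where level 1 is
    the directly-affected surface layer.  ``rule="root"`` extracts
    R(s) ∩ A(s) = A(s) instead, peeling from the causes; on matrices whose
    strata are unambiguous both give the same grouping with the level
    order reversed relative to causation depth.

    R and A sets are recomputed on the remaining submatrix each round, so
    termination is guaranteed for any reflexive ``K`` (each round removes
    at least one factor).
    """
    if rule not in ("surface", "root"):
        raise ValueError("rule must be 'surface' or 'root'")
    dfK = _as_frame(K, dtype=int)
    labels = [str(c) for c in dfK.columns]
    arr = dfK.to_numpy(dtype=bool)
    n = len(labels)

    reach_full = {
        labels[i]: frozenset(labels[j] for j in range(n) if arr[i, j])
        for i in range(n)
    }
    ante_full = {
        labels[i]: frozenset(labels[j] for j in range(n) if arr[j, i])
        for i in range(n)
    }

    remaining = list(range(n))
    levels: list[list[str]] = []
    while remaining:
        extracted = []
        for i in remaining:
            reach = {j for j in remaining if arr[i, j]}
            ante = {j for j in remaining if arr[j, i]}
            inter = reach & ante
            if (inter == reach) if rule == "surface" else (inter == ante):
                extracted.append(i)
        if not extracted:
            raise RuntimeError(
                "level extraction stalled; reachability matrix is not "
                "transitive-reflexive"
            )
        levels.append([labels[i] for i in extracted])
        remaining = [i for i in remaining if i not in set(extracted)]

    level_of = {f: i + 1 for i, level in enumerate(levels) for f in level}

    edges_src = _as_frame(H, dtype=int) if H is not None else dfK
    earr = edges_src.to_numpy(dtype=bool)
    digraph = nx.DiGraph()
    digraph.add_nodes_from(labels)
    for i in range(n):
        for j in range(n):
            if i != j and earr[i, j]:
                digraph.add_edge(labels[i], labels[j])

    return IsmResult(
        levels=levels,
        level_of=level_of,
        reachable=reach_full,
        antecedent=ante_full,
        digraph=digraph,
    )


def ism_hierarchy(T, threshold: float, rule: str = "surface") -> tuple[pd.DataFrame, pd.DataFrame, IsmResult]:
    """Threshold ``T``, close, and partition.  Returns (H, K, result)."""
    H = binarize(T, threshold)
    K = reachability_closure(H)
    return H, K, level_partition(K, rule=rule, H=H)


def to_dot(result: IsmResult, name: str = "ism") -> str:
    """Render the hierarchy as a DOT digraph, one rank group per level."""
    lines = [f"digraph {name} {{", "  rankdir=BT;"]
    for i, level in enumerate(result.levels, start=1):
        members = " ".join(f'"{f}";' for f in level)
        lines.append(f"  {{ rank=same; /* level {i} */ {members} }}")
    for u, v in sorted(result.digraph.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines)
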
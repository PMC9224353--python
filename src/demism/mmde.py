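"""Maximum mean de-entropy (MMDE) threshold selection.

DEMATEL-style total relation matrices are dense; turning one into a digraph
needs a cutoff deciding which influences are strong enough to keep.  MMDE
derives that cutoff from the matrix itself.  All n^2 entries are ordered
descending as triplets (t_ij, source, target).  The source ("dispatch") and
target ("receive") node sequences of that ordering are scanned prefix by
prefix: a prefix of length t with m distinct nodes and occurrence counts
k_u has mean de-entropy

    MDE_t = (ln m - H_emp) / m,     H_emp = -sum_u (k_u / t) ln(k_u / t),

the information gained relative to a uniform spread over the prefix's nodes,
averaged per node.  The prefix maximizing MDE isolates the small set of
nodes that dominate the strongest influences.  For each node in the
dispatch-side maximizing set, its strongest outgoing triplet enters the
threshold set; for each receive-side node, its strongest incoming triplet.
The threshold is the minimum influence value in that set, so it is always
an actual matrix entry.

By default the prefix scan stops at t = n, the number of factors (node
sets larger than the factor count cannot occur and in practice the curve
maximum that identifies a *small* dominant set sits well below n); passing
``prefix_limit=n*n`` scans every prefix.  See docs/methods.md for why the
capped scan is the default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrderedTriplet",
    "MmdeTrace",
    "order_triplets",
    "mde_sequence",
    "max_mde_node_set",
    "mmde_threshold",
]


class OrderedTriplet(NamedTuple):
    """One matrix entry as (value, source label, target label)."""

    value: float
    source: str
    target: str


def _as_frame(T) -> pd.DataFrame:
    if isinstance(T, pd.DataFrame):
        return T
    arr = np.asarray(T, dtype=float)
    labels = [f"x{i + 1}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=labels, columns=labels)


def order_triplets(T) -> list[OrderedTriplet]:
    """All n^2 entries sorted by value descending.

    Ties are broken by (row index, column index) ascending so the ordering
    is deterministic.
    """
    df = _as_frame(T)
    if df.shape[0] != df.shape[1]:
        raise ValueError("total relation matrix must be square")
    arr = df.to_numpy(dtype=float)
    n = arr.shape[0]
    rows, cols = np.divmod(np.arange(n * n), n)
    order = np.lexsort((cols, rows, -arr.ravel()))
    labels = [str(c) for c in df.columns]
    return [
        OrderedTriplet(float(arr[rows[o], cols[o]]), labels[rows[o]], labels[cols[o]])
        for o in order
    ]


def mde_sequence(nodes: Sequence) -> np.ndarray:
    """Mean de-entropy of every prefix of a node sequence.

    Uses an incremental update of sum(k ln k) so the full curve costs
    O(len) despite recomputing the entropy at every prefix length.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("node sequence must be non-empty")
    counts: Counter = Counter()
    s_klnk = 0.0  # sum over nodes of k ln k
    out = np.empty(len(nodes))
    for t, node in enumerate(nodes, start=1):
        k = counts[node]
        if k:
            s_klnk -= k * np.log(k)
        k += 1
        counts[node] = k
        s_klnk += k * np.log(k)
        m = len(counts)
        # H_emp = ln t - (1/t) sum k ln k
        h_emp = np.log(t) - s_klnk / t
        out[t - 1] = (np.log(m) - h_emp) / m
    # clip tiny negative round-off at uniform prefixes
    return np.where(np.abs(out) < 1e-15, 0.0, out)


def max_mde_node_set(
    nodes: Sequence, mde: Sequence[float]
) -> tuple[float, int, list]:
    """Maximum of an MDE curve and the distinct nodes of its prefix.

    Returns ``(max value, argmax prefix length, nodes in first-appearance
    order)``.  Ties at the maximum resolve to the earliest prefix.
    """
    nodes = list(nodes)
    mde = np.asarray(mde, dtype=float)
    if len(nodes) != len(mde):
        raise ValueError("node and MDE sequences must have equal length")
    # exact ties between prefix lengths exist (different count patterns can
    # have identical MDE); resolve to the earliest within float tolerance
    t_max = int(np.argmax(mde >= mde.max() - 1e-12)) + 1
    seen: dict = {}
    for node in nodes[:t_max]:
        seen.setdefault(node, None)
    return float(mde[t_max - 1]), t_max, list(seen)


@dataclass(frozen=True)
class MmdeTrace:
    """Full audit trail of a threshold computation."""

    triplets: list[OrderedTriplet]
    dispatch_nodes: list[str]
    receive_nodes: list[str]
    mde_dispatch: np.ndarray
    mde_receive: np.ndarray
    max_mde_dispatch: float
    argmax_dispatch: int
    dispatch_node_set: list[str]
    max_mde_receive: float
    argmax_receive: int
    receive_node_set: list[str]
    threshold_set: list[OrderedTriplet]
    threshold: float
    prefix_limit: int = field(default=0)

    def to_dict(self) -> dict:
        """JSON-ready report mirroring the algorithm's steps."""
        trip = lambda t: {"value": t.value, "source": t.source, "target": t.target}
        return {
            "ordered_triplets_head": [trip(t) for t in self.triplets[:5]],
            "ordered_triplets_tail": [trip(t) for t in self.triplets[-1:]],
            "prefix_limit": self.prefix_limit,
            "mde_dispatch": [float(v) for v in self.mde_dispatch],
            "mde_receive": [float(v) for v in self.mde_receive],
            "max_mde_dispatch": self.max_mde_dispatch,
            "argmax_dispatch": self.argmax_dispatch,
            "dispatch_node_set": list(self.dispatch_node_set),
            "max_mde_receive": self.max_mde_receive,
            "argmax_receive": self.argmax_receive,
            "receive_node_set": list(self.receive_node_set),
            "threshold_set": [trip(t) for t in self.threshold_set],
            "threshold": self.threshold,
        }


def _first_triplet(triplets: list[OrderedTriplet], node: str, side: str) -> OrderedTriplet:
    idx = 1 if side == "source" else 2
    for t in triplets:
        if t[idx] == node:
            return t
    raise KeyError(node)


def mmde_threshold(T, prefix_limit: int | None = None) -> tuple[float, MmdeTrace]:
    """Unique threshold for a total relation matrix via MMDE.

    ``prefix_limit`` bounds the prefix scan; ``None`` means n, the number
    of factors.  Returns ``(threshold, trace)``.
    """
    df = _as_frame(T)
    n = df.shape[0]
    triplets = order_triplets(df)
    if prefix_limit is None:
        prefix_limit = n
    prefix_limit = int(min(max(prefix_limit, 1), n * n))

    dispatch = [t.source for t in triplets]
    receive = [t.target for t in triplets]
    mde_di = mde_sequence(dispatch[:prefix_limit])
    mde_re = mde_sequence(receive[:prefix_limit])

    max_di, t_di, set_di = max_mde_node_set(dispatch[:prefix_limit], mde_di)
    max_re, t_re, set_re = max_mde_node_set(receive[:prefix_limit], mde_re)

    # strongest outgoing triplet of each dispatch-set node, strongest
    # incoming triplet of each receive-set node
    threshold_set = [_first_triplet(triplets, u, "source") for u in set_di]
    threshold_set += [_first_triplet(triplets, v, "target") for v in set_re]
    lam = min(t.value for t in threshold_set)

    trace = MmdeTrace(
        triplets=triplets,
        dispatch_nodes=dispatch,
        receive_nodes=receive,
        mde_dispatch=mde_di,
        mde_receive=mde_re,
        max_mde_dispatch=max_di,
        argmax_dispatch=t_di,
        dispatch_node_set=set_di,
        max_mde_receive=max_re,
        argmax_receive=t_re,
        receive_node_set=set_re,
        threshold_set=threshold_set,
        threshold=lam,
        prefix_limit=prefix_limit,
    )
    return lam, trace
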
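"""MICMAC classification of factors by driving power and dependence.

From the final reachability matrix ``K``, a factor's driving power is its
row sum (how many factors it reaches, itself included) and its dependence
the column sum (how many reach it).  Plotting dependence against driving
power splits factors into four quadrants:

* I   autonomous — low driving, low dependence;
* II  dependent  — low driving, high dependence;
* III linkage    — high driving, high dependence (unstable relays);
* IV  driving    — high driving, low dependence (root levers).

The axis boundary on each side defaults to the midpoint of the observed
min-max range, with counts equal to the boundary classified as "high".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MicmacResult", "driving_dependence", "classify"]

QUADRANTS = {
    (False, False): "I",
    (False, True): "II",
    (True, True): "III",
    (True, False): "IV",
}

QUADRANT_NAMES = {
    "I": "autonomous",
    "II": "dependent",
    "III": "linkage",
    "IV": "driving",
}


def driving_dependence(K) -> pd.DataFrame:
    """Row (driving) and column (dependence) sums of the reachability matrix."""
    if not isinstance(K, pd.DataFrame):
        arr = np.asarray(K, dtype=int)
        K = pd.DataFrame(arr, index=[f"x{i+1}" for i in range(arr.shape[0])],
                         columns=[f"x{i+1}" for i in range(arr.shape[0])])
    arr = K.to_numpy(dtype=int)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("reachability matrix must be square")
    return pd.DataFrame(
        {"driving": arr.sum(axis=1), "dependence": arr.sum(axis=0)},
        index=[str(c) for c in K.columns],
    )


@dataclass(frozen=True)
class MicmacResult:
    """Counts, quadrant per factor, and the axis boundaries used."""

    table: pd.DataFrame
    driving_boundary: float
    dependence_boundary: float

    def cluster(self, quadrant: str) -> list[str]:
        return list(self.table.index[self.table["quadrant"] == quadrant])

    def to_dict(self) -> dict:
        return {
            "boundaries": {
                "driving": float(self.driving_boundary),
                "dependence": float(self.dependence_boundary),
            },
            "clusters": {q: self.cluster(q) for q in ("I", "II", "III", "IV")},
        }


def classify(
    counts: pd.DataFrame,
    boundaries: tuple[float, float] | None = None,
) -> MicmacResult:
    """Assign each factor to a MICMAC quadrant.

    ``boundaries`` is ``(driving_boundary, dependence_boundary)``; by
    default each is the midpoint of that axis's observed range.  A count
    greater than or equal to its boundary is "high".
    """
    if not {"driving", "dependence"}.issubset(counts.columns):
        raise ValueError("counts must have 'driving' and 'dependence' columns")
    drv = counts["driving"].to_numpy(dtype=float)
    dep = counts["dependence"].to_numpy(dtype=float)
    if boundaries is not None:
        drv_b, dep_b = map(float, boundaries)
    else:
        drv_b = (drv.min() + drv.max()) / 2.0
        dep_b = (dep.min() + dep.max()) / 2.0
    for name, axis in (("driving", drv), ("dependence", dep)):
        if axis.min() == axis.max():
            warnings.warn(
                f"degenerate {name} axis (all counts equal); every factor "
                f"is classified low on it", stacklevel=2,
            )
    # on a degenerate axis everything counts as low
    high_drv = (drv >= drv_b) if drv.min() != drv.max() else np.zeros_like(drv, bool)
    high_dep = (dep >= dep_b) if dep.min() != dep.max() else np.zeros_like(dep, bool)
    table = counts.copy()
    table["quadrant"] = [
        QUADRANTS[(bool(hd), bool(he))] for hd, he in zip(high_drv, high_dep)
    ]
    table["cluster"] = table["quadrant"].map(QUADRANT_NAMES)
    return MicmacResult(
        table=table, driving_boundary=drv_b, dependence_boundary=dep_b
    )
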
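"""Bundled example data."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ._io import read_matrix

__all__ = ["load_miner_safety"]


def load_miner_safety() -> pd.DataFrame:
    """20x20 total relation matrix of a miner-safety influence study.

    Factors x1..x20 are influences on miners' unsafe behaviors in
    intelligent (highly automated) coal mines, spanning individual traits,
    equipment, management and environment — e.g. x11 leadership attention,
    x12 safety-system standardization, x13 safety input level, x19
    government regulation.  The matrix was produced by a seven-expert
    fuzzy DEMATEL elicitation and is printed to four decimals; it is the
    package's reference fixture for the threshold, hierarchy and
    classification stages.
    """
    ref = resources.files("demism.data") / "miner_safety_total_relation.csv"
    with resources.as_file(ref) as path:
        return read_matrix(path)
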
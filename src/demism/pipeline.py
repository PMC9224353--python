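"""End-to-end orchestration and report export.

``run_pipeline`` accepts exactly one input form — an expert panel, a crisp
direct matrix, or a total relation matrix — enters the stage chain at the
matching point and runs the rest in order: defuzzify/DEMATEL -> MMDE
threshold -> ISM hierarchy -> MICMAC classification.  A manual threshold
override skips the MMDE stage.  The report records every option in effect,
so deterministic runs are reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from ._io import write_matrix
from .fuzzy_dematel import (
    DematelScores,
    InfluenceMatrices,
    defuzzify_panel,
    normalize,
    prominence_causality,
    total_relation,
)
from .ism import IsmResult, ism_hierarchy, to_dot
from .micmac import MicmacResult, classify, driving_dependence
from .mmde import MmdeTrace, mmde_threshold
from .panel import ExpertPanel

__all__ = ["PipelineReport", "run_pipeline", "export"]

log = logging.getLogger("demism")


@dataclass
class PipelineReport:
    """All stage outputs of one run, plus the options that produced them."""

    options: dict[str, Any]
    direct: pd.DataFrame | None
    normalized: pd.DataFrame | None
    total: pd.DataFrame
    scores: DematelScores
    trace: MmdeTrace | None
    threshold: float
    adjacency: pd.DataFrame
    reachability: pd.DataFrame
    ism: IsmResult
    micmac: MicmacResult

    def summary(self) -> dict[str, Any]:
        return {
            "options": self.options,
            "n_factors": int(self.total.shape[0]),
            "threshold": self.threshold,
            "levels": self.ism.to_dict(),
            "micmac": self.micmac.to_dict(),
        }


def run_pipeline(
    panel: ExpertPanel | None = None,
    direct: pd.DataFrame | None = None,
    total: pd.DataFrame | None = None,
    *,
    zero_diagonal: bool = False,
    threshold: float | None = None,
    prefix_limit: int | None = None,
    level_rule: str = "surface",
    boundaries: tuple[float, float] | None = None,
) -> PipelineReport:
    """Run the stage chain from whichever input form is given.

    Exactly one of ``panel``, ``direct``, ``total`` must be supplied.
    ``threshold`` overrides MMDE; the other keywords expose the documented
    stage options (diagonal handling, MMDE prefix scan bound, level
    extraction rule, MICMAC axis boundaries).
    """
    given = [x is not None for x in (panel, direct, total)]
    if sum(given) != 1:
        raise ValueError(
            "supply exactly one of panel=, direct= or total= as input"
        )

    options: dict[str, Any] = {
        "zero_diagonal": zero_diagonal,
        "threshold_override": threshold,
        "prefix_limit": prefix_limit,
        "level_rule": level_rule,
        "micmac_boundaries": boundaries,
        "triplet_tie_break": "(row, column) ascending",
        "mde_argmax_tie_break": "earliest prefix",
    }

    D = N = None
    if panel is not None:
        log.info("defuzzify: CFCS over %d experts, %d factors (zero_diagonal=%s)",
                 panel.k, panel.n, zero_diagonal)
        D = defuzzify_panel(panel, zero_diagonal=zero_diagonal)
    elif direct is not None:
        D = direct
    if D is not None:
        N = normalize(D)
        T = total_relation(N)
    else:
        T = total

    scores = prominence_causality(T)

    trace = None
    if threshold is None:
        threshold, trace = mmde_threshold(T, prefix_limit=prefix_limit)
        log.info("mmde: threshold %.4f (prefix_limit=%d)", threshold,
                 trace.prefix_limit)
    else:
        log.info("mmde skipped: manual threshold %.4f", threshold)

    H, K, ism_result = ism_hierarchy(T, threshold, rule=level_rule)
    log.info("ism: %d levels (rule=%s)", ism_result.depth, level_rule)

    counts = driving_dependence(K)
    micmac_result = classify(counts, boundaries=boundaries)
    log.info("micmac: boundaries driving=%.2f dependence=%.2f",
             micmac_result.driving_boundary, micmac_result.dependence_boundary)

    return PipelineReport(
        options=options,
        direct=None if D is None else pd.DataFrame(D),
        normalized=N,
        total=pd.DataFrame(T) if not isinstance(T, pd.DataFrame) else T,
        scores=scores,
        trace=trace,
        threshold=float(threshold),
        adjacency=H,
        reachability=K,
        ism=ism_result,
        micmac=micmac_result,
    )


def export(
    report: PipelineReport,
    directory: str | Path,
    formats: tuple[str, ...] = ("csv", "json", "dot"),
) -> list[Path]:
    """Write the report to ``directory``; returns the files written.

    ``csv`` emits the matrices and score/classification tables, ``json``
    the self-contained summary (with the MMDE trace when present), and
    ``dot`` the level-ranked hierarchy digraph.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    if "csv" in formats:
        if report.direct is not None:
            write_matrix(report.direct, _w(directory / "direct.csv"))
        if report.normalized is not None:
            write_matrix(report.normalized, _w(directory / "normalized.csv"))
        write_matrix(report.total, _w(directory / "total_relation.csv"))
        report.scores.table.to_csv(_w(directory / "scores.csv"),
                                   float_format="%.6f", index_label="factor")
        write_matrix(report.adjacency, _w(directory / "adjacency.csv"), decimals=0)
        write_matrix(report.reachability, _w(directory / "reachability.csv"), decimals=0)
        report.micmac.table.to_csv(_w(directory / "micmac.csv"),
                                   index_label="factor")
    if "json" in formats:
        payload = report.summary()
        if report.trace is not None:
            payload["mmde_trace"] = report.trace.to_dict()
        with open(_w(directory / "report.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
    if "dot" in formats:
        (_w(directory / "hierarchy.dot")).write_text(to_dot(report.ism) + "\n")
    return written
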
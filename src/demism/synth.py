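"""Synthetic expert panels with planted structure.

Generates multi-expert linguistic survey grids so the whole pipeline is
testable end to end without external data.  Every expert draws each
off-diagonal cell independently from a base distribution over the five
terms; designated "driver" factors have all their outgoing ratings shifted
up the ordinal scale, "sink" factors their incoming ratings, and each
expert independently perturbs cells by one term with a small probability.
Shifts and noise clamp at the scale ends, the diagonal is always the
lowest term, and everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import DEFAULT_SCALE, ExpertPanel, LinguisticScale

__all__ = ["PanelSpec", "generate_panel"]

#: base probabilities over (No, VL, L, H, VH): mostly weak-to-moderate
#: judgments, occasional strong ones — a typical survey profile.
DEFAULT_TERM_PROBS = (0.15, 0.25, 0.30, 0.20, 0.10)


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for one synthetic panel.

    ``drivers``/``sinks`` are 0-based factor indices; a driver's outgoing
    (row) ratings and a sink's incoming (column) ratings are shifted up by
    ``driver_shift``/``sink_shift`` ordinal steps before noise.
    """

    n: int = 20
    k: int = 7
    seed: int = 0
    term_probs: tuple[float, ...] = DEFAULT_TERM_PROBS
    drivers: tuple[int, ...] = ()
    sinks: tuple[int, ...] = ()
    driver_shift: int = 2
    sink_shift: int = 2
    noise: float = 0.1

    def __post_init__(self) -> None:
        if self.n < 2 or self.k < 1:
            raise ValueError("need n >= 2 factors and k >= 1 experts")
        probs = np.asarray(self.term_probs, dtype=float)
        if probs.shape != (5,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("term_probs must be 5 non-negative values summing to 1")
        if set(self.drivers) & set(self.sinks):
            raise ValueError("driver and sink sets must be disjoint")
        for idx in (*self.drivers, *self.sinks):
            if not 0 <= idx < self.n:
                raise ValueError(f"factor index {idx} outside 0..{self.n - 1}")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be a probability")


def generate_panel(spec: PanelSpec, scale: LinguisticScale = DEFAULT_SCALE) -> ExpertPanel:
    """Draw one reproducible panel from the spec."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n, spec.k
    n_terms = len(scale.terms)

    idx = rng.choice(n_terms, size=(k, n, n), p=np.asarray(spec.term_probs))

    shift = np.zeros((n, n), dtype=int)
    for d in spec.drivers:
        shift[d, :] += spec.driver_shift
    for s in spec.sinks:
        shift[:, s] += spec.sink_shift
    idx = idx + shift[None, :, :]

    if spec.noise > 0:
        flips = rng.random((k, n, n)) < spec.noise
        signs = rng.choice((-1, 1), size=(k, n, n))
        idx = idx + flips * signs

    idx = np.clip(idx, 0, n_terms - 1)
    idx[:, np.arange(n), np.arange(n)] = 0  # diagonal is the lowest term

    terms = np.array(scale.terms, dtype=object)
    grids = terms[idx]
    factors = [f"x{i + 1}" for i in range(n)]
    experts = [f"expert{e + 1}" for e in range(k)]
    return ExpertPanel(factors=factors, experts=experts, grids=grids, scale=scale)
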
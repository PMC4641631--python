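"""Trophic position and trophic-level bands from d15N.

Continuous trophic position relative to a baseline consumer of known position
lambda (here the long-lived deposit/suspension-feeding bivalve *Yoldia
eightsi*, a first consumer, lambda = 2):

    TP = lambda + (d15N_consumer - d15N_base) / Delta_n

with Delta_n the per-level d15N enrichment.  The default Delta_n is 1.8 per
mil — an invertebrate/plant-diet fractionation step — rather than the classic
3 per mil.

Discrete trophic levels are bands on the d15N axis: TL2 spans the observed
range of the designated first consumers (filter/suspension feeders plus the
baseline bivalve), and TL3, TL4, ... are consecutive bands of width Delta_n
stacked above the TL2 upper edge.  A value exactly on a band boundary is
assigned to the lower band; consumers below the TL2 band (e.g. an
ectosymbiont-bearing copepod with a chemosynthetic signal) are kept at TL2
with a below-band warning flag rather than rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .data import GroupSummary, IsotopeRecord, TrophicGroup

__all__ = [
    "TrophicConfig",
    "TrophicAssignment",
    "baseline_d15n",
    "derive_tl2_band",
    "trophic_position",
    "assign_trophic_levels",
    "count_consumer_levels",
]

BASELINE_TAXON = "Yoldia eightsi"

FIRST_CONSUMER_GROUPS = frozenset({TrophicGroup.FILTER_SUSPENSION_FEEDER})


@dataclass(frozen=True)
class TrophicConfig:
    """Baseline and fractionation settings for trophic-position estimation."""

    lam: float = 2.0  # trophic position of the baseline organism
    delta_n: float = 1.8  # per-mil d15N enrichment per trophic level
    baseline_d15N: float | None = None  # derived from the data when None
    tl2_band: tuple[float, float] | None = None  # derived when None
    printed_form: bool = False  # compatibility: divide (lam + delta) jointly

    def __post_init__(self) -> None:
        if self.delta_n <= 0:
            raise ValueError("delta_n must be > 0")
        if self.tl2_band is not None and not self.tl2_band[0] < self.tl2_band[1]:
            raise ValueError("tl2_band must satisfy low < high")


@dataclass(frozen=True)
class TrophicAssignment:
    item: GroupSummary | IsotopeRecord
    tp: float
    tl_band: int  # 2, 3, 4, ...
    below_band: bool = False


def _d15n(item) -> float:
    return item.mean_d15N if isinstance(item, GroupSummary) else item.d15N


def baseline_d15n(items: Iterable, taxon: str = BASELINE_TAXON) -> float:
    """Mean d15N of the baseline taxon, pooled across sites."""
    vals = [_d15n(it) for it in items if it.taxon == taxon]
    if not vals:
        raise ValueError(f"baseline taxon {taxon!r} not found")
    return float(np.mean(vals))


def derive_tl2_band(items: Iterable) -> tuple[float, float]:
    """[min, max] d15N over the designated first consumers.

    First consumers are the filter/suspension feeders plus the baseline
    bivalve, whose feeding habits place them at TL2 irrespective of their
    d15N spread.
    """
    vals = [
        _d15n(it)
        for it in items
        if it.trophic_group in FIRST_CONSUMER_GROUPS or it.taxon == BASELINE_TAXON
    ]
    if len(vals) < 2:
        raise ValueError("not enough first-consumer rows to derive the TL2 band")
    return (float(min(vals)), float(max(vals)))


def trophic_position(d15n_consumer: float, config: TrophicConfig) -> float:
    """Continuous trophic position of one d15N value."""
    if config.baseline_d15N is None:
        raise ValueError("config.baseline_d15N is unset; derive it from data first")
    if config.printed_form:
        return (config.lam + (d15n_consumer - config.baseline_d15N)) / config.delta_n
    return config.lam + (d15n_consumer - config.baseline_d15N) / config.delta_n


def resolve_config(items: Sequence, config: TrophicConfig) -> TrophicConfig:
    """Fill the data-derived defaults (baseline, TL2 band) from ``items``."""
    if config.baseline_d15N is None:
        config = replace(config, baseline_d15N=baseline_d15n(items))
    if config.tl2_band is None:
        config = replace(config, tl2_band=derive_tl2_band(items))
    return config


def _band_of(x: float, band: tuple[float, float], dn: float) -> tuple[int, bool]:
    low, high = band
    if x <= high:
        # boundary values belong to the lower band; below-band values are kept
        # at TL2 with a warning flag
        return 2, x < low
    # small epsilon keeps values that are exactly on a band edge (up to float
    # representation error) in the lower band
    k = 2 + math.ceil((x - high) / dn - 1e-9)
    return k, False


def assign_trophic_levels(
    items: Sequence[GroupSummary] | Sequence[IsotopeRecord],
    config: TrophicConfig = TrophicConfig(),
) -> list[TrophicAssignment]:
    """TP and TL band for every consumer item (food sources are skipped)."""
    config = resolve_config(items, config)
    out = []
    for item in items:
        if not item.is_consumer:
            continue
        x = _d15n(item)
        band, below = _band_of(x, config.tl2_band, config.delta_n)
        out.append(
            TrophicAssignment(
                item=item, tp=trophic_position(x, config), tl_band=band, below_band=below
            )
        )
    return out


def count_consumer_levels(assignments: Iterable[TrophicAssignment]) -> int:
    """Number of distinct occupied trophic-level bands."""
    return len({a.tl_band for a in assignments})
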
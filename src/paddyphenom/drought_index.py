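"""LER stress-tolerance index and biomass composition accounting.

The leaf-emergence-rate (LER) stress tolerance index compares how many
leaves a genotype sets between drought onset (TS1) and peak stress (TS4)
under drought versus under well-watered control:

    LER = 100 * (Δnl_drought / Δnl_control),   scaled into [0, 100].

Genotypes are then banded: sensitive (< 60), moderate ([60, 75)),
tolerant (>= 75). The biomass accounting splits above-ground biomass
(BMW = stem weight + leaf weight) into stem and leaf percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .synth_phenome import DestructiveRecord

logger = logging.getLogger(__name__)

TOLERANT = "tolerant"
MODERATE = "moderate"
SENSITIVE = "sensitive"
UNDEFINED = "undefined"


@dataclass
class LERResult:
    """Eq.-style LER index for one genotype."""

    genotype_id: str
    delta_nl_drought: float
    delta_nl_control: float
    ler_percent: float          # NaN when the control delta is zero
    tolerance_class: str


@dataclass
class BiomassComposition:
    """Above-ground biomass split into stem and leaf percentages."""

    BMW_g: float
    stem_pct: float
    leaf_pct: float


def delta_leaves(counts: Mapping[int, int] | Sequence[int], ts_start: int, ts_peak: int) -> int:
    """Leaves emerged between two time snaps: count(ts_peak) - count(ts_start).

    ``counts`` maps time snap -> leaf count; a plain sequence is treated
    as counts at snaps 1..len(counts). Missing snaps raise ``KeyError``.
    """
    if ts_peak <= ts_start:
        raise ValueError("ts_peak must be after ts_start")
    if not isinstance(counts, Mapping):
        counts = {i + 1: c for i, c in enumerate(counts)}
    for ts in (ts_start, ts_peak):
        if ts not in counts:
            raise KeyError(f"time snap {ts} missing from trajectory")
    return int(counts[ts_peak]) - int(counts[ts_start])


def ler(delta_drought: float, delta_control: float) -> float:
    """LER percentage, clipped into [0, 100].

    A zero control delta leaves the index undefined (NaN) rather than
    crashing; raw ratios above 100 (drought out-emerging control) are
    clipped, with the raw value logged.
    """
    if delta_drought < 0 or delta_control < 0:
        raise ValueError("leaf-emergence deltas must be non-negative")
    if delta_control == 0:
        return float("nan")
    raw = 100.0 * delta_drought / delta_control
    if raw > 100.0:
        logger.info("LER raw ratio %.2f%% clipped to 100%%", raw)
    return float(min(max(raw, 0.0), 100.0))


def classify_ler(ler_percent: float) -> str:
    """Band a LER value: sensitive < 60 <= moderate < 75 <= tolerant."""
    if ler_percent is None or (isinstance(ler_percent, float) and math.isnan(ler_percent)):
        return UNDEFINED
    if not 0.0 <= ler_percent <= 100.0:
        raise ValueError("LER must lie in [0, 100]")
    if ler_percent < 60.0:
        return SENSITIVE
    if ler_percent < 75.0:
        return MODERATE
    return TOLERANT


def ler_for_genotype(
    genotype_id: str,
    drought_counts: Mapping[int, int] | Sequence[int],
    control_counts: Mapping[int, int] | Sequence[int],
    ts_start: int = 1,
    ts_peak: int = 4,
) -> LERResult:
    """Full per-genotype LER computation from two leaf-count trajectories."""
    dd = delta_leaves(drought_counts, ts_start, ts_peak)
    dc = delta_leaves(control_counts, ts_start, ts_peak)
    value = ler(dd, dc)
    return LERResult(
        genotype_id=genotype_id,
        delta_nl_drought=dd,
        delta_nl_control=dc,
        ler_percent=value,
        tolerance_class=classify_ler(value),
    )


def biomass_composition(rec: DestructiveRecord) -> BiomassComposition:
    """Stem/leaf percentage split of above-ground biomass.

    BMW = StW + LW; percentages are NaN-flagged when BMW is zero, and sum
    to 100 exactly otherwise.
    """
    stw, lw = rec.stem_weight_g, rec.leaf_weight_g
    if stw < 0 or lw < 0:
        raise ValueError("weights must be non-negative")
    bmw = stw + lw
    if bmw == 0:
        return BiomassComposition(0.0, float("nan"), float("nan"))
    return BiomassComposition(bmw, 100.0 * stw / bmw, 100.0 * lw / bmw)
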
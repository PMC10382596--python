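"""Pollen-fertility phenotyping.

Pollen fertility is scored as the stained fraction of >=200 iodine-stained
grains per plant.  In a population segregating for the Se killer-protector
system the per-plant fertilities are bimodal (semi-sterile heterozygotes
around 50%, fertile homozygotes near 95%) with a valley in the 70-80% band;
that band is used as the cut-off region, plants below 70% are called
semi-sterile and plants above 80% fertile, and the band itself is left
unassigned ("ambiguous") and excluded from segregation-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .inference import GoFResult, chisq_gof

__all__ = [
    "FertilityRecord",
    "FertilityClass",
    "ClassCounts",
    "classify_fertility",
    "fertility_histogram",
    "class_ratio_counts",
    "segregation_ratio_test",
    "DEFAULT_LOW",
    "DEFAULT_HIGH",
]

logger = logging.getLogger(__name__)

DEFAULT_LOW = 0.70
DEFAULT_HIGH = 0.80


@dataclass(frozen=True)
class FertilityRecord:
    plant_id: str
    stained_fraction: float
    n_pollen: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.stained_fraction <= 1.0:
            raise ValueError(
                f"stained_fraction must lie in [0, 1], got {self.stained_fraction}"
            )
        if self.n_pollen < 1:
            raise ValueError(f"n_pollen must be >= 1, got {self.n_pollen}")


class FertilityClass(str, Enum):
    SEMI_STERILE = "semi_sterile"
    FERTILE = "fertile"
    AMBIGUOUS = "ambiguous"


class ClassCounts(NamedTuple):
    n_semi_sterile: int
    n_fertile: int
    n_ambiguous: int


def classify_fertility(
    record: FertilityRecord, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> FertilityClass:
    """Threshold classification with a strict open cut-off band.

    ``fraction < low`` is semi-sterile, ``fraction > high`` fertile; values
    inside ``[low, high]`` (including the boundaries) are ambiguous.
    """
    if not 0.0 <= low <= high <= 1.0:
        raise ValueError(f"invalid cut-off bounds ({low}, {high})")
    x = record.stained_fraction
    if x < low:
        return FertilityClass.SEMI_STERILE
    if x > high:
        return FertilityClass.FERTILE
    return FertilityClass.AMBIGUOUS


def fertility_histogram(
    records: Sequence[FertilityRecord], bin_width: float = 0.05
) -> pd.Series:
    """Right-open histogram of stained fractions over [0, 1].

    ``bin_width`` must divide 1 evenly.  Returned as a Series indexed by
    ``pandas`` intervals; the last bin is closed on the right so a fraction
    of exactly 1.0 is counted.  Counts sum to the number of records.
    """
    if not records:
        raise ValueError("no fertility records supplied")
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    values = np.array([r.stained_fraction for r in records])
    counts, _ = np.histogram(values, bins=edges)  # numpy closes the last bin
    index = pd.IntervalIndex.from_breaks(np.round(edges, 12), closed="left")
    return pd.Series(counts, index=index, name="count")


def class_ratio_counts(
    records: Iterable[FertilityRecord],
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> ClassCounts:
    """Counts of semi-sterile / fertile / ambiguous plants."""
    n_semi = n_fert = n_amb = 0
    for record in records:
        cls = classify_fertility(record, low=low, high=high)
        if cls is FertilityClass.SEMI_STERILE:
            n_semi += 1
        elif cls is FertilityClass.FERTILE:
            n_fert += 1
        else:
            n_amb += 1
    return ClassCounts(n_semi, n_fert, n_amb)


def segregation_ratio_test(
    records: Sequence[FertilityRecord],
    ratio: tuple[float, float] = (1.0, 1.0),
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    alpha: float = 0.05,
) -> GoFResult:
    """Chi-square test of the semi-sterile:fertile ratio against ``ratio``.

    Ambiguous-band plants are excluded (and logged): the cut-off wording
    assigns no class to the 70-80% band, so they carry no information about
    the segregation ratio under the threshold rule.
    """
    counts = class_ratio_counts(records, low=low, high=high)
    if counts.n_ambiguous:
        logger.info(
            "excluding %d ambiguous plants (stained fraction in [%.2f, %.2f])",
            counts.n_ambiguous,
            low,
            high,
        )
    total = ratio[0] + ratio[1]
    observed = {"semi_sterile": counts.n_semi_sterile, "fertile": counts.n_fertile}
    expected = {"semi_sterile": ratio[0] / total, "fertile": ratio[1] / total}
    return chisq_gof(observed, expected, alpha=alpha)
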
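"""Tracing quantification arithmetic.

Retrograde (input) counts are normalized within animal — the percentage
of labeled neurons per input region relative to that animal's total —
then averaged across animals, which controls for injection size and
viral efficiency.  Anterograde axon density is reduced from per-pixel
axon-probability maps either as the mean probability or as the fraction
of pixels above a threshold; per-animal region densities can be
renormalized to percentages across the sampled regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RegionCounts", "ProbabilityMap", "input_fractions", "axon_density", "density_percentages"]


@dataclass(frozen=True)
class RegionCounts:
    animal_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for region, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValidationError(f"{self.animal_id}/{region}: counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class ProbabilityMap:
    values: np.ndarray  # 2-D, per-pixel axon probability in [0, 1]
    region: str
    animal_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.size == 0:
            raise ValidationError("probability map must be a non-empty 2-D array")
        if values.min() < 0 or values.max() > 1:
            raise ValidationError("probabilities must lie in [0, 1]")


def input_fractions(counts: list[RegionCounts]) -> pd.DataFrame:
    """Per-region labeled-cell percentages: within-animal, then averaged.

    Each animal's region count becomes ``100 * count / total`` (regions
    an animal lacks count as 0%); the table reports the across-animal
    mean and SEM per region.  Animals with zero total cells are
    excluded with a warning.  With a single animal, SEM is 0.
    """
    usable = []
    for rc in counts:
        if rc.total == 0:
            logger.warning("animal %s has zero labeled cells; excluded", rc.animal_id)
        else:
            usable.append(rc)
    if not usable:
        raise ValidationError("no animal with labeled cells")
    regions = sorted({r for rc in usable for r in rc.counts})
    pct = pd.DataFrame(
        {
            rc.animal_id: [100.0 * rc.counts.get(r, 0) / rc.total for r in regions]
            for rc in usable
        },
        index=regions,
    )
    n = pct.shape[1]
    mean = pct.mean(axis=1)
    sem = pct.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(0.0, index=regions)
    return pd.DataFrame({"mean_pct": mean, "sem_pct": sem, "n_animals": n})


def axon_density(
    pmap: ProbabilityMap,
    mode: str = "mean_probability",
    threshold: float = 0.5,
) -> float:
    """Scalar axon density of one probability map, in [0, 1].

    ``mean_probability``: mean of all pixel probabilities.
    ``thresholded_fraction``: fraction of pixels at or above
    ``threshold``.  Multiply by 100 for percent.
    """
    if mode == "mean_probability":
        return float(pmap.values.mean())
    if mode == "thresholded_fraction":
        return float((pmap.values >= threshold).mean())
    raise ValidationError(f"unknown density mode {mode!r}")


def density_percentages(densities: dict[str, float]) -> dict[str, float]:
    """Renormalize per-region densities of one animal to percentages."""
    total = sum(densities.values())
    if total <= 0:
        raise ValidationError("all densities zero")
    return {r: 100.0 * d / total for r, d in densities.items()}
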
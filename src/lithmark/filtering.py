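"""Coverage-based CpG inclusion filter and count-to-ratio conversion.

A CpG enters the analysis only if it is covered at >= ``min_coverage``
reads in at least ``min_fraction_per_group`` of the samples of EACH
response group separately (defaults 5x in >= 80%). The comparison uses
the exact fraction (>=), with no rounding of sample counts. The primary
analysis is ER vs NR; partial responders do not enter the filter
denominator unless explicitly included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import MethylationCountMatrix, MethylationRatioMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = ["FilterCriteria", "filter_cpgs", "to_ratios"]


@dataclass(frozen=True)
class FilterCriteria:
    min_coverage: int = 5
    min_fraction_per_group: float = 0.80

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0 < self.min_fraction_per_group <= 1):
            raise ValueError("min_fraction_per_group must be in (0, 1]")


class NoSitesError(ValueError):
    """No CpG sites survive the coverage filter."""


def filter_cpgs(m: MethylationCountMatrix, sheet: SampleSheet,
                criteria: FilterCriteria = FilterCriteria(),
                groups: tuple[str, ...] = ("ER", "NR"),
                ) -> MethylationCountMatrix:
    """Retain sites adequately covered in every group in ``groups``.

    Sample order is unchanged; samples outside ``groups`` are kept as
    columns but do not influence the filter decision.
    """
    labels = sheet.group_labels(m.samples)
    keep = np.ones(m.n_sites, dtype=bool)
    for g in groups:
        cols = labels == g
        if not cols.any():
            raise ValueError(f"no samples of group {g} in the matrix")
        covered = (m.total[:, cols] >= criteria.min_coverage).sum(axis=1)
        frac = covered / cols.sum()
        keep &= frac >= criteria.min_fraction_per_group
    out = m.subset_sites(keep)
    logger.info("coverage filter: %d of %d sites retained", out.n_sites, m.n_sites)
    if out.n_sites == 0:
        raise NoSitesError("no sites survive filtering")
    return out


def to_ratios(m: MethylationCountMatrix) -> MethylationRatioMatrix:
    """meth/total per site and sample; NaN where total == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m.total > 0, m.meth / np.maximum(m.total, 1), np.nan)
    return MethylationRatioMatrix(m.chrom, m.pos, list(m.samples), ratio, m.strand)
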
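"""Differentially methylated region (DMR) calling between responder groups.

The caller implements the printed metilene-style criteria — a DMR must
span at least ``min_cpg`` consecutive CpGs with every adjacent gap below
``max_gap`` bp, built on coverage-filtered data — using a documented,
self-contained procedure:

1. *Pre-segmentation*: maximal runs of consecutive CpGs whose adjacent
   gaps are all < ``max_gap``; runs shorter than ``min_cpg`` are dropped.
2. *Recursive binary segmentation* of the per-CpG group mean-difference
   signal within each run. A run with >= 2*min_cpg CpGs is split at the
   interior index maximizing the absolute difference between the left
   and right mean-difference means, provided the split increases the
   maximum absolute segment mean difference; ties break to the leftmost
   index. Terminal segments with >= min_cpg CpGs become candidates.
3. *Testing*: per-sample region means (over CpGs with data) are compared
   between groups by a two-sided Mann-Whitney U test — exact enumeration
   when both groups have <= 8 samples, otherwise the normal
   approximation with tie correction.
4. *Multiplicity*: Benjamini-Hochberg across all candidate regions
   genome-wide; regions with q below ``fdr_threshold`` are reported.

The sign convention is mean_diff = ER - NR in percentage points, so a
positive difference means hypermethylation in excellent responders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MethylationRatioMatrix, SampleSheet

__all__ = ["DmrParams", "DMR", "presegment", "segment_candidates",
           "test_region", "call_dmrs", "bh_adjust"]


@dataclass(frozen=True)
class DmrParams:
    min_cpg: int = 5
    max_gap: int = 100          # exclusive: adjacent CpG gaps must be < max_gap
    min_depth: int = 5          # enforced upstream by the coverage filter
    fdr_threshold: float = 0.05
    min_mean_diff: float = 0.0  # percentage points

    def __post_init__(self) -> None:
        if self.min_cpg < 1 or self.max_gap < 1 or self.min_depth < 0:
            raise ValueError("DmrParams values must be positive")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")


@dataclass
class DMR:
    """A called region; ``start``/``end`` are the 1-based positions of the
    first and last member CpG. ``mean_diff`` = ER - NR in percentage points."""

    dmr_id: str
    chrom: str
    start: int
    end: int
    cpg_positions: list[int]
    mean_meth_er: float   # region mean methylation, percent
    mean_meth_nr: float
    mean_diff: float      # percentage points, ER - NR
    p: float
    q: float = float("nan")
    location: str | None = None
    gene: str | None = None

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def presegment(chrom: np.ndarray, pos: np.ndarray, params: DmrParams,
               ) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of consecutive CpGs with all adjacent gaps
    < max_gap on one chromosome, keeping runs of >= min_cpg CpGs.
    Sites must be sorted by (chrom, pos)."""
    n = len(pos)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = i + 1
        while (j < n and chrom[j] == chrom[j - 1]
               and pos[j] - pos[j - 1] < params.max_gap):
            j += 1
        if j - i >= params.min_cpg:
            runs.append((i, j))
        i = j
    return runs


def _prefix_means(d: np.ndarray):
    csum = np.concatenate([[0.0], np.cumsum(d)])

    def seg_mean(lo: int, hi: int) -> float:
        return (csum[hi] - csum[lo]) / (hi - lo)

    return seg_mean


def segment_candidates(diff_signal: np.ndarray, params: DmrParams,
                       offset: int = 0) -> list[tuple[int, int]]:
    """Recursively split a run's mean-difference signal; return terminal
    [lo, hi) index intervals (relative to ``offset``) with >= min_cpg CpGs."""
    d = np.asarray(diff_signal, dtype=float)
    seg_mean = _prefix_means(d)
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n >= 2 * params.min_cpg:
            whole = abs(seg_mean(lo, hi))
            best_s, best_score, best_max = -1, -np.inf, whole
            for s in range(lo + 1, hi):
                left, right = seg_mean(lo, s), seg_mean(s, hi)
                score = abs(left - right)
                if score > best_score + 1e-15:
                    best_s, best_score = s, score
                    best_max = max(abs(left), abs(right))
            if best_s >= 0 and best_max > whole + 1e-12:
                recurse(lo, best_s)
                recurse(best_s, hi)
                return
        if n >= params.min_cpg:
            out.append((offset + lo, offset + hi))

    recurse(0, len(d))
    return out


def test_region(ratio_block: np.ndarray, is_er: np.ndarray,
                ) -> tuple[float, float, float, float]:
    """Test one candidate region.

    ``ratio_block`` is (n_cpgs, n_samples) with NaN for missing;
    ``is_er`` marks ER columns (the rest are NR). Returns
    (mean_meth_er %, mean_meth_nr %, mean_diff pp, two-sided MWU p)
    computed on per-sample region means. Samples with no covered CpG in
    the region are dropped with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        sample_means = np.nanmean(ratio_block, axis=0)
    ok = ~np.isnan(sample_means)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} sample(s) with no covered CpG dropped "
                      "from region test", stacklevel=2)
    er = sample_means[ok & is_er]
    nr = sample_means[ok & ~is_er]
    if len(er) == 0 or len(nr) == 0:
        raise ValueError("a group is empty after dropping uncovered samples")
    mean_er = float(np.mean(er)) * 100.0
    mean_nr = float(np.mean(nr)) * 100.0
    if np.ptp(np.concatenate([er, nr])) == 0:
        return mean_er, mean_nr, 0.0, 1.0  # all values tied
    method = "exact" if max(len(er), len(nr)) <= 8 and _no_ties(er, nr) else "asymptotic"
    res = stats.mannwhitneyu(er, nr, alternative="two-sided", method=method)
    return mean_er, mean_nr, mean_er - mean_nr, float(res.pvalue)


def _no_ties(a: np.ndarray, b: np.ndarray) -> bool:
    v = np.concatenate([a, b])
    return len(np.unique(v)) == len(v)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def call_dmrs(ratios: MethylationRatioMatrix, sheet: SampleSheet,
              params: DmrParams = DmrParams(),
              keep_all_candidates: bool = False) -> list[DMR]:
    """Run the full caller: presegment, segment, test, BH-adjust.

    Only ER and NR samples participate. Returns DMRs with q <
    ``fdr_threshold`` and |mean_diff| >= ``min_mean_diff``, sorted by
    (chrom, start); with ``keep_all_candidates`` every tested candidate
    is returned (q still filled in), which is useful for calibration
    studies.
    """
    labels = sheet.group_labels(ratios.samples)
    use = np.isin(labels, ("ER", "NR"))
    sub = ratios.subset_samples([s for s, u in zip(ratios.samples, use) if u])
    is_er = sheet.group_labels(sub.samples) == "ER"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        er_mean = np.nanmean(sub.ratio[:, is_er], axis=1)
        nr_mean = np.nanmean(sub.ratio[:, ~is_er], axis=1)
    diff = er_mean - nr_mean
    diff = np.nan_to_num(diff, nan=0.0)

    candidates: list[tuple[int, int]] = []
    for lo, hi in presegment(sub.chrom, sub.pos, params):
        candidates.extend(segment_candidates(diff[lo:hi], params, offset=lo))

    records = []
    for lo, hi in candidates:
        m_er, m_nr, mdiff, p = test_region(sub.ratio[lo:hi], is_er)
        records.append((lo, hi, m_er, m_nr, mdiff, p))

    qvals = bh_adjust(np.array([r[5] for r in records]))
    dmrs: list[DMR] = []
    for (lo, hi, m_er, m_nr, mdiff, p), q in zip(records, qvals):
        if not keep_all_candidates:
            if q >= params.fdr_threshold or abs(mdiff) < params.min_mean_diff:
                continue
        dmrs.append(DMR(
            dmr_id="", chrom=str(sub.chrom[lo]),
            start=int(sub.pos[lo]), end=int(sub.pos[hi - 1]),
            cpg_positions=[int(x) for x in sub.pos[lo:hi]],
            mean_meth_er=m_er, mean_meth_nr=m_nr, mean_diff=mdiff,
            p=p, q=float(q)))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    for i, d in enumerate(dmrs, start=1):
        d.dmr_id = f"DMR{i:05d}"
    return dmrs
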
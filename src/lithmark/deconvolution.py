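"""Reference-based blood cell-type deconvolution.

Each sample's methylation ratios at cell-type marker CpGs are projected
onto a reference methylome matrix (one column per cell type, e.g. CD4T,
CD8T, B, NK, Mono, Gran) by non-negative least squares:

    min over beta >= 0 of || y - P beta ||^2

Estimated mixing coefficients are reported as-is (row sums are *not*
forced to one, matching constrained-projection practice); a normalized
view is provided for interpretation. Group differences per cell type
are assessed by Welch's two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .io import MethylationRatioMatrix, SampleSheet

__all__ = ["CellTypeReference", "CellProportions", "match_markers",
           "project_cell_types", "deconvolve_cohort", "compare_groups"]

DEFAULT_CELL_TYPES = ["CD4T", "CD8T", "B", "NK", "Mono", "Gran"]


@dataclass
class CellTypeReference:
    """Reference methylome at marker CpGs: (n_markers, n_types) in [0, 1]."""

    chrom: np.ndarray
    pos: np.ndarray
    cell_types: list[str]
    profile: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.profile = np.asarray(self.profile, dtype=float)
        if len(self.cell_types) < 2:
            raise ValueError("need at least two cell types")
        if self.profile.shape != (len(self.pos), len(self.cell_types)):
            raise ValueError("profile dimensions inconsistent")
        if np.nanmin(self.profile) < 0 or np.nanmax(self.profile) > 1:
            raise ValueError("profile must lie in [0, 1]")

    @property
    def n_markers(self) -> int:
        return len(self.pos)


@dataclass
class CellProportions:
    samples: list[str]
    cell_types: list[str]
    prop: np.ndarray  # (n_samples, n_types), >= 0, row sums unconstrained

    def normalized(self) -> np.ndarray:
        s = self.prop.sum(axis=1, keepdims=True)
        return np.divide(self.prop, s, out=np.zeros_like(self.prop), where=s > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prop, index=self.samples, columns=self.cell_types)


class InsufficientMarkerOverlap(ValueError):
    pass


def match_markers(ratios: MethylationRatioMatrix, ref: CellTypeReference,
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """Intersect data sites with reference markers by (chrom, pos).

    Returns (Y, P, n_overlap): Y is (n_overlap, n_samples) sample ratios
    and P the aligned (n_overlap, n_types) reference profile. Refuses to
    proceed when fewer than 2x the number of cell types overlap.
    """
    data_idx = {(c, int(p)): i for i, (c, p) in enumerate(zip(ratios.chrom, ratios.pos))}
    di, ri = [], []
    for j, (c, p) in enumerate(zip(ref.chrom, ref.pos)):
        i = data_idx.get((c, int(p)))
        if i is not None:
            di.append(i)
            ri.append(j)
    n_overlap = len(di)
    if n_overlap < 2 * len(ref.cell_types):
        raise InsufficientMarkerOverlap(
            f"insufficient marker overlap: {n_overlap} < "
            f"{2 * len(ref.cell_types)} (2x number of cell types)")
    return ratios.ratio[di], ref.profile[ri], n_overlap


def project_cell_types(y: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Non-negative least-squares projection of one sample's marker
    ratios onto the reference profile; missing markers dropped pairwise."""
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    if not ok.any():
        raise ValueError("sample has no observed marker CpGs")
    beta, _ = nnls(profile[ok], y[ok])
    return beta


def deconvolve_cohort(ratios: MethylationRatioMatrix, ref: CellTypeReference,
                      ) -> CellProportions:
    Y, P, _ = match_markers(ratios, ref)
    props = np.vstack([project_cell_types(Y[:, j], P)
                       for j in range(Y.shape[1])])
    return CellProportions(list(ratios.samples), list(ref.cell_types), props)


def compare_groups(props: CellProportions, sheet: SampleSheet) -> pd.DataFrame:
    """Welch two-sample t-test per cell type, ER vs NR.

    Returns a table (cell_type, mean_ER, mean_NR, t, df, p); degenerate
    zero-variance-in-both-groups cases get t = 0, p = 1 with a note.
    """
    labels = sheet.group_labels(props.samples)
    er = props.prop[labels == "ER"]
    nr = props.prop[labels == "NR"]
    if len(er) < 2 or len(nr) < 2:
        raise ValueError("both groups need >= 2 samples")
    rows = []
    for j, t_name in enumerate(props.cell_types):
        a, b = er[:, j], nr[:, j]
        note = ""
        if np.var(a) == 0 and np.var(b) == 0:
            t_stat, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
            note = "zero variance in both groups"
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append({"cell_type": t_name, "mean_ER": float(np.mean(a)),
                     "mean_NR": float(np.mean(b)), "t": t_stat, "df": df,
                     "p": p, "note": note})
    return pd.DataFrame(rows)
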
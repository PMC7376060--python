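"""DMR annotation, partial-responder post-hoc analysis, and cohort
description statistics.

Location classes follow promoter-annotation conventions: a DMR midpoint
within -1000..+100 bp of a TSS (strand-aware) is Promoter-TSS, within
+/-1000 bp of a TTS is TTS, then exonic, then intronic, otherwise
Intergenic — evaluated in that precedence order. The windows are
configurable; the midpoint rule keeps classification deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, SampleSheet

__all__ = ["LOCATION_CLASSES", "classify_location", "annotate_dmrs",
           "partial_responder_anova", "cohort_table", "location_fractions"]

LOCATION_CLASSES = ["Promoter-TSS", "TTS", "Exon", "Intron", "Intergenic"]


def _signed_tss_offset(mid: int, g: GeneModel) -> int:
    """Offset of ``mid`` from the TSS in transcription direction
    (negative = upstream)."""
    return (mid - g.tss) if g.strand == "+" else (g.tss - mid)


def classify_location(dmr, genes: list[GeneModel],
                      promoter_upstream: int = 1000,
                      promoter_downstream: int = 100,
                      tts_window: int = 1000,
                      ) -> tuple[str, str | None]:
    """Assign one location class and (for non-intergenic DMRs) the
    nearest qualifying gene's name. Classification uses the DMR
    midpoint; precedence Promoter-TSS > TTS > Exon > Intron."""
    mid = (dmr.start + dmr.end) // 2
    hits: dict[str, list[tuple[int, GeneModel]]] = {c: [] for c in LOCATION_CLASSES[:4]}
    for g in genes:
        if g.chrom != dmr.chrom:
            continue
        off = _signed_tss_offset(mid, g)
        if -promoter_upstream <= off <= promoter_downstream:
            hits["Promoter-TSS"].append((abs(off), g))
        if abs(mid - g.tts) <= tts_window:
            hits["TTS"].append((abs(mid - g.tts), g))
        if g.start <= mid <= g.end:
            if any(a <= mid <= b for a, b in g.exons):
                hits["Exon"].append((abs(off), g))
            else:
                hits["Intron"].append((abs(off), g))
    for cls in LOCATION_CLASSES[:4]:
        if hits[cls]:
            dist, gene = min(hits[cls], key=lambda t: (t[0], t[1].gene_id))
            return cls, gene.gene_name
    return "Intergenic", None


def annotate_dmrs(dmrs, genes: list[GeneModel], **windows) -> None:
    """Fill ``location``/``gene`` in place on each DMR."""
    for d in dmrs:
        d.location, d.gene = classify_location(d, genes, **windows)


def location_fractions(dmrs) -> pd.Series:
    """Fraction of DMRs per location class (sums to 1)."""
    counts = pd.Series([d.location for d in dmrs]).value_counts()
    return counts.reindex(LOCATION_CLASSES, fill_value=0) / len(list(dmrs))


# ---------------------------------------------------------------------------
# Partial-responder post-hoc


def _box_stats(v: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(lo), "whisker_high": float(hi)}


def partial_responder_anova(features: pd.DataFrame, sheet: SampleSheet,
                            signature_dmrs: list[str],
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA of each signature DMR's methylation across
    ER/PR/NR, plus boxplot summaries per group.

    Returns (anova_table, boxplot_table)."""
    labels = sheet.group_labels(features.index)
    groups = {}
    for g in ("ER", "PR", "NR"):
        idx = labels == g
        if idx.sum() < 2:
            raise ValueError(f"group {g} has < 2 samples")
        groups[g] = idx
    anova_rows, box_rows = [], []
    for dmr_id in signature_dmrs:
        vals = {g: features.loc[m, dmr_id].to_numpy(dtype=float)
                for g, m in groups.items()}
        if np.ptp(np.concatenate(list(vals.values()))) == 0:
            f_stat, p = 0.0, 1.0
        else:
            res = stats.f_oneway(vals["ER"], vals["PR"], vals["NR"])
            f_stat, p = float(res.statistic), float(res.pvalue)
            if np.isnan(f_stat):  # all values identical
                f_stat, p = 0.0, 1.0
        anova_rows.append({"dmr_id": dmr_id, "F": f_stat, "p": p})
        for g in ("ER", "PR", "NR"):
            box_rows.append({"dmr_id": dmr_id, "group": g,
                             "n": int(len(vals[g])), **_box_stats(vals[g])})
    return pd.DataFrame(anova_rows), pd.DataFrame(box_rows)


# ---------------------------------------------------------------------------
# Cohort description statistics


@dataclass
class CohortTestResult:
    variable: str
    test: str
    statistic: float
    p: float
    detail: str = ""


def _fisher_one_sided(er_yes: int, er_no: int, nr_yes: int, nr_no: int,
                      ) -> tuple[float, str]:
    """One-sided Fisher exact p in the direction of the observed
    enrichment (toward the group with the higher rate)."""
    er_rate = er_yes / max(er_yes + er_no, 1)
    nr_rate = nr_yes / max(nr_yes + nr_no, 1)
    alt = "greater" if er_rate >= nr_rate else "less"
    p = stats.fisher_exact([[er_yes, er_no], [nr_yes, nr_no]],
                           alternative=alt).pvalue
    return float(p), f"toward {'ER' if alt == 'greater' else 'NR'}"


def cohort_table(sheet: SampleSheet) -> pd.DataFrame:
    """Between-group (ER vs NR) tests for every cohort variable.

    Continuous variables get Mann-Whitney and Welch t; binary variables
    get a one-sided Fisher exact (observed-enrichment direction) and a
    Pearson chi-square without continuity correction; the psychotropic
    drug count gets a chi-square over the 1/2/>=3 table.
    """
    df = sheet.df
    er = df[df["group"] == "ER"]
    nr = df[df["group"] == "NR"]
    if len(er) == 0 or len(nr) == 0:
        raise ValueError("both ER and NR samples are required")
    out: list[CohortTestResult] = []

    for var in ("age", "bmi"):
        a, b = er[var].to_numpy(float), nr[var].to_numpy(float)
        mwu = stats.mannwhitneyu(a, b, alternative="two-sided")
        out.append(CohortTestResult(var, "mann-whitney", float(mwu.statistic),
                                    float(mwu.pvalue)))
        t = stats.ttest_ind(a, b, equal_var=False)
        out.append(CohortTestResult(var, "welch-t", float(t.statistic),
                                    float(t.pvalue)))

    binaries = [("sex", lambda s: s["sex"] == "M"),
                ("smoker", lambda s: s["smoker"]),
                ("current_li", lambda s: s["current_li"]),
                ("med_anticonvulsant", lambda s: s["med_anticonvulsant"]),
                ("med_atypical", lambda s: s["med_atypical"]),
                ("med_antidepressant", lambda s: s["med_antidepressant"])]
    for var, f in binaries:
        ey, en = int(f(er).sum()), int((~f(er)).sum())
        ny, nn = int(f(nr).sum()), int((~f(nr)).sum())
        p_f, direction = _fisher_one_sided(ey, en, ny, nn)
        out.append(CohortTestResult(var, "fisher-one-sided", float("nan"), p_f,
                                    f"{ey}/{en} vs {ny}/{nn}, {direction}"))
        tab = np.array([[ey, en], [ny, nn]])
        if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
            chi = stats.chi2_contingency(tab, correction=False)
            out.append(CohortTestResult(var, "chi-square",
                                        float(chi.statistic), float(chi.pvalue),
                                        f"{ey}/{en} vs {ny}/{nn}"))

    np_er = np.minimum(er["n_psychotropics"].to_numpy(int), 3)
    np_nr = np.minimum(nr["n_psychotropics"].to_numpy(int), 3)
    cats = sorted(set(np_er) | set(np_nr))
    tab = np.array([[(np_er == c).sum() for c in cats],
                    [(np_nr == c).sum() for c in cats]])
    keep = tab.sum(axis=0) > 0
    tab = tab[:, keep]
    if tab.shape[1] >= 2:
        chi = stats.chi2_contingency(tab, correction=False)
        out.append(CohortTestResult("n_psychotropics", "chi-square",
                                    float(chi.statistic), float(chi.pvalue),
                                    f"categories {list(np.array(cats)[keep])}"))
    return pd.DataFrame([r.__dict__ for r in out])
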
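"""Synthetic cohort generator.

Emulates the statistical structure of a targeted bisulfite-sequencing
study of lithium response in bipolar disorder type 1: 15 excellent
responders (ER) vs 11 non-responders (NR) plus 14 partial responders
(PR); CpGs arranged in dense clusters (adjacent gaps well below the
100 bp DMR chaining threshold); beta-binomial read counts at negative-
binomially distributed depth; per-sample expected methylation formed as
a cell-type mixture of reference profiles; planted DMRs shifting the
ER-vs-NR expectation by a configurable effect in percentage points
(PR intermediate at half the effect); and psychotropic comedications
drawn with group-dependent log-odds so that non-responders are enriched
for atypical antipsychotics and excellent responders for current
lithium, mirroring the real cohort's confounding pattern.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolution import CellTypeReference, DEFAULT_CELL_TYPES
from .io import MethylationCountMatrix, SampleSheet

__all__ = ["SimulationConfig", "GroundTruth", "generate_cohort",
           "generate_reference", "generate_feature_matrix",
           "simulate_screen_cohort", "SIGNATURE_EFFECTS_PP"]

# Signature-scale effects (percentage points, ER - NR) used by the
# feature-level recovery experiments: seven region effects spanning
# roughly -12 to +16 pp with one deliberately weak member.
SIGNATURE_EFFECTS_PP = [15.99, -9.89, 16.25, 12.49, 11.66, -12.2, -3.48]

# Single-region discriminative AUCs on the same scale. Together with the
# effects these imply per-region standardized separations
# d = sqrt(2) * Phi^-1(AUC) of ~1.1-1.8 and hence per-region
# between-subject SDs sigma = |effect| / d of ~3-10 pp — region noise is
# heterogeneous, and the weak-effect region is also the quietest.
SIGNATURE_REGION_AUCS = [0.891, 0.897, 0.879, 0.855, 0.842, 0.842, 0.788]

# Group-dependent prescription log-odds (base = ER; nr_delta added for NR,
# half of it for PR). Defaults reproduce the real cohort's direction:
# atypical antipsychotics and anticonvulsants NR-enriched, current
# lithium strongly ER-enriched.
MED_GROUP_LOGODDS = {
    "med_atypical": (-2.2, 2.6),
    "med_antidepressant": (-1.4, 0.8),
    "med_anticonvulsant": (-1.4, 1.2),
    "current_li": (2.6, -3.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_er: int = 15
    n_nr: int = 11
    n_pr: int = 14
    n_clusters: int = 200
    cluster_size_range: tuple[int, int] = (5, 15)
    intra_cluster_gap_range: tuple[int, int] = (5, 80)
    n_dmr: int = 20
    effect_range: tuple[float, float] = (3.0, 16.0)  # |effect| in pp
    effect_sign: str = "random"                      # random | positive | negative
    depth_mean: float = 30.0
    depth_shape: float = 8.0                         # negative-binomial size
    dispersion: float = 0.05                         # beta-binomial rho in (0,1)
    confounding: float = 1.0                         # scales med-group log-odds
    n_celltypes: int = 6
    celltype_concentration: float = 60.0
    n_marker_cpgs: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_er, self.n_nr) < 2 or self.n_pr < 0:
            raise ValueError("cohort sizes must be positive")
        if not (0 < self.dispersion < 1):
            raise ValueError("dispersion must be in (0, 1)")
        if self.effect_range[1] > 100 or self.effect_range[0] < 0:
            raise ValueError("effect magnitudes must lie in [0, 100] pp")
        if self.n_dmr > self.n_clusters:
            raise ValueError("cannot plant more DMRs than clusters")
        if self.effect_sign not in ("random", "positive", "negative"):
            raise ValueError("effect_sign must be random|positive|negative")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    planted_dmrs: list[dict]                 # chrom/start/end/effect_pp
    cluster_intervals: list[dict]            # chrom/start/end per cluster
    true_props: pd.DataFrame                 # samples x cell types
    med_logodds: dict[str, tuple[float, float]]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "planted_dmrs": self.planted_dmrs,
            "cluster_intervals": self.cluster_intervals,
            "true_props": self.true_props.to_dict(orient="index"),
            "med_logodds": {k: list(v) for k, v in self.med_logodds.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_reference(n_celltypes: int = 6, n_marker_cpgs: int = 600,
                       seed: int = 0, chrom: str = "chrR",
                       ) -> CellTypeReference:
    """Cell-type reference methylome at marker CpGs with high
    between-type contrast (column spread >= 0.5 at every marker)."""
    if n_celltypes < 2:
        raise ValueError("need >= 2 cell types")
    rng = np.random.default_rng(seed)
    names = (DEFAULT_CELL_TYPES[:n_celltypes]
             if n_celltypes <= len(DEFAULT_CELL_TYPES)
             else [f"CT{i + 1}" for i in range(n_celltypes)])
    pos = 1000 * (np.arange(n_marker_cpgs) + 1)
    profile = rng.uniform(0.05, 0.25, size=(n_marker_cpgs, n_celltypes))
    target = np.arange(n_marker_cpgs) % n_celltypes  # each marker tags one type
    profile[np.arange(n_marker_cpgs), target] = rng.uniform(0.78, 0.95, n_marker_cpgs)
    return CellTypeReference(np.full(n_marker_cpgs, chrom, dtype=object),
                             pos, names, profile)


def _draw_counts(rng: np.random.Generator, p_exp: np.ndarray,
                 depth: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial counts with mean p_exp and overdispersion rho."""
    p = np.clip(p_exp, 1e-6, 1 - 1e-6)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    probs = rng.beta(a, b)
    return rng.binomial(depth, probs)


def generate_cohort(cfg: SimulationConfig,
                    ) -> tuple[MethylationCountMatrix, SampleSheet,
                               CellTypeReference, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)

    # --- samples and sheet -------------------------------------------------
    ids = ([f"ER{i + 1:02d}" for i in range(cfg.n_er)]
           + [f"NR{i + 1:02d}" for i in range(cfg.n_nr)]
           + [f"PR{i + 1:02d}" for i in range(cfg.n_pr)])
    groups = ["ER"] * cfg.n_er + ["NR"] * cfg.n_nr + ["PR"] * cfg.n_pr
    n = len(ids)
    group_arr = np.array(groups)
    nr_ind = (group_arr == "NR").astype(float) + 0.5 * (group_arr == "PR")

    sheet_cols: dict[str, object] = {
        "sample_id": ids,
        "group": groups,
        "sex": rng.choice(["M", "F"], size=n),
        "age": np.round(rng.normal(48.0, 10.0, size=n), 1),
        "bmi": np.round(rng.normal(25.0, 3.2, size=n), 1),
        "smoker": rng.random(n) < 0.45,
    }
    for med, (base, nr_delta) in MED_GROUP_LOGODDS.items():
        pvec = _sigmoid(base + cfg.confounding * nr_delta * nr_ind)
        sheet_cols[med] = rng.random(n) < pvec
    p_extra = _sigmoid(-1.1 + cfg.confounding * 1.3 * nr_ind)
    sheet_cols["n_psychotropics"] = 1 + rng.binomial(2, p_extra)
    alda = np.concatenate([rng.integers(7, 11, cfg.n_er),
                           rng.integers(0, 4, cfg.n_nr),
                           rng.integers(4, 7, cfg.n_pr)])
    sheet_cols["alda_total"] = alda
    sheet = SampleSheet(pd.DataFrame(sheet_cols))

    # --- cell-type mixtures ------------------------------------------------
    ref = generate_reference(cfg.n_celltypes, cfg.n_marker_cpgs,
                             seed=int(rng.integers(2**31)))
    if cfg.n_celltypes == 6:
        base_props = np.array([0.15, 0.08, 0.05, 0.05, 0.07, 0.60])
    else:
        base_props = np.full(cfg.n_celltypes, 1.0 / cfg.n_celltypes)
    alpha = base_props * cfg.celltype_concentration
    props = rng.dirichlet(alpha, size=n)          # (n_samples, n_types)

    # --- cluster layout on chr1 -------------------------------------------
    sizes = rng.integers(cfg.cluster_size_range[0],
                         cfg.cluster_size_range[1] + 1, cfg.n_clusters)
    cluster_pos: list[np.ndarray] = []
    cursor = 10_000
    for s in sizes:
        gaps = rng.integers(cfg.intra_cluster_gap_range[0],
                            cfg.intra_cluster_gap_range[1] + 1, s - 1)
        p = cursor + np.concatenate([[0], np.cumsum(gaps)])
        cluster_pos.append(p)
        cursor = int(p[-1]) + 10_000  # inter-cluster gap >> max_gap
    pos1 = np.concatenate(cluster_pos)
    n_sites1 = len(pos1)

    # Per-CpG baseline (cluster-level, bimodal) + per-cell-type wiggle.
    cl_base = np.clip(rng.beta(0.4, 0.4, cfg.n_clusters), 0.05, 0.95)
    base_site = np.concatenate([
        np.clip(b + rng.normal(0, 0.03, s), 0.02, 0.98)
        for b, s in zip(cl_base, sizes)])
    type_dev = rng.normal(0, 0.02, size=(n_sites1, cfg.n_celltypes))
    profile1 = np.clip(base_site[:, None] + type_dev, 0.0, 1.0)

    # --- plant DMRs --------------------------------------------------------
    # The shift is split symmetrically (ER +e/2, NR -e/2, PR at the
    # midpoint), and only clusters with intermediate baseline
    # methylation are eligible, so a 3-16 pp difference is always
    # representable without clipping — DMRs live at partially
    # methylated regions, not at fully (un)methylated ones.
    effect_site = np.zeros(n_sites1)
    planted: list[dict] = []
    max_eff = cfg.effect_range[1] / 100.0
    eligible = np.flatnonzero((cl_base >= 0.05 + max_eff / 2 + 0.04)
                              & (cl_base <= 0.95 - max_eff / 2 - 0.04))
    if len(eligible) < cfg.n_dmr:
        raise ValueError("not enough intermediate-methylation clusters to "
                         "plant the requested DMRs")
    dmr_clusters = rng.choice(eligible, size=cfg.n_dmr, replace=False)
    starts = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    for ci in sorted(int(c) for c in dmr_clusters):
        size = int(sizes[ci])
        length = int(rng.integers(min(5, size), size + 1))
        off = int(rng.integers(0, size - length + 1))
        mag = rng.uniform(*cfg.effect_range)
        sign = {"positive": 1.0, "negative": -1.0}.get(
            cfg.effect_sign, float(rng.choice([-1.0, 1.0])))
        idx = slice(starts[ci] + off, starts[ci] + off + length)
        effect_site[idx] = sign * mag
        planted.append({"chrom": "chr1",
                        "start": int(cluster_pos[ci][off]),
                        "end": int(cluster_pos[ci][off + length - 1]),
                        "n_cpgs": length,
                        "effect_pp": float(sign * mag)})

    # --- expected methylation and counts ----------------------------------
    mix1 = props @ profile1.T                     # (n_samples, n_sites1)
    shift = np.outer(np.where(group_arr == "ER", 0.5,
                              np.where(group_arr == "PR", 0.0, -0.5)),
                     effect_site / 100.0)
    exp1 = mix1 + shift
    if np.any((exp1 < 0) | (exp1 > 1)):
        warnings.warn("planted effect pushed expected methylation outside "
                      "[0, 1]; clipped", stacklevel=2)
        exp1 = np.clip(exp1, 0.0, 1.0)
    mixR = props @ ref.profile.T                  # marker sites

    p_nb = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
    exp_all = np.hstack([exp1, mixR]).T           # (n_sites, n_samples)
    depth = rng.negative_binomial(cfg.depth_shape, p_nb, size=exp_all.shape)
    meth = _draw_counts(rng, exp_all, depth, cfg.dispersion)

    chrom = np.concatenate([np.full(n_sites1, "chr1", dtype=object),
                            np.asarray(ref.chrom, dtype=object)])
    pos = np.concatenate([pos1, ref.pos])
    order = np.lexsort((pos, chrom.astype(str)))
    m = MethylationCountMatrix(chrom[order], pos[order], ids,
                               meth[order], depth[order])

    truth = GroundTruth(
        planted_dmrs=planted,
        cluster_intervals=[{"chrom": "chr1", "start": int(p[0]), "end": int(p[-1])}
                           for p in cluster_pos],
        true_props=pd.DataFrame(props, index=ids, columns=ref.cell_types),
        med_logodds=dict(MED_GROUP_LOGODDS))
    return m, sheet, ref, truth


# ---------------------------------------------------------------------------
# Feature-level simulators for the screening and signature stages


def implied_region_sds(effects: list[float] = SIGNATURE_EFFECTS_PP,
                       aucs: list[float] = SIGNATURE_REGION_AUCS) -> np.ndarray:
    """Per-region between-subject SDs implied by (effect, single-region
    AUC) pairs under a normal model: sigma = |effect| / (sqrt2 * z(AUC))."""
    from scipy.stats import norm

    d = np.sqrt(2.0) * norm.ppf(np.asarray(aucs, dtype=float))
    return np.abs(np.asarray(effects, dtype=float)) / d


def generate_feature_matrix(n_er: int = 15, n_nr: int = 11,
                            n_features: int = 66,
                            planted_effects: list[float] = SIGNATURE_EFFECTS_PP,
                            planted_sds: list[float] | None = None,
                            null_sd_range: tuple[float, float] = (4.0, 10.0),
                            shared_rho: float = 0.6,
                            baseline_range: tuple[float, float] = (20.0, 80.0),
                            seed: int = 0,
                            ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Region-level methylation features (percent) for signature tests.

    The first ``len(planted_effects)`` features carry the given ER-NR
    mean differences (pp); the rest are null. Returns (X, y, planted_ids)
    with y = +1 for ER, -1 for NR.

    Two empirically grounded structural choices:

    * *Heterogeneous region noise.* Each planted region's SD defaults to
      the value its (effect, single-region AUC) pair implies
      (:func:`implied_region_sds`, ~3-10 pp); null regions draw SDs from
      ``null_sd_range``.
    * *Signal-aligned shared variation.* A per-subject latent factor
      enters every region with correlation ``shared_rho``, aligned with
      each planted region's effect sign (random sign for nulls). This
      reflects that co-selected regions covary within subjects (shared
      cell-composition and treatment biology), so combining regions
      improves discrimination only gradually — the honest
      cross-validated AUC of a multi-region panel stays well below 1
      even when single regions look strong, exactly the pattern
      small-cohort methylation classifiers show.
    """
    rng = np.random.default_rng(seed)
    n = n_er + n_nr
    n_planted = len(planted_effects)
    if planted_sds is None:
        planted_sds = implied_region_sds(planted_effects) if n_planted else []
    if not (0 <= shared_rho < 1):
        raise ValueError("shared_rho must be in [0, 1)")
    y = np.concatenate([np.ones(n_er), -np.ones(n_nr)])
    base = rng.uniform(*baseline_range, size=n_features)
    sds = np.concatenate([
        np.asarray(planted_sds, dtype=float),
        rng.uniform(*null_sd_range, size=n_features - n_planted)])
    signs = np.concatenate([
        np.sign(planted_effects) if n_planted else [],
        rng.choice([-1.0, 1.0], size=n_features - n_planted)])
    u = rng.normal(0.0, 1.0, size=n)                   # per-subject factor
    eps = rng.normal(0.0, 1.0, size=(n, n_features))
    noise = sds[None, :] * (shared_rho * np.outer(u, signs)
                            + np.sqrt(1 - shared_rho**2) * eps)
    X = base[None, :] + noise
    for j, eff in enumerate(planted_effects):
        X[:n_er, j] += eff
    ids = [f"DMR{j + 1:03d}" for j in range(n_features)]
    planted = ids[:len(planted_effects)]
    return pd.DataFrame(X, columns=ids,
                        index=[f"ER{i+1:02d}" for i in range(n_er)]
                        + [f"NR{i+1:02d}" for i in range(n_nr)]), y, planted


def simulate_screen_cohort(n_er: int = 15, n_nr: int = 11,
                           n_features: int = 100,
                           scenario: str = "clean",
                           outcome_effect: float = 5.0,
                           med_effect: float = 25.0,
                           med_group_logodds: float = 6.0,
                           noise_sd: float | None = None,
                           seed: int = 0,
                           ) -> tuple[pd.DataFrame, SampleSheet]:
    """Cohort for confounder-screen calibration.

    ``scenario='clean'``: features carry a moderate direct outcome
    effect (default 5 pp against 6 pp noise, a per-SD odds ratio a
    screen at p < 0.1 would typically surface); all medications are
    drawn independently of both outcome and features, so the
    crude-vs-adjusted exclusion rule should almost never fire.

    ``scenario='confounded'``: a medication is strongly associated with
    the outcome, and features are functions of that medication *only*
    (no direct outcome effect) — the classic confounding triangle the
    rule is designed to catch. Strong confounding here means the
    medication splits the groups almost deterministically and drives
    the feature with little residual noise (default 4 pp).
    """
    if scenario not in ("clean", "confounded"):
        raise ValueError("scenario must be 'clean' or 'confounded'")
    if noise_sd is None:
        noise_sd = 6.0 if scenario == "clean" else 4.0
    rng = np.random.default_rng(seed)
    n = n_er + n_nr
    ids = [f"ER{i+1:02d}" for i in range(n_er)] + [f"NR{i+1:02d}" for i in range(n_nr)]
    groups = ["ER"] * n_er + ["NR"] * n_nr
    is_nr = np.array([g == "NR" for g in groups], dtype=float)

    meds = {}
    for med in ("med_atypical", "med_antidepressant", "med_anticonvulsant",
                "current_li"):
        if scenario == "confounded" and med == "med_atypical":
            # mirrors the atypical-antipsychotic pattern (ER ~0/15, NR ~7/11)
            meds[med] = rng.random(n) < _sigmoid(-2.5 + med_group_logodds * is_nr)
        else:
            meds[med] = rng.random(n) < 0.35
    n_psy = 1 + rng.binomial(2, 0.4, size=n)

    base = rng.uniform(20.0, 80.0, size=n_features)
    X = base[None, :] + rng.normal(0.0, noise_sd, size=(n, n_features))
    if scenario == "clean":
        X += np.outer(1.0 - is_nr, np.full(n_features, outcome_effect))
    else:
        X += np.outer(meds["med_atypical"].astype(float),
                      np.full(n_features, med_effect))

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": ids, "group": groups,
        "sex": rng.choice(["M", "F"], size=n),
        "age": np.round(rng.normal(48, 10, n), 1),
        "bmi": np.round(rng.normal(25, 3, n), 1),
        "smoker": rng.random(n) < 0.45,
        "med_atypical": meds["med_atypical"],
        "med_antidepressant": meds["med_antidepressant"],
        "med_anticonvulsant": meds["med_anticonvulsant"],
        "n_psychotropics": n_psy,
        "current_li": meds["current_li"],
    }))
    cols = [f"DMR{j + 1:03d}" for j in range(n_features)]
    return pd.DataFrame(X, columns=cols, index=ids), sheet
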
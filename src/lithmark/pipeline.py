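"""End-to-end orchestration of the signature-discovery flow:

coverage filter -> DMR calling -> cell-type check -> confounder screen
-> sPLS-DA signature -> annotation and post-hoc analyses.

Each stage writes its outputs under a run directory and is resumable:
with ``resume=True`` a stage whose outputs already exist is skipped and
its products are read back from disk, so deleting one stage's files and
re-running recomputes only that stage and its dependents. A manifest
records the config hash, seed, per-stage record counts (the
discovery-funnel bookkeeping: candidates -> screen-positive ->
retained -> signature size) and a content hash over all outputs.

The single configured seed fans out to per-stage seeds by stable
hashing of the stage name, so resuming never shifts random streams.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .annotate import annotate_dmrs, cohort_table, partial_responder_anova
from .deconvolution import compare_groups, deconvolve_cohort
from .dmr import DmrParams, call_dmrs
from .filtering import FilterCriteria, filter_cpgs, to_ratios
from .screen import (DEFAULT_COVARIATES, confounder_exclusion,
                     dmr_feature_matrix, screen_table, univariate_screen)
from .signature import loocv_scores, roc_curve, stepwise_signature

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline",
           "stage_seed"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    coverage_files: list[str]
    sample_sheet: str
    out_dir: str
    sample_ids: list[str] | None = None
    celltype_reference: str | None = None
    gene_models: str | None = None
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    dmr_params: DmrParams = field(default_factory=DmrParams)
    screen_alpha: float = 0.1
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    max_k: int = 10
    bootstrap: int = 1000
    seed: int = 0
    cv_mode: str = "fixed"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "filter_criteria" in raw:
            raw["filter_criteria"] = FilterCriteria(**raw["filter_criteria"])
        if "dmr_params" in raw:
            raw["dmr_params"] = DmrParams(**raw["dmr_params"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of the stage name."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


def _outputs_exist(out_dir: Path, names: list[str]) -> bool:
    return all((out_dir / n).exists() for n in names)


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Run (or resume) the full pipeline; returns the manifest dict.

    The manifest is also written to ``<out_dir>/manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = lio.read_sample_sheet(cfg.sample_sheet)
    manifest: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                      "stages": {}, "counts": {}}
    executed: list[str] = []

    def record(stage: str, outputs: list[str], ran: bool, **counts) -> None:
        manifest["stages"][stage] = {"outputs": outputs, "executed": ran}
        manifest["counts"].update(counts)
        if ran:
            executed.append(stage)

    # ---- filter -----------------------------------------------------------
    stage, outs = "filter", ["ratios.tsv"]
    try:
        if resume and _outputs_exist(out, outs):
            ratios = lio.read_ratio_table(out / "ratios.tsv")
            record(stage, outs, False)
        else:
            m = lio.read_coverage_files(cfg.coverage_files, cfg.sample_ids)
            filtered = filter_cpgs(m, sheet, cfg.filter_criteria)
            ratios = to_ratios(filtered)
            lio.write_ratio_table(ratios, out / "ratios.tsv", sheet)
            record(stage, outs, True, n_sites_raw=m.n_sites,
                   n_sites_filtered=filtered.n_sites)
    except Exception as exc:
        _fail(out, stage, exc)

    # ---- dmrs -------------------------------------------------------------
    stage, outs = "dmrs", ["dmrs.tsv", "dmrs.bed"]
    try:
        if resume and _outputs_exist(out, outs):
            dmrs = lio.read_dmr_table(out / "dmrs.tsv")
            record(stage, outs, False)
        else:
            dmrs = call_dmrs(ratios, sheet, cfg.dmr_params)
            lio.write_dmr_table(dmrs, out / "dmrs.tsv")
            lio.write_dmr_bed(dmrs, out / "dmrs.bed")
            record(stage, outs, True, n_dmrs=len(dmrs),
                   n_dmr_cpgs=sum(d.n_cpgs for d in dmrs))
    except Exception as exc:
        _fail(out, stage, exc)

    # ---- deconvolve (optional) -------------------------------------------
    if cfg.celltype_reference:
        stage, outs = "deconvolve", ["cell_proportions.csv", "celltype_tests.tsv"]
        try:
            if resume and _outputs_exist(out, outs):
                record(stage, outs, False)
            else:
                ref = lio.read_celltype_reference(cfg.celltype_reference)
                props = deconvolve_cohort(ratios, ref)
                props.to_frame().to_csv(out / "cell_proportions.csv")
                compare_groups(props, sheet).to_csv(
                    out / "celltype_tests.tsv", sep="\t", index=False)
                record(stage, outs, True)
        except Exception as exc:
            _fail(out, stage, exc)

    # ---- screen -----------------------------------------------------------
    stage, outs = "screen", ["features.tsv", "screen.tsv"]
    try:
        if resume and _outputs_exist(out, outs):
            features = pd.read_csv(out / "features.tsv", sep="\t", index_col=0)
            sdf = pd.read_csv(out / "screen.tsv", sep="\t")
            retained_ids = list(sdf.loc[sdf["retained"], "dmr_id"])
            n_pass = int((sdf["p_univariate"] < cfg.screen_alpha).sum())
            record(stage, outs, False)
        else:
            features = dmr_feature_matrix(dmrs, ratios)
            features.to_csv(out / "features.tsv", sep="\t")
            results = univariate_screen(features, sheet, alpha=cfg.screen_alpha)
            results = confounder_exclusion(results, features, sheet,
                                           cfg.covariates)
            sdf = screen_table(results)
            sdf.to_csv(out / "screen.tsv", sep="\t", index=False)
            retained_ids = [r.dmr_id for r in results if r.retained]
            n_pass = sum(1 for r in results
                         if r.p_univariate < cfg.screen_alpha)
            record(stage, outs, True, n_dmrs_tested=len(results),
                   n_screen_pass=n_pass,
                   n_excluded_confounding=n_pass - len(retained_ids),
                   n_retained=len(retained_ids))
    except Exception as exc:
        _fail(out, stage, exc)

    # ---- signature --------------------------------------------------------
    stage, outs = "signature", ["signature.json", "roc.tsv"]
    try:
        if resume and _outputs_exist(out, outs):
            record(stage, outs, False)
            sig = json.loads((out / "signature.json").read_text())
            sig_dmrs = sig["selected_dmrs"]
        else:
            if not retained_ids:
                raise ValueError("no DMRs retained for signature selection")
            labels = sheet.group_labels(features.index)
            use = np.isin(labels, ("ER", "NR"))
            X = features.loc[use, retained_ids]
            y = np.where(labels[use] == "ER", 1.0, -1.0)
            model = stepwise_signature(X, y, max_k=cfg.max_k, B=cfg.bootstrap,
                                       seed=stage_seed(cfg.seed, "signature"),
                                       cv_mode=cfg.cv_mode)
            model.to_json(out / "signature.json")
            sel = [list(X.columns).index(d) for d in model.selected_dmrs]
            scores = loocv_scores(X.to_numpy(float), y, np.sort(sel),
                                  mode=cfg.cv_mode)
            roc_curve(scores, y).to_csv(out / "roc.tsv", sep="\t", index=False)
            sig_dmrs = model.selected_dmrs
            record(stage, outs, True, final_k=model.final_k,
                   loocv_auc=model.loocv_auc)
    except Exception as exc:
        _fail(out, stage, exc)

    # ---- annotate (optional) ----------------------------------------------
    if cfg.gene_models:
        stage, outs = "annotate", ["dmrs_annotated.tsv"]
        try:
            if resume and _outputs_exist(out, outs):
                record(stage, outs, False)
            else:
                genes = lio.read_gene_models(cfg.gene_models)
                annotate_dmrs(dmrs, genes)
                lio.write_dmr_table(dmrs, out / "dmrs_annotated.tsv")
                record(stage, outs, True)
        except Exception as exc:
            _fail(out, stage, exc)

    # ---- post-hoc (optional, needs PR samples) ----------------------------
    if (sheet.df["group"] == "PR").sum() >= 2:
        stage, outs = "posthoc", ["pr_anova.tsv", "pr_boxplots.tsv"]
        try:
            if resume and _outputs_exist(out, outs):
                record(stage, outs, False)
            else:
                anova, boxes = partial_responder_anova(features, sheet, sig_dmrs)
                anova.to_csv(out / "pr_anova.tsv", sep="\t", index=False)
                boxes.to_csv(out / "pr_boxplots.tsv", sep="\t", index=False)
                record(stage, outs, True)
        except Exception as exc:
            _fail(out, stage, exc)

    # ---- cohort stats -----------------------------------------------------
    stage, outs = "cohort", ["cohort_stats.tsv"]
    try:
        if resume and _outputs_exist(out, outs):
            record(stage, outs, False)
        else:
            cohort_table(sheet).to_csv(out / "cohort_stats.tsv", sep="\t",
                                       index=False)
            record(stage, outs, True)
    except Exception as exc:
        _fail(out, stage, exc)

    manifest["executed"] = executed
    manifest["content_hash"] = _content_hash(out, manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _content_hash(out_dir: Path, manifest: dict) -> str:
    h = hashlib.sha256()
    names = sorted({n for s in manifest["stages"].values() for n in s["outputs"]})
    for n in names:
        h.update(n.encode())
        h.update((out_dir / n).read_bytes())
    return h.hexdigest()


def _fail(out_dir: Path, stage: str, exc: BaseException) -> None:
    record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
    (out_dir / "error.json").write_text(json.dumps(record, indent=1))
    raise PipelineStageError(stage, exc) from exc
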
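#!/usr/bin/env python
"""Reduce the DMR list to response-specific regions: univariate
logistic screen at p < 0.1 on per-DMR mean methylation, then the
crude-vs-adjusted odds-ratio rule against each comedication covariate
(atypical antipsychotics, antidepressants, anticonvulsants, number of
psychotropic drugs, current lithium). Writes the screen table and the
per-sample DMR feature matrix."""

import argparse
from pathlib import Path

import numpy as np

from lithmark import io as lio
from lithmark.screen import (DEFAULT_COVARIATES, confounder_exclusion,
                             dmr_feature_matrix, screen_table,
                             univariate_screen)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--run", type=Path, default=ROOT / "results" / "run")
    args = ap.parse_args()

    sheet = lio.read_sample_sheet(args.data / "sample_sheet.csv")
    ratios = lio.read_ratio_table(args.run / "ratios.tsv")
    dmrs = lio.read_dmr_table(args.run / "dmrs.tsv")

    features = dmr_feature_matrix(dmrs, ratios)
    features.to_csv(args.run / "features.tsv", sep="\t")

    res = univariate_screen(features, sheet, alpha=0.1)
    res = confounder_exclusion(res, features, sheet, DEFAULT_COVARIATES)
    screen_table(res).to_csv(args.run / "screen.tsv", sep="\t", index=False)

    n_pos = sum(1 for r in res
                if not np.isnan(r.p_univariate) and r.p_univariate < 0.1)
    n_exc = sum(1 for r in res if r.excluded_by)
    n_ret = sum(1 for r in res if r.retained)
    print(f"funnel: {len(res)} DMRs -> {n_pos} at p < 0.1 -> "
          f"{n_exc} excluded as confounded -> {n_ret} retained")


if __name__ == "__main__":
    main()
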
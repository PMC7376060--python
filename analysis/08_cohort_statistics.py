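#!/usr/bin/env python
"""Cohort description statistics: group comparisons of demographics and
comedication (Mann-Whitney/Welch for continuous, one-sided Fisher and
chi-square for binary, chi-square for the psychotropic-drug count) —
run both on the simulated cohort and on the published contingency
tables, whose three reference values (0.011, 0.95, 0.17) the code
reproduces."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lithmark import io as lio
from lithmark.annotate import cohort_table
from lithmark.io import SampleSheet

ROOT = Path(__file__).resolve().parent.parent


def published_margins_sheet() -> SampleSheet:
    """Cohort rebuilt from the published 2x2 margins."""
    return SampleSheet(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(26)],
        "group": ["ER"] * 15 + ["NR"] * 11,
        "sex": ["M"] * 8 + ["F"] * 7 + ["M"] * 6 + ["F"] * 5,
        "age": np.linspace(35, 62, 26).round(1),
        "bmi": np.linspace(21, 30, 26).round(1),
        "smoker": [True] * 6 + [False] * 9 + [True] * 6 + [False] * 5,
        "med_atypical": [False] * 15 + [True] * 7 + [False] * 4,
        "med_antidepressant": [True] * 3 + [False] * 12 + [True] * 4 + [False] * 7,
        "med_anticonvulsant": [True] * 3 + [False] * 12 + [True] * 5 + [False] * 6,
        "n_psychotropics": [1] * 11 + [2] * 3 + [3] + [1] * 3 + [2] * 4 + [3] * 4,
        "current_li": [True] * 14 + [False] + [True] * 5 + [False] * 6,
    }))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--run", type=Path, default=ROOT / "results" / "run")
    args = ap.parse_args()

    pub = cohort_table(published_margins_sheet())
    pub.to_csv(args.run / "cohort_stats_published_margins.tsv",
               sep="\t", index=False)
    key = pub.set_index(["variable", "test"])["p"]
    print("published margins: "
          f"current Li one-sided Fisher p = "
          f"{key[('current_li', 'fisher-one-sided')]:.3f}, "
          f"sex chi-square p = {key[('sex', 'chi-square')]:.2f}, "
          f"anticonvulsants one-sided Fisher p = "
          f"{key[('med_anticonvulsant', 'fisher-one-sided')]:.2f}")

    sheet = lio.read_sample_sheet(args.data / "sample_sheet.csv")
    sim = cohort_table(sheet)
    sim.to_csv(args.run / "cohort_stats.tsv", sep="\t", index=False)
    fisher = sim[sim["test"] == "fisher-one-sided"].set_index("variable")
    print("simulated cohort one-sided Fisher p: "
          + ", ".join(f"{v}={fisher.loc[v, 'p']:.3f}"
                      for v in ("current_li", "med_atypical",
                                "med_anticonvulsant")))


if __name__ == "__main__":
    main()
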
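#!/usr/bin/env python
"""Apply the CpG inclusion filter (>= 5x coverage in >= 80% of samples
of each of the ER and NR groups) and convert counts to methylation
ratios; writes the group-blocked ratio table under results/run/."""

import argparse
from pathlib import Path

from lithmark import io as lio
from lithmark.filtering import FilterCriteria, filter_cpgs, to_ratios

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "run")
    args = ap.parse_args()

    sheet = lio.read_sample_sheet(args.data / "sample_sheet.csv")
    paths = sorted((args.data / "coverage").glob("*.cov"))
    m = lio.read_coverage_files(paths)
    filtered = filter_cpgs(m, sheet, FilterCriteria())
    ratios = to_ratios(filtered)

    args.out.mkdir(parents=True, exist_ok=True)
    lio.write_ratio_table(ratios, args.out / "ratios.tsv", sheet)
    print(f"coverage filter: {filtered.n_sites}/{m.n_sites} CpGs retained "
          f"-> {args.out / 'ratios.tsv'}")


if __name__ == "__main__":
    main()
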
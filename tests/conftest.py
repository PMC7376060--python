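import numpy as np
import pandas as pd
import pytest

from lithmark.io import MethylationCountMatrix, MethylationRatioMatrix, SampleSheet


def make_sheet(n_er=3, n_nr=3, n_pr=0, seed=0, **overrides):
    """Minimal valid sample sheet for unit tests."""
    rng = np.random.default_rng(seed)
    ids = ([f"ER{i+1:02d}" for i in range(n_er)]
           + [f"NR{i+1:02d}" for i in range(n_nr)]
           + [f"PR{i+1:02d}" for i in range(n_pr)])
    n = len(ids)
    df = pd.DataFrame({
        "sample_id": ids,
        "group": ["ER"] * n_er + ["NR"] * n_nr + ["PR"] * n_pr,
        "sex": rng.choice(["M", "F"], n),
        "age": rng.normal(48, 10, n).round(1),
        "bmi": rng.normal(25, 3, n).round(1),
        "smoker": rng.random(n) < 0.5,
        "med_atypical": rng.random(n) < 0.3,
        "med_antidepressant": rng.random(n) < 0.3,
        "med_anticonvulsant": rng.random(n) < 0.3,
        "n_psychotropics": 1 + rng.binomial(2, 0.4, n),
        "current_li": rng.random(n) < 0.5,
    })
    for k, v in overrides.items():
        df[k] = v
    return SampleSheet(df)


@pytest.fixture
def sheet_3v3():
    return make_sheet(3, 3)


@pytest.fixture
def sheet_15v11():
    return make_sheet(15, 11)


def make_counts(chrom, pos, samples, meth, total):
    return MethylationCountMatrix(np.array(chrom, dtype=object),
                                  np.array(pos), list(samples),
                                  np.array(meth), np.array(total))


def make_ratios(chrom, pos, samples, ratio):
    return MethylationRatioMatrix(np.array(chrom, dtype=object),
                                  np.array(pos), list(samples),
                                  np.array(ratio, dtype=float))
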
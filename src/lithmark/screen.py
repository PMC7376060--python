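"""Univariate logistic screen and crude-vs-adjusted odds-ratio
confounder exclusion.

Each DMR's per-sample mean methylation is standardized (so odds ratios
are per standard deviation) and regressed on the ER/NR outcome. DMRs
with a univariate Wald p below ``alpha`` (default 0.1) continue to the
confounder stage, where for each comedication covariate a second model
adds that covariate; if the adjusted methylation OR falls outside the
95% Wald confidence interval of the crude OR, the covariate is recorded
in ``excluded_by`` and the DMR is dropped as confounded.

With n = 26 and strong effects, maximum-likelihood logistic fits can
separate; separated or non-convergent fits fall back to a Firth-type
(Jeffreys-prior) penalized likelihood and are flagged ``penalized``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreenResult", "dmr_feature_matrix", "univariate_screen",
           "confounder_exclusion", "firth_logistic",
           "DEFAULT_COVARIATES", "screen_table"]

DEFAULT_COVARIATES = ["med_atypical", "med_antidepressant",
                      "med_anticonvulsant", "n_psychotropics", "current_li"]

_Z95 = 1.959963984540054


@dataclass
class ScreenResult:
    dmr_id: str
    crude_or: float = float("nan")
    crude_ci: tuple[float, float] = (float("nan"), float("nan"))
    p_univariate: float = float("nan")
    adjusted_or: dict[str, float] = field(default_factory=dict)
    excluded_by: list[str] = field(default_factory=list)
    retained: bool = False
    penalized: bool = False
    separation: bool = False
    note: str = ""


def dmr_feature_matrix(dmrs, ratios, percent: bool = True) -> pd.DataFrame:
    """Per-sample mean methylation of each DMR (mean over member CpGs
    with data). Rows = samples, columns = DMR ids."""
    pos_index = {}
    for i, (c, p) in enumerate(zip(ratios.chrom, ratios.pos)):
        pos_index[(c, int(p))] = i
    cols = {}
    for d in dmrs:
        idx = [pos_index[(d.chrom, p)] for p in d.cpg_positions
               if (d.chrom, p) in pos_index]
        if not idx:
            raise ValueError(f"{d.dmr_id}: no member CpGs in the ratio matrix")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanmean(ratios.ratio[idx], axis=0)
        cols[d.dmr_id] = v * (100.0 if percent else 1.0)
    df = pd.DataFrame(cols, index=list(ratios.samples))
    if df.isna().any().any():
        # impute rare all-missing region means with the column mean
        df = df.fillna(df.mean())
    return df


# ---------------------------------------------------------------------------
# Logistic fitting


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Quasi-complete separation check for a single predictor."""
    x1, x0 = x[y == 1], x[y == 0]
    return (x1.min() >= x0.max()) or (x0.min() >= x1.max())


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalized logistic regression (Jeffreys prior).

    ``X`` includes the intercept column. Returns (beta, se).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # hat diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # dampen huge steps for stability
        nstep = np.linalg.norm(step)
        if nstep > 5.0:
            step *= 5.0 / nstep
        beta = beta + step
        if np.linalg.norm(step) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return beta, np.sqrt(np.maximum(np.diag(cov), 0.0))


def _fit_logit(X: np.ndarray, y: np.ndarray,
               force_firth: bool = False) -> tuple[np.ndarray, np.ndarray, bool]:
    """ML logistic via statsmodels with Firth fallback.

    Returns (beta, se, penalized).
    """
    if not force_firth:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = np.asarray(res.params), np.asarray(res.bse)
            ok = (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))
                  and np.all(np.abs(beta) < 15) and np.all(se < 50)
                  and res.mle_retvals.get("converged", True))
            if ok:
                return beta, se, False
        except Exception:
            pass
    beta, se = firth_logistic(X, y)
    return beta, se, True


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    return (v - v.mean()) / sd


def univariate_screen(features: pd.DataFrame, sheet, alpha: float = 0.1,
                      ) -> list[ScreenResult]:
    """One logistic fit per DMR: outcome (ER=1/NR=0) ~ standardized
    methylation. Wald p < ``alpha`` marks the DMR as screen-positive
    (``retained`` pending the confounder stage)."""
    labels = sheet.group_labels(features.index)
    use = np.isin(labels, ("ER", "NR"))
    y = (labels[use] == "ER").astype(float)
    results = []
    for dmr_id in features.columns:
        r = ScreenResult(dmr_id=dmr_id)
        v = features.loc[use, dmr_id].to_numpy(dtype=float)
        if np.std(v, ddof=1) == 0:
            r.note = "zero variance; dropped"
            r.retained = False
            results.append(r)
            continue
        z = _standardize(v)
        r.separation = _is_separated(z, y)
        X = np.column_stack([np.ones_like(z), z])
        beta, se, pen = _fit_logit(X, y, force_firth=r.separation)
        r.penalized = pen
        from scipy import stats as _st

        wald_z = beta[1] / se[1] if se[1] > 0 else np.inf
        r.p_univariate = float(2 * _st.norm.sf(abs(wald_z)))
        r.crude_or = float(np.exp(beta[1]))
        r.crude_ci = (float(np.exp(beta[1] - _Z95 * se[1])),
                      float(np.exp(beta[1] + _Z95 * se[1])))
        r.retained = r.p_univariate < alpha
        results.append(r)
    return results


def confounder_exclusion(screen: list[ScreenResult], features: pd.DataFrame,
                         sheet, covariates: list[str] = DEFAULT_COVARIATES,
                         ) -> list[ScreenResult]:
    """Apply the crude-vs-adjusted OR rule, one covariate at a time.

    For each screen-positive DMR and each covariate, the outcome is
    refit on methylation plus that covariate; an adjusted methylation OR
    outside the crude OR's 95% CI adds the covariate to ``excluded_by``.
    A covariate constant across the analysed samples is skipped with a
    warning. Final ``retained`` = screen-positive and nothing excluded.
    """
    labels = sheet.group_labels(features.index)
    use = np.isin(labels, ("ER", "NR"))
    y = (labels[use] == "ER").astype(float)
    used_samples = list(np.asarray(features.index)[use])
    for r in screen:
        if not r.retained:
            continue
        v = features.loc[use, r.dmr_id].to_numpy(dtype=float)
        z = _standardize(v)
        Xc = np.column_stack([np.ones_like(z), z])
        for cov in covariates:
            c = np.asarray(sheet.covariate(cov, used_samples), dtype=float)
            if np.ptp(c) == 0:
                warnings.warn(f"covariate {cov} is constant; skipped for "
                              f"{r.dmr_id}", stacklevel=2)
                continue
            X = np.column_stack([np.ones_like(z), z, c])
            sep = r.separation or _covariate_separates(c, y)
            beta, se, pen = _fit_logit(X, y, force_firth=sep)
            r.penalized = r.penalized or pen
            adj_or = float(np.exp(beta[1]))
            r.adjusted_or[cov] = adj_or
            # compare like with like: when the adjusted model needed
            # penalization, re-derive the crude interval under the same
            # (Firth) likelihood so the rule tests confounding, not the
            # estimator switch
            if pen:
                cb, cse, _ = _fit_logit(Xc, y, force_firth=True)
                lo = float(np.exp(cb[1] - _Z95 * cse[1]))
                hi = float(np.exp(cb[1] + _Z95 * cse[1]))
            else:
                lo, hi = r.crude_ci
            if not (lo <= adj_or <= hi):
                r.excluded_by.append(cov)
        r.retained = len(r.excluded_by) == 0
    return screen


def _covariate_separates(c: np.ndarray, y: np.ndarray) -> bool:
    vals = np.unique(c)
    if len(vals) > 2:
        return False
    for v in vals:
        if len(np.unique(y[c == v])) == 1:  # covariate level fixes the outcome
            return True
    return False


def screen_table(screen: list[ScreenResult]) -> pd.DataFrame:
    rows = []
    for r in screen:
        rows.append({
            "dmr_id": r.dmr_id, "crude_or": r.crude_or,
            "ci_low": r.crude_ci[0], "ci_high": r.crude_ci[1],
            "p_univariate": r.p_univariate,
            **{f"adj_or_{k}": v for k, v in r.adjusted_or.items()},
            "excluded_by": ";".join(r.excluded_by),
            "retained": r.retained, "penalized": r.penalized,
            "separation": r.separation, "note": r.note,
        })
    return pd.DataFrame(rows)
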
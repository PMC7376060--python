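"""Sparse PLS-DA signature construction with LOOCV-AUC model sizing and
bootstrap selection-stability frequencies.

The first sparse PLS component for a two-class outcome y in {-1, +1}
and column-standardized X has loading direction w proportional to X'y.
Lasso-style sparsity is imposed by soft-thresholding: with ``keepX``
features to retain, the threshold is the (keepX+1)-th largest |w|;
surviving entries are shrunk toward zero by it and the loading vector is
renormalized to unit length. Sample scores are t = Xw.

Model size is chosen by expanding the selected set one feature at a
time along the |X'y| ranking and computing a leave-one-out
cross-validated AUC at each size k; the final size is the smallest k
attaining the maximum of the trajectory. Selection stability is the
fraction of group-stratified bootstrap resamples in which each feature
is re-selected at the final size. The reported operating point is the
Youden-optimal threshold on the LOOCV scores.

Two cross-validation modes are available: ``fixed`` scores a pre-named
feature set inside each fold (the trajectory evaluates candidate
combinations, as when reproducing a published stepwise path), and
``nested`` repeats the selection itself inside every fold, which is the
unbiased estimate and is on average no higher than ``fixed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignatureModel", "splsda_component", "select_features",
           "loocv_auc", "loocv_scores", "stepwise_signature",
           "auc_from_scores", "roc_curve", "youden_point", "standardize_columns"]


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Column z-scores (ddof=1); zero-variance columns map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _rank_order(w: np.ndarray) -> np.ndarray:
    """Indices sorted by decreasing |w|, ties broken by lower index."""
    return np.lexsort((np.arange(len(w)), -np.abs(w)))


def select_features(Xs: np.ndarray, y: np.ndarray, keepX: int) -> np.ndarray:
    """Top-``keepX`` features by |X'y| on standardized X (the sparse
    PLS selection for one component)."""
    w = Xs.T @ y
    return np.sort(_rank_order(w)[:keepX])


def splsda_component(Xs: np.ndarray, y: np.ndarray, keepX: int,
                     ) -> np.ndarray:
    """First sparse PLS-DA loading vector (unit norm, exactly ``keepX``
    non-zeros) for standardized ``Xs`` and y in {-1, +1}."""
    n, p = Xs.shape
    if not (1 <= keepX <= p):
        raise ValueError(f"keepX must be in [1, {p}]")
    w = Xs.T @ y
    order = _rank_order(w)
    keep = order[:keepX]
    thr = np.abs(w[order[keepX]]) if keepX < p else 0.0
    mag = np.abs(w[keep]) - thr
    if keepX < p and np.any(mag <= 0):
        warnings.warn("tie at the soft threshold; keeping lower-index "
                      "features", stacklevel=2)
        mag = np.maximum(mag, 1e-12)
    out = np.zeros(p)
    out[keep] = np.sign(w[keep]) * mag
    nrm = np.linalg.norm(out)
    if nrm == 0:
        out[keep] = np.sign(w[keep])
        nrm = np.linalg.norm(out)
    return out / nrm


def auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC for the positive class (y == +1) by the Mann-Whitney
    statistic; tied score pairs count one half."""
    s_pos = np.asarray(scores)[y > 0]
    s_neg = np.asarray(scores)[y < 0]
    if len(s_pos) == 0 or len(s_neg) == 0:
        raise ValueError("both classes must be present")
    diff = s_pos[:, None] - s_neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(s_pos) * len(s_neg)))


def _fold_loading(Xtr: np.ndarray, ytr: np.ndarray, selected: np.ndarray,
                  mode: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Training-fold standardization stats and loading vector."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xtr - mu) / sd
    if mode == "nested":
        sel = select_features(Xs, ytr, k)
    else:
        sel = selected
    w_full = np.zeros(Xtr.shape[1])
    w_sel = Xs[:, sel].T @ ytr
    nrm = np.linalg.norm(w_sel)
    w_full[sel] = w_sel / (nrm if nrm > 0 else 1.0)
    return mu, sd, w_full


def loocv_scores(X: np.ndarray, y: np.ndarray, selected: np.ndarray,
                 mode: str = "fixed") -> np.ndarray:
    """Held-out component score for every sample under leave-one-out."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4 or len(np.unique(y)) < 2:
        raise ValueError("need >= 4 samples and both classes")
    if mode not in ("fixed", "nested"):
        raise ValueError("mode must be 'fixed' or 'nested'")
    selected = np.asarray(selected, dtype=int)
    k = len(selected)
    scores = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if len(np.unique(y[tr])) < 2:  # unreachable with both-class input, guarded
            raise ValueError("a training fold lost a class")
        mu, sd, w = _fold_loading(X[tr], y[tr], selected, mode, k)
        scores[i] = ((X[i] - mu) / sd) @ w
    return scores


def loocv_auc(X: np.ndarray, y: np.ndarray, selected: np.ndarray,
              mode: str = "fixed") -> float:
    """Leave-one-out cross-validated AUC of the component built on
    ``selected`` (or re-selected per fold when ``mode='nested'``)."""
    return auc_from_scores(loocv_scores(X, y, selected, mode), np.asarray(y))


def roc_curve(scores: np.ndarray, y: np.ndarray,
              ) -> pd.DataFrame:
    """ROC coordinates (threshold, sensitivity, specificity) over the
    observed score thresholds; positive class is y == +1, predicted
    positive when score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pos, neg = (y > 0).sum(), (y < 0).sum()
    rows = []
    for t in thresholds:
        pred = scores >= t
        sens = (pred & (y > 0)).sum() / pos
        spec = (~pred & (y < 0)).sum() / neg
        rows.append({"threshold": t, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def youden_point(scores: np.ndarray, y: np.ndarray,
                 ) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing Youden's J."""
    roc = roc_curve(scores, y)
    j = roc["sensitivity"] + roc["specificity"] - 1.0
    i = int(j.idxmax())
    return (float(roc.loc[i, "threshold"]),
            float(roc.loc[i, "sensitivity"]),
            float(roc.loc[i, "specificity"]))


@dataclass
class SignatureModel:
    selected_dmrs: list[str]
    loadings: dict[str, float]
    auc_trajectory: list[tuple[int, float]]
    ssf: dict[str, float]
    sensitivity: float
    specificity: float
    threshold: float
    final_k: int
    loocv_auc: float
    cv_mode: str
    seed: int

    def to_json(self, path: str | Path) -> None:
        obj = {k: (v if not isinstance(v, dict) else dict(v))
               for k, v in self.__dict__.items()}
        obj["auc_trajectory"] = [[int(k), float(a)] for k, a in self.auc_trajectory]
        Path(path).write_text(json.dumps(obj, indent=1))


def stepwise_signature(X: pd.DataFrame | np.ndarray, y: np.ndarray,
                       feature_ids: list[str] | None = None,
                       max_k: int = 10, B: int = 1000, seed: int = 0,
                       cv_mode: str = "fixed") -> SignatureModel:
    """One-by-one signature expansion with bootstrap stability.

    For k = 1..max_k the top-k features (by |X'y| on standardized data)
    are scored by LOOCV-AUC; the final size is the smallest k attaining
    the trajectory maximum. Selection is then repeated on ``B``
    group-stratified bootstrap resamples to obtain per-feature
    selection-stability frequencies (SSF). Deterministic given ``seed``.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if feature_ids is None:
            feature_ids = [f"F{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if max_k > p:
        warnings.warn(f"max_k={max_k} > {p} features; clipped", stacklevel=2)
        max_k = p

    Xs = standardize_columns(Xa)
    ranking = _rank_order(Xs.T @ y)

    trajectory: list[tuple[int, float]] = []
    for k in range(1, max_k + 1):
        sel = np.sort(ranking[:k])
        trajectory.append((k, loocv_auc(Xa, y, sel, mode=cv_mode)))
    aucs = np.array([a for _, a in trajectory])
    final_k = int(np.argmax(aucs >= aucs.max() - 1e-12) + 1)
    selected_idx = np.sort(ranking[:final_k])
    # order the reported signature by selection (ranking) order
    ordered_idx = [int(i) for i in ranking[:final_k]]

    w = splsda_component(Xs, y, final_k)
    loadings = {feature_ids[i]: float(w[i]) for i in ordered_idx}

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y > 0)
    neg_idx = np.flatnonzero(y < 0)
    counts = np.zeros(p)
    for _ in range(B):
        bi = np.concatenate([rng.choice(pos_idx, len(pos_idx), replace=True),
                             rng.choice(neg_idx, len(neg_idx), replace=True)])
        Xb = standardize_columns(Xa[bi])
        sel_b = select_features(Xb, y[bi], final_k)
        counts[sel_b] += 1
    ssf_all = counts / B

    scores = loocv_scores(Xa, y, selected_idx, mode=cv_mode)
    thr, sens, spec = youden_point(scores, y)

    return SignatureModel(
        selected_dmrs=[feature_ids[i] for i in ordered_idx],
        loadings=loadings,
        auc_trajectory=trajectory,
        ssf={feature_ids[j]: float(ssf_all[j]) for j in range(p)},
        sensitivity=sens, specificity=spec, threshold=thr,
        final_k=final_k, loocv_auc=float(aucs[final_k - 1]),
        cv_mode=cv_mode, seed=seed)
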
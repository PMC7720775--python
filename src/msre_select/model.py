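"""Sparse logistic tumor/normal classifier on normalized amplicon features.

The model is L1-penalized logistic regression fitted along a glmnet-style
decreasing lambda path, scored by stratified K-fold cross-validated ROC AUC
(pooled out-of-fold scores by default), with the one-standard-error rule:
the largest lambda whose CV AUC is within one SE of the maximum is chosen
and the model refitted on the full training set there. Features are
log2(normalized + eps), standardized with training statistics only. AUC
confidence intervals use the DeLong variance estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .assay import rank_auc
from .io import AssayTable
from .simulate import stage_rng

__all__ = [
    "ModelSpec",
    "PanelModel",
    "train_test_split",
    "features_from_normalized",
    "fit_lasso_logistic",
    "evaluate",
    "delong_variance",
]


@dataclass
class ModelSpec:
    n_folds: int = 3
    n_lambda: int = 100
    lambda_decades: float = 4.0
    eps: float = 1e-3
    cv_scoring: str = "pooled"  # 'pooled' out-of-fold AUC or 'per_fold' mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_lambda < 2 or self.lambda_decades <= 0:
            raise ValueError("lambda path must be decreasing with >=2 points")


@dataclass
class PanelModel:
    feature_names: list[str]
    coefficients: np.ndarray  # on the standardized scale; zeros = unselected
    intercept: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    chosen_lambda: float
    lambda_path: np.ndarray
    cv_auc: np.ndarray
    cv_auc_se: np.ndarray
    eps: float = 1e-3
    train_auc: float = float("nan")
    train_auc_ci: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def support(self) -> list[str]:
        return [f for f, c in zip(self.feature_names, self.coefficients) if c != 0.0]

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        x = features.loc[:, self.feature_names].to_numpy(float)
        z = (x - self.feature_means) / self.feature_scales
        return z @ self.coefficients + self.intercept

    def to_json(self, path: str) -> None:
        payload = {
            "features": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "chosen_lambda": self.chosen_lambda,
            "support": self.support,
            "train_auc": self.train_auc,
            "train_auc_ci": list(self.train_auc_ci),
            "eps": self.eps,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def train_test_split(
    table: AssayTable, fractions: tuple[float, float] = (0.5, 0.5), seed: int = 0
) -> tuple[AssayTable, AssayTable]:
    """Stratified random partition of samples into train and test tables."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = stage_rng(seed, "train_test_split")
    train_ids: list[str] = []
    test_ids: list[str] = []
    for grp in sorted(set(table.metadata["group"])):
        ids = sorted(table.metadata.index[table.metadata["group"] == grp])
        if len(ids) < 2:
            raise ValueError(f"group {grp!r} too small to stratify")
        rng.shuffle(ids)
        k = int(round(fractions[0] * len(ids)))
        train_ids += ids[:k]
        test_ids += ids[k:]
    order = list(table.counts.columns)
    train_ids.sort(key=order.index)
    test_ids.sort(key=order.index)
    return table.subset_samples(train_ids), table.subset_samples(test_ids)


def features_from_normalized(normalized: pd.DataFrame, eps: float = 1e-3) -> pd.DataFrame:
    """Sample x feature matrix: log2(normalized value + eps)."""
    return np.log2(normalized.T + eps)


def _labels(table: AssayTable, samples) -> np.ndarray:
    return (table.metadata.loc[list(samples), "group"] == "cancer").to_numpy(int)


def _l1_kwargs() -> dict:
    import sklearn

    major, minor = (int(v) for v in sklearn.__version__.split(".")[:2])
    if (major, minor) >= (1, 8):
        return {"l1_ratio": 1.0}
    return {"penalty": "l1"}


_L1_KWARGS = _l1_kwargs()


def _fit_path_point(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    # glmnet-scale lambda: objective (1/n) sum logloss + lam * ||w||_1,
    # equivalent to sklearn's C = 1 / (n * lam)
    clf = LogisticRegression(
        C=1.0 / (len(y) * lam),
        solver="liblinear",
        max_iter=2000,
        tol=1e-7,
        random_state=0,
        **_L1_KWARGS,
    )
    clf.fit(x, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def fit_lasso_logistic(
    train_table: AssayTable,
    normalized: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> PanelModel:
    """Fit the sparse panel on training samples.

    The lambda path starts at the smallest penalty that zeroes every
    coefficient (lambda_max = max|X'(y - ybar)|/n on standardized features)
    and descends ``lambda_decades`` decades over ``n_lambda`` points.
    Each lambda is scored by stratified K-fold out-of-fold AUC; the largest
    lambda within one standard error of the best AUC is selected and the
    model refitted on all training data.
    """
    spec = spec or ModelSpec()
    feats = features_from_normalized(normalized, spec.eps)
    samples = list(feats.index)
    y = _labels(train_table, samples)
    if min((y == 0).sum(), (y == 1).sum()) < spec.n_folds:
        raise ValueError("too few samples per class for the requested folds")
    x_raw = feats.to_numpy(float)
    mu = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x_raw - mu) / sd

    n = len(y)
    lam_max = np.max(np.abs(x.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-6)
    path = np.geomspace(lam_max, lam_max * 10 ** (-spec.lambda_decades), spec.n_lambda)

    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed % (2**31))
    folds = list(skf.split(x, y))
    oof = np.full((len(path), n), np.nan)
    fold_auc = np.full((len(path), spec.n_folds), np.nan)
    for fi, (tr, te) in enumerate(folds):
        mu_f = x_raw[tr].mean(axis=0)
        sd_f = x_raw[tr].std(axis=0)
        sd_f[sd_f == 0] = 1.0
        xtr = (x_raw[tr] - mu_f) / sd_f
        xte = (x_raw[te] - mu_f) / sd_f
        for li, lam in enumerate(path):
            try:
                w, b = _fit_path_point(xtr, y[tr], lam)
            except Exception:
                continue  # non-converged path point dropped for this fold
            scores = xte @ w + b
            oof[li, te] = scores
            if len(np.unique(y[te])) == 2:
                fold_auc[li, fi] = rank_auc(scores[y[te] == 1], scores[y[te] == 0])
    cv_auc = np.empty(len(path))
    for li in range(len(path)):
        s = oof[li]
        ok = ~np.isnan(s)
        if spec.cv_scoring == "pooled" and ok.sum() and len(np.unique(y[ok])) == 2:
            cv_auc[li] = rank_auc(s[ok & (y == 1)], s[ok & (y == 0)])
        else:
            cv_auc[li] = np.nanmean(fold_auc[li])
    with np.errstate(invalid="ignore"):
        cv_se = np.nanstd(fold_auc, axis=1, ddof=1) / np.sqrt(spec.n_folds)

    best = int(np.nanargmax(cv_auc))
    threshold = cv_auc[best] - (cv_se[best] if np.isfinite(cv_se[best]) else 0.0)
    # one-SE rule: largest lambda within one SE of the best CV AUC whose
    # full-data refit is not the empty model (near-separable data can score
    # fold models perfectly at penalties where the full fit selects nothing)
    chosen, w, b = None, None, None
    for li in range(len(path)):  # path is decreasing: first qualifying = largest lambda
        if not (np.isfinite(cv_auc[li]) and cv_auc[li] >= threshold):
            continue
        w_li, b_li = _fit_path_point(x, y, path[li])
        if chosen is None:
            chosen, w, b = li, w_li, b_li  # fallback: plain one-SE choice
        if np.any(w_li != 0.0):
            chosen, w, b = li, w_li, b_li
            break
    if chosen is None:
        chosen = best
        w, b = _fit_path_point(x, y, path[chosen])

    model = PanelModel(
        feature_names=list(feats.columns),
        coefficients=w,
        intercept=b,
        feature_means=mu,
        feature_scales=sd,
        chosen_lambda=float(path[chosen]),
        lambda_path=path,
        cv_auc=cv_auc,
        cv_auc_se=cv_se,
        eps=spec.eps,
    )
    auc, ci = evaluate(model, train_table, normalized)
    model.train_auc, model.train_auc_ci = auc, ci
    return model


def delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """DeLong variance of the AUC U-statistic (midrank formulation)."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    m, n = len(pos), len(neg)
    from scipy.stats import rankdata

    allv = np.concatenate([pos, neg])
    r_all = rankdata(allv)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # P(neg < pos_i), structural components
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    del auc
    return s10 / m + s01 / n


def evaluate(
    model: PanelModel, table: AssayTable, normalized: pd.DataFrame
) -> tuple[float, tuple[float, float]]:
    """ROC AUC of the model's scores with a 95% DeLong confidence interval,
    truncated to [0, 1]."""
    feats = features_from_normalized(normalized, model.eps)
    y = _labels(table, feats.index)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for evaluation")
    scores = model.decision_function(feats)
    auc = rank_auc(scores[y == 1], scores[y == 0])
    var = delong_variance(scores[y == 1], scores[y == 0])
    half = 1.96 * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))
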
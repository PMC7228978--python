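"""Permutation-calibrated robustness of ridge-logistic microbiome classifiers.

Randomized permutation cross-validation (RPCV): k stratified random 70/30
train/test splits, a ridge-penalized logistic model fit on each training set
and scored by held-out AUROC.  In the null arm the class labels are permuted
uniformly at random before each iteration — one corrupted model per real
iteration — and significance is the empirical p-value

    p = (#{iterations whose real error >= mean null error} + 1) / (k + 1)

with error = 1 - AUROC, i.e. the fraction of real-arm classifiers that
performed no better than the averaged permuted classifier.  The displayed
set-notation variant of this formula in the literature compares the same
quantities; the prose definition above is what is implemented.

Features enter as log(count + 1), standardized per feature, after dropping
ASVs whose mean relative abundance is below 0.1%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .tables import AsvTable

log = logging.getLogger(__name__)


def preprocess_features(table: AsvTable, min_mean_rel_abund: float = 0.001) -> pd.DataFrame:
    """Abundance-filter, log-transform, and standardize an ASV table.

    ASVs with mean relative abundance below ``min_mean_rel_abund`` are
    removed; surviving counts are transformed log(x+1) then scaled per
    feature to mean 0 / sd 1.  Zero-variance features map to all-zeros with
    a warning rather than dividing by zero.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("samples with zero total reads cannot be normalized")
    rel = counts / totals
    keep = rel.mean(axis=0) >= min_mean_rel_abund
    if not keep.any():
        raise ValueError("no features survive the mean relative abundance filter")
    X = np.log1p(counts[:, keep])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("preprocess_features: %d constant features mapped to zero", int(degenerate.sum()))
    sd = np.where(degenerate, 1.0, sd)
    Z = (X - mu) / sd
    cols = [a for a, k in zip(table.asv_ids, keep) if k]
    return pd.DataFrame(Z, index=table.counts.index, columns=cols)


def auroc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def empirical_pvalue(real_aurocs, mean_null_auroc: float) -> float:
    """Empirical p: fraction of real classifiers at or below the averaged
    null performance, with the +1/+1 finite-sample correction."""
    real = np.asarray(real_aurocs, dtype=float)
    k = len(real)
    if k < 1:
        raise ValueError("need at least one iteration")
    real_err = 1.0 - real
    mean_null_err = 1.0 - mean_null_auroc
    worse = int((real_err >= mean_null_err).sum())
    return (worse + 1) / (k + 1)


@dataclass
class RobustnessReport:
    real_aurocs: np.ndarray
    null_aurocs: np.ndarray
    mean_auroc: float
    sd_auroc: float
    mean_null_auroc: float
    sd_null_auroc: float
    empirical_p: float
    coefficients: pd.Series          # mean per-feature coefficient, real arm
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"AUROC = {self.mean_auroc:.2f} ± {self.sd_auroc:.2f} "
            f"(null {self.mean_null_auroc:.2f} ± {self.sd_null_auroc:.2f}), "
            f"empirical p = {self.empirical_p:.4g} over k = {len(self.real_aurocs)}"
        )


def _make_model(penalty_c: float, model: str, rs: int):
    if model == "ridge_logistic":
        # L2 (ridge) penalty is sklearn's default; C is its inverse strength
        return LogisticRegression(C=penalty_c, solver="lbfgs", max_iter=2000)
    if model == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=rs)
    raise ValueError(f"unknown model {model!r}")


def _one_arm(X: np.ndarray, y: np.ndarray, k: int, train_frac: float,
             penalty_c: float, rng: np.random.Generator, permute: bool,
             model: str) -> tuple[np.ndarray, np.ndarray]:
    """Run k split/fit/score iterations; returns (aurocs, mean coefficients)."""
    aurocs = np.empty(k)
    coef_sum = np.zeros(X.shape[1])
    for i in range(k):
        yi = y if not permute else rng.permutation(y)
        rs = int(rng.integers(2**31 - 1))
        splitter = StratifiedShuffleSplit(n_splits=1, train_size=train_frac, random_state=rs)
        train, test = next(splitter.split(X, yi))
        clf = _make_model(penalty_c, model, rs)
        clf.fit(X[train], yi[train])
        if hasattr(clf, "decision_function"):
            scores = clf.decision_function(X[test])
            coef_sum += clf.coef_.ravel()
        else:
            scores = clf.predict_proba(X[test])[:, 1]
        aurocs[i] = roc_auc_score(yi[test], scores)
    return aurocs, coef_sum / k


def _validate_xy(features, labels):
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        names = list(features.columns)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(labels)
    classes, y01 = np.unique(y, return_inverse=True)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    if np.bincount(y01).min() < 2:
        raise ValueError("each class needs at least two samples")
    return X, y01, names


def rpcv(features, labels, k: int = 500, train_frac: float = 0.7,
         penalty_c: float = 1.0, seed=None, model: str = "ridge_logistic") -> tuple[np.ndarray, pd.Series]:
    """Real-arm RPCV: per-iteration held-out AUROCs and mean coefficients."""
    X, y, names = _validate_xy(features, labels)
    rng = np.random.default_rng(seed)
    aurocs, coefs = _one_arm(X, y, k, train_frac, penalty_c, rng, permute=False, model=model)
    return aurocs, pd.Series(coefs, index=names, name="mean_coefficient")


def permutation_null(features, labels, k: int = 500, train_frac: float = 0.7,
                     penalty_c: float = 1.0, seed=None, model: str = "ridge_logistic") -> np.ndarray:
    """Null-arm RPCV: labels permuted uniformly at random each iteration."""
    X, y, names = _validate_xy(features, labels)
    rng = np.random.default_rng(seed)
    aurocs, _ = _one_arm(X, y, k, train_frac, penalty_c, rng, permute=True, model=model)
    return aurocs


def robustness_report(features, labels, k: int = 500, train_frac: float = 0.7,
                      penalty_c: float = 1.0, seed=None,
                      model: str = "ridge_logistic") -> RobustnessReport:
    """Full robustness estimate: real and permuted arms plus empirical p.

    The two arms run the identical split/fit/score protocol; the null arm
    trains one corrupted-label model per real iteration.
    """
    X, y, names = _validate_xy(features, labels)
    rng = np.random.default_rng(seed)
    real, coefs = _one_arm(X, y, k, train_frac, penalty_c, rng, permute=False, model=model)
    null = _one_arm(X, y, k, train_frac, penalty_c, rng, permute=True, model=model)[0]
    p = empirical_pvalue(real, float(null.mean()))
    return RobustnessReport(
        real_aurocs=real,
        null_aurocs=null,
        mean_auroc=float(real.mean()),
        sd_auroc=float(real.std(ddof=1)) if k > 1 else 0.0,
        mean_null_auroc=float(null.mean()),
        sd_null_auroc=float(null.std(ddof=1)) if k > 1 else 0.0,
        empirical_p=p,
        coefficients=pd.Series(coefs, index=names, name="mean_coefficient"),
        config={"k": k, "train_frac": train_frac, "penalty_c": penalty_c,
                "seed": seed, "model": model},
    )
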
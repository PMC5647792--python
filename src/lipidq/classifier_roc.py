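"""ROC analysis and random-forest biomarker-panel selection.

Univariate AUC uses the Mann–Whitney identity (ties count one half)
with a DeLong 95% confidence interval.  Multivariate panels are scored
by out-of-fold random-forest class probabilities; panel selection ranks
features by impurity importance averaged over stratified folds inside a
2/3 training split, keeping the untouched third for a single honest
test AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .tableio import FeatureTable

__all__ = ["RocCurve", "PanelSelection", "roc_auc", "panel_roc", "rf_select_panel"]

N_TREES = 500


@dataclass
class RocCurve:
    """AUC with a DeLong 95% CI and the operating-point polyline."""

    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    orientation: int = 1      # -1 when scores were flipped so AUC >= 0.5


def _binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"ROC needs exactly two classes, got {classes}")
    return (labels == classes[1]).astype(int)


def _mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    r = rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_variance(scores: np.ndarray, y: np.ndarray, auc: float) -> float:
    """DeLong variance via placement values."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    # V10_i = P(neg < pos_i) + 0.5 P(neg == pos_i); symmetric for V01
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, alpha: float = 0.05, orient: bool = True) -> RocCurve:
    """ROC curve and AUC with a DeLong confidence interval.

    Scores are auto-oriented so AUC ≥ 0.5 (orientation recorded) unless
    ``orient=False`` — classifier probabilities already carry a
    direction and must be allowed to score below chance.  AUC is the
    Mann–Whitney U statistic over class pairs with ties counting ½.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    auc = _mann_whitney_auc(scores, y)
    orientation = 1
    if orient and auc < 0.5:
        scores = -scores
        auc = 1.0 - auc
        orientation = -1
    var = _delong_variance(scores, y, auc)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return RocCurve(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        fpr=fpr, tpr=tpr, thresholds=thr, orientation=orientation,
    )


def _log2_matrix(table: FeatureTable, features: list[str]) -> np.ndarray:
    missing = [f for f in features if f not in table.intensities.index]
    if missing:
        raise ValueError(f"panel features absent from table: {missing}")
    vals = table.intensities.loc[features].to_numpy(dtype=float).T
    if np.any(vals <= 0) or np.isnan(vals).any():
        raise ValueError("panel scoring requires positive, complete intensities")
    return np.log2(vals)


def panel_roc(
    table: FeatureTable,
    features: list[str],
    labels,
    folds: int = 7,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> RocCurve:
    """ROC of out-of-fold random-forest probabilities for a feature panel.

    Each injection's score is the class-1 probability predicted by a
    forest trained on the other folds, so the curve reflects held-out
    discrimination rather than training fit.
    """
    if not features:
        raise ValueError("panel must be nonempty")
    X = _log2_matrix(table, list(features))
    y = _binary_labels(labels)
    folds = min(folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(y.size)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + k)
        rf.fit(X[tr], y[tr])
        oof[te] = rf.predict_proba(X[te])[:, list(rf.classes_).index(1)]
    return roc_auc(oof, y, orient=False)


@dataclass
class PanelSelection:
    """Ranked features, selected panel, and its training/test AUCs."""

    ranking: pd.Series            # importance, descending
    panel: list[str]
    cv_auc: float                 # out-of-fold AUC within the training split
    test_auc: float               # single evaluation on the held-out third
    seed: int


def rf_select_panel(
    table: FeatureTable,
    labels,
    train_frac: float = 2.0 / 3.0,
    folds: int = 7,
    panel_size: int = 10,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> PanelSelection:
    """Random-forest biomarker-panel selection with an honest test split.

    Subjects are split stratified into a ``train_frac`` training set and
    a held-out test set.  Within the training set, features are ranked
    by mean impurity importance over ``folds`` stratified folds; the top
    ``panel_size`` features form the panel.  The test AUC is computed
    once, from a forest trained on the full training split restricted to
    the panel and applied to the untouched test split.
    """
    feature_ids = list(table.feature_ids)
    if panel_size > len(feature_ids):
        raise ValueError(
            f"panel_size={panel_size} exceeds candidate count {len(feature_ids)}"
        )
    X = _log2_matrix(table, feature_ids)
    y = _binary_labels(labels)
    idx = np.arange(y.size)
    tr_idx, te_idx = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed
    )
    Xtr, ytr = X[tr_idx], y[tr_idx]

    folds_eff = min(folds, int(np.bincount(ytr).min()))
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    importances = np.zeros(len(feature_ids))
    for k, (a, _) in enumerate(skf.split(Xtr, ytr)):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + k)
        rf.fit(Xtr[a], ytr[a])
        importances += rf.feature_importances_
    importances /= folds_eff
    ranking = pd.Series(importances, index=feature_ids).sort_values(ascending=False)
    panel = ranking.index[:panel_size].tolist()
    cols = [feature_ids.index(f) for f in panel]

    # out-of-fold AUC within the training split, panel features only
    oof = np.empty(ytr.size)
    for k, (a, b) in enumerate(skf.split(Xtr, ytr)):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + 100 + k)
        rf.fit(Xtr[a][:, cols], ytr[a])
        oof[b] = rf.predict_proba(Xtr[b][:, cols])[:, list(rf.classes_).index(1)]
    cv_auc = roc_auc(oof, ytr, orient=False).auc

    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + 999)
    rf.fit(Xtr[:, cols], ytr)
    test_scores = rf.predict_proba(X[te_idx][:, cols])[:, list(rf.classes_).index(1)]
    test_auc = roc_auc(test_scores, y[te_idx], orient=False).auc
    return PanelSelection(
        ranking=ranking, panel=panel, cv_auc=cv_auc, test_auc=test_auc, seed=seed
    )
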
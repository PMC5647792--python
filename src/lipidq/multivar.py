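"""Scaling, PCA, and NIPALS PLS-DA with VIP and permutation validation.

The discriminant model is exposed statsmodels-style: build a
:class:`PLSDA` model from a scaled matrix and binary labels, call
``fit()`` to obtain a :class:`PLSDAResults` carrying weights, scores,
R²Y, VIP, and methods for cross-validated Q², the label-permutation
null, and a text ``summary()``.  Thin functional wrappers
(:func:`plsda_fit`, :func:`vip`, :func:`plsda_cv_q2`,
:func:`permutation_test`) cover the same operations.

Scaling is log2 + Pareto (center, divide by the square root of the
column SD): heavy lipid features are tempered without being flattened
to unit variance.  Inside cross-validation the scaling is refit on each
training fold so held-out injections never leak into the centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .tableio import FeatureTable

__all__ = [
    "ScaledMatrix",
    "PcaResult",
    "PLSDA",
    "PLSDAResults",
    "PermutationSummary",
    "log2_pareto",
    "pca",
    "plsda_fit",
    "plsda_cv_q2",
    "vip",
    "permutation_test",
    "encode_labels",
]


# ----------------------------------------------------------------- scaling

@dataclass
class ScaledMatrix:
    """Injections × features matrix after log2 + Pareto scaling."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    means: np.ndarray
    pareto_divisors: np.ndarray
    transform: str = "log2+pareto"


def _pareto_fit(logx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = logx.mean(axis=0)
    sds = logx.std(axis=0, ddof=1)
    return means, np.sqrt(sds)


def log2_pareto(table: FeatureTable | pd.DataFrame, already_log: bool = False) -> ScaledMatrix:
    """log2-transform, column-center and Pareto-scale a feature table.

    Input orientation is features × injections (the table convention);
    output is injections × features for modelling.  Raises on
    nonpositive intensities or a zero-variance feature.
    """
    if isinstance(table, FeatureTable):
        df = table.intensities
    else:
        df = table
    vals = df.to_numpy(dtype=float).T      # injections x features
    if np.isnan(vals).any():
        raise ValueError("scaling requires a complete (imputed) table")
    if not already_log:
        if np.any(vals <= 0):
            raise ValueError("nonpositive intensity: log2 transform undefined")
        vals = np.log2(vals)
    means, divisors = _pareto_fit(vals)
    zero = divisors == 0
    if zero.any():
        bad = [fid for fid, z in zip(df.index, zero) if z]
        raise ValueError(f"zero variance feature(s): {bad[:5]}")
    scaled = (vals - means) / divisors
    return ScaledMatrix(
        values=scaled,
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        means=means,
        pareto_divisors=divisors,
    )


# ----------------------------------------------------------------- PCA

@dataclass
class PcaResult:
    scores: np.ndarray          # samples x A
    loadings: np.ndarray        # features x A
    explained_variance_ratio: np.ndarray


def pca(X: ScaledMatrix | np.ndarray, n_comp: int = 2) -> PcaResult:
    """PCA by SVD of the (already centered) matrix.

    Deterministic sign convention: each component is flipped so its
    largest-magnitude loading is positive.
    """
    vals = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
    vals = vals - vals.mean(axis=0)
    if n_comp > min(vals.shape):
        raise ValueError(f"n_comp={n_comp} exceeds matrix rank bound {min(vals.shape)}")
    u, s, vt = np.linalg.svd(vals, full_matrices=False)
    loadings = vt[:n_comp].T
    scores = u[:, :n_comp] * s[:n_comp]
    for a in range(n_comp):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    total_var = np.sum(s**2)
    evr = (s[:n_comp] ** 2) / total_var if total_var > 0 else np.zeros(n_comp)
    return PcaResult(scores=scores, loadings=loadings, explained_variance_ratio=evr)


# ----------------------------------------------------------------- PLS-DA

def encode_labels(y) -> tuple[np.ndarray, list]:
    """Binary labels → 0/1 floats; returns (codes, class order)."""
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"PLS-DA requires exactly two classes, got {classes}")
    return (y == classes[1]).astype(float), classes


def _nipals(X: np.ndarray, y_centered: np.ndarray, A: int):
    """Single-response NIPALS with X and y deflation."""
    Xd = X.copy()
    yd = y_centered.copy()
    n, p = X.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    c = np.zeros(A)
    for a in range(A):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(f"degenerate component {a + 1}: X'y vanished")
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        ca = float(t @ yd) / tt
        pa = Xd.T @ t / tt
        Xd -= np.outer(t, pa)
        yd = yd - ca * t
        W[:, a], P[:, a], T[:, a], c[a] = w, pa, t, ca
    return W, P, T, c


class PLSDA:
    """Two-class PLS-DA model on a scaled matrix.

    Parameters
    ----------
    X : ScaledMatrix or ndarray
        Injections × features, already centered/scaled.
    y : array-like
        Two class labels (any hashable pair); encoded 0/1 then centered.
    n_components : int
        Number of latent components (default 2).
    """

    def __init__(self, X: ScaledMatrix | np.ndarray, y, n_components: int = 2):
        self.X = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
        self.feature_ids = (
            X.feature_ids if isinstance(X, ScaledMatrix) else
            [f"x{i}" for i in range(self.X.shape[1])]
        )
        self.y_codes, self.classes_ = encode_labels(y)
        counts = [int((self.y_codes == v).sum()) for v in (0.0, 1.0)]
        if min(counts) < 2:
            raise ValueError("each class needs at least two samples")
        self.n_components = int(n_components)

    def fit(self) -> "PLSDAResults":
        y_mean = self.y_codes.mean()
        yc = self.y_codes - y_mean
        W, P, T, c = _nipals(self.X, yc, self.n_components)
        y_hat = T @ c
        rss = float(np.sum((yc - y_hat) ** 2))
        tss = float(np.sum(yc**2))
        r2y = 1.0 - rss / tss
        x_tss = float(np.sum(self.X**2))
        r2x = float(np.sum((T**2).sum(axis=0) * (P**2).sum(axis=0))) / x_tss
        return PLSDAResults(
            model=self, W=W, P=P, T=T, c=c, y_mean=y_mean, R2Y=r2y, R2X=r2x
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA: weights, loadings, scores, fit statistics, VIP."""

    model: PLSDA
    W: np.ndarray       # features x A, unit columns
    P: np.ndarray       # features x A
    T: np.ndarray       # samples x A, mutually orthogonal
    c: np.ndarray       # y-loadings, length A
    y_mean: float
    R2Y: float
    R2X: float

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def coefficients(self) -> np.ndarray:
        """Regression vector B with ŷ_centered = X @ B."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, np.atleast_1d(self.c))

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Predicted (uncentered) class code for scaled new data."""
        return self.y_mean + np.asarray(X_new, dtype=float) @ self.coefficients()

    def vip(self) -> np.ndarray:
        """Variable importance in projection.

        VIP_j = sqrt(p · Σ_a SSY_a w_aj² / Σ_a SSY_a) with
        SSY_a = c_a² t_a·t_a; mean of VIP² over features is exactly 1.
        """
        ssy = self.c**2 * (self.T**2).sum(axis=0)
        p = self.W.shape[0]
        num = (self.W**2) @ ssy
        return np.sqrt(p * num / ssy.sum())

    def cv_q2(self, folds: int = 7, seed: int = 0,
              raw_X: np.ndarray | None = None) -> float:
        """Stratified k-fold cross-validated Q² (see :func:`plsda_cv_q2`)."""
        X = raw_X if raw_X is not None else self.model.X
        return plsda_cv_q2(
            X, self.model.y_codes, self.n_components, folds=folds, seed=seed,
            rescale=raw_X is not None,
        )

    def permutation_test(self, n_perm: int = 200, folds: int = 7, seed: int = 0,
                         raw_X: np.ndarray | None = None) -> "PermutationSummary":
        X = raw_X if raw_X is not None else self.model.X
        return permutation_test(
            X, self.model.y_codes, self.n_components, n_perm=n_perm,
            folds=folds, seed=seed, rescale=raw_X is not None,
        )

    def summary(self) -> str:
        q2 = self.cv_q2()
        lines = [
            "PLS-DA results",
            "=" * 46,
            f"classes:        {self.model.classes_[0]} (0) vs {self.model.classes_[1]} (1)",
            f"n samples:      {self.T.shape[0]}",
            f"n features:     {self.W.shape[0]}",
            f"components:     {self.n_components}",
            f"R2X:            {self.R2X:.3f}",
            f"R2Y:            {self.R2Y:.3f}",
            f"Q2 (7-fold CV): {q2:.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)


def plsda_fit(X: ScaledMatrix | np.ndarray, y, A: int = 2) -> PLSDAResults:
    """Fit a two-class PLS-DA with A NIPALS components."""
    return PLSDA(X, y, n_components=A).fit()


def _scale_train_test(Xtr, Xte, rescale):
    if not rescale:
        return Xtr, Xte
    means, div = _pareto_fit(Xtr)
    div = div.clip(min=1e-12)
    return (Xtr - means) / div, (Xte - means) / div


def plsda_cv_q2(
    X: ScaledMatrix | np.ndarray, y, A: int = 2, folds: int = 7, seed: int = 0,
    rescale: bool = False,
) -> float:
    """Cumulative Q² from stratified k-fold held-out predictions.

    Q² = 1 − PRESS/TSS, PRESS summed over held-out injections (target
    centered by the training-fold mean).  With ``rescale=True`` the
    input is unscaled log2 data and Pareto scaling is refit per training
    fold (no leakage).
    """
    vals = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
    y_codes, _ = encode_labels(y) if not _is_codes(y) else (np.asarray(y, float), None)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    folds = min(folds, int(np.bincount(y_codes.astype(int)).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for tr, te in skf.split(vals, y_codes):
        ytr = y_codes[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError("a training fold lost a class; reduce folds")
        Xtr, Xte = _scale_train_test(vals[tr], vals[te], rescale)
        ytr_mean = ytr.mean()
        W, P, T, c = _nipals(Xtr, ytr - ytr_mean, A)
        B = W @ np.linalg.solve(P.T @ W, np.atleast_1d(c))
        y_pred = Xte @ B
        press += float(np.sum(((y_codes[te] - ytr_mean) - y_pred) ** 2))
    tss = float(np.sum((y_codes - y_codes.mean()) ** 2))
    return 1.0 - press / tss


def _is_codes(y) -> bool:
    arr = np.asarray(y)
    return arr.dtype.kind == "f" and set(np.unique(arr)) <= {0.0, 1.0}


def vip(results: PLSDAResults) -> np.ndarray:
    """Functional alias for :meth:`PLSDAResults.vip`."""
    return results.vip()


@dataclass
class PermutationSummary:
    """Observed R²Y/Q² against their label-permutation nulls."""

    observed_r2y: float
    observed_q2: float
    null_r2y: np.ndarray
    null_q2: np.ndarray
    p_r2y: float
    p_q2: float


def permutation_test(
    X: ScaledMatrix | np.ndarray, y, A: int = 2, n_perm: int = 200,
    folds: int = 7, seed: int = 0, rescale: bool = False,
) -> PermutationSummary:
    """Label-permutation null for R²Y and Q².

    Empirical p = (1 + #{null ≥ observed}) / (n_perm + 1).
    """
    vals = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
    y_codes, _ = encode_labels(y) if not _is_codes(y) else (np.asarray(y, float), None)
    rng = np.random.default_rng(seed)

    def _r2y(Xv, yv):
        scaled = Xv
        if rescale:
            means, div = _pareto_fit(Xv)
            scaled = (Xv - means) / div.clip(min=1e-12)
        yc = yv - yv.mean()
        W, P, T, c = _nipals(scaled, yc, A)
        y_hat = T @ c
        return 1.0 - float(np.sum((yc - y_hat) ** 2)) / float(np.sum(yc**2))

    obs_r2y = _r2y(vals, y_codes)
    obs_q2 = plsda_cv_q2(vals, y_codes, A, folds=folds, seed=seed, rescale=rescale)
    null_r2y = np.empty(n_perm)
    null_q2 = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y_codes)
        null_r2y[i] = _r2y(vals, yp)
        null_q2[i] = plsda_cv_q2(
            vals, yp, A, folds=folds, seed=int(rng.integers(2**31)), rescale=rescale
        )
    p_r2y = (1.0 + np.sum(null_r2y >= obs_r2y)) / (n_perm + 1.0)
    p_q2 = (1.0 + np.sum(null_q2 >= obs_q2)) / (n_perm + 1.0)
    return PermutationSummary(
        observed_r2y=obs_r2y, observed_q2=obs_q2,
        null_r2y=null_r2y, null_q2=null_q2, p_r2y=p_r2y, p_q2=p_q2,
    )
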
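"""High-content-screening profile analysis.

The morphological profile matrix (cells x features) is Z-score normalized,
reduced by factor analysis retaining a target fraction (default 80%) of
total variance, and the factor scores are classified by linear
discriminant analysis (LDA).  A biplot-style attribution then ranks, for
every pair of classes, the factors whose coefficient vectors align with
the centroid-difference direction in discriminant space — i.e. the
factors that stand perpendicular to the separating boundary and drive
that separation.

Factor extraction is principal-axis factoring (iterated communalities on
the reduced correlation matrix, no rotation); the factor count is the
smallest k whose leading correlation-matrix eigenvalues sum to the
variance target.  Scores follow Thurstone's regression method.  The
estimators are sklearn-compatible (``fit``/``transform``/``get_params``)
and compose with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict


def zscore_normalize(matrix) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise (x - mean) / SD; constant columns are dropped.

    Returns ``(normalized, dropped_columns)``.  Raises on fewer than two
    rows (the SD is undefined).  Idempotent on already-normalized input.
    """
    df = pd.DataFrame(matrix).copy()
    if len(df) < 2:
        raise ValueError("Z-score normalization needs at least 2 rows")
    sd = df.std(axis=0, ddof=1)
    dropped = list(df.columns[(sd == 0) | sd.isna()])
    kept = df.drop(columns=dropped)
    out = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    return out, dropped


class FactorReducer(BaseEstimator, TransformerMixin):
    """Principal-axis factor analysis keeping >= ``variance_target`` of
    total variance.

    Parameters
    ----------
    variance_target : float in (0, 1]
        Smallest factor count is chosen whose leading eigenvalues of the
        feature correlation matrix sum to at least this fraction of the
        total variance.
    n_factors : int, optional
        Overrides the variance-based choice.
    max_iter, tol : communality iteration controls.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : (n_features, n_factors) factor loading matrix.
    n_factors_ : selected factor count.
    eigenvalues_ : correlation-matrix spectrum (descending).
    variance_explained_ratio_ : per-factor share of total variance
        (from the selection spectrum).
    total_variance_fraction_ : cumulative share at ``n_factors_``.
    communalities_ : final per-feature communalities.
    """

    def __init__(self, variance_target: float = 0.80,
                 n_factors: int | None = None,
                 max_iter: int = 200, tol: float = 1e-5):
        self.variance_target = variance_target
        self.n_factors = n_factors
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        if not (0.0 < self.variance_target <= 1.0):
            raise ValueError("variance_target must lie in (0, 1]")
        X = self._validate(X)
        n, p = X.shape
        corr = np.corrcoef(X, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        self.eigenvalues_ = evals
        cum = np.cumsum(np.clip(evals, 0.0, None)) / p
        if self.n_factors is not None:
            k = int(self.n_factors)
        else:
            k = int(np.searchsorted(cum, self.variance_target - 1e-12) + 1)
            k = min(k, p)
        # principal-axis iteration: SMC-initialized communalities
        try:
            inv = np.linalg.inv(corr + 1e-10 * np.eye(p))
            h2 = 1.0 - 1.0 / np.diag(inv)
        except np.linalg.LinAlgError:
            h2 = np.max(np.abs(corr - np.eye(p)), axis=0)
        h2 = np.clip(h2, 0.0, 0.999)
        loadings = None
        for _ in range(self.max_iter):
            red = corr.copy()
            np.fill_diagonal(red, h2)
            w, v = np.linalg.eigh(red)
            idx = np.argsort(w)[::-1][:k]
            lam = np.clip(w[idx], 0.0, None)
            loadings = v[:, idx] * np.sqrt(lam)
            h2_new = np.clip((loadings ** 2).sum(axis=1), 0.0, 0.999)
            if np.max(np.abs(h2_new - h2)) < self.tol:
                h2 = h2_new
                break
            h2 = h2_new
        # sign convention: largest-magnitude loading positive per factor
        signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                                 np.arange(k)])
        signs[signs == 0] = 1.0
        loadings = loadings * signs
        self.loadings_ = loadings
        self.n_factors_ = k
        self.communalities_ = h2
        self.variance_explained_ratio_ = np.clip(evals[:k], 0, None) / p
        self.total_variance_fraction_ = float(cum[k - 1])
        self._corr = corr
        self._mean = X.mean(axis=0)
        self._sd = X.std(axis=0, ddof=1)
        return self

    def transform(self, X):
        """Thurstone regression factor scores, (n_samples, n_factors)."""
        X = self._validate(X)
        z = (X - self._mean) / self._sd
        weights = np.linalg.pinv(self._corr) @ self.loadings_
        return z @ weights

    def _validate(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2D with at least 2 rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X


def factor_reduce(matrix, variance_target: float = 0.80) -> FactorReducer:
    """Fit a :class:`FactorReducer` on a normalized profile matrix."""
    return FactorReducer(variance_target=variance_target).fit(matrix)


def simulate_factor_data(loadings: np.ndarray, n_samples: int,
                         noise_sd: float = 0.3,
                         seed: int = 0) -> np.ndarray:
    """Draw samples from the common-factor model ``x = L f + e``."""
    rng = np.random.default_rng(seed)
    p, k = np.asarray(loadings).shape
    f = rng.standard_normal((n_samples, k))
    e = noise_sd * rng.standard_normal((n_samples, p))
    return f @ np.asarray(loadings).T + e


def loading_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Mean Tucker congruence between two loading matrices.

    Factors are matched by maximum |congruence| (Hungarian assignment);
    signs are ignored.  1.0 means identical factor structure.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na = a / np.linalg.norm(a, axis=0, keepdims=True)
    nb = b / np.linalg.norm(b, axis=0, keepdims=True)
    c = np.abs(na.T @ nb)
    r, cidx = linear_sum_assignment(-c)
    return float(c[r, cidx].mean())


@dataclass
class LDAResult:
    """Fitted discriminant model with cross-validated classification."""

    model: LinearDiscriminantAnalysis
    classes: np.ndarray
    scores: np.ndarray                  # (n_samples, n_axes)
    coefficients: np.ndarray            # (n_factors, n_axes) scalings
    confusion: np.ndarray               # held-out confusion matrix
    accuracy: float                     # held-out accuracy
    recall_per_class: pd.Series
    n_splits: int

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def lda_fit(scores, labels, n_splits: int = 5, seed: int = 0) -> LDAResult:
    """LDA on factor scores with stratified k-fold held-out evaluation.

    The discriminant axes (at most n_groups - 1) come from a fit on all
    cells; the confusion matrix and accuracy come from stratified
    ``n_splits``-fold cross-validated predictions, so they estimate
    held-out performance.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two cells")
    model = LinearDiscriminantAnalysis(solver="svd")
    model.fit(X, y)
    proj = model.transform(X)
    splits = min(n_splits, counts.min())
    cv = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
    pred = cross_val_predict(LinearDiscriminantAnalysis(solver="svd"),
                             X, y, cv=cv)
    conf = confusion_matrix(y, pred, labels=classes)
    acc = float(np.trace(conf) / conf.sum())
    recall = pd.Series(np.diag(conf) / conf.sum(axis=1), index=classes)
    return LDAResult(model, classes, proj, model.scalings_[:, :proj.shape[1]],
                     conf, acc, recall, splits)


def biplot_attribution(result: LDAResult,
                       axes: tuple[int, int] = (0, 1)) -> pd.DataFrame:
    """Rank factors by alignment with each class pair's separation.

    For each pair of classes the separating direction is the difference
    of class centroids in the plotted discriminant plane; factors are
    ranked by |cos| of the angle between their coefficient vector and
    that direction.  Pairs with coincident centroids are skipped.
    """
    if result.n_axes < 2:
        raise ValueError("biplot attribution needs two discriminant axes")
    a0, a1 = axes
    coef = result.coefficients[:, [a0, a1]]
    # centroids: class means projected on the plotted discriminant plane
    # (the svd solver centers on xbar_ before applying the scalings)
    centroids = {}
    xbar = result.model.xbar_ if hasattr(result.model, "xbar_") else 0.0
    means = (result.model.means_ - xbar) @ \
        result.model.scalings_[:, :result.n_axes]
    for cls, m in zip(result.model.classes_, means):
        centroids[cls] = m[[a0, a1]]
    norms = np.linalg.norm(coef, axis=1)
    rows = []
    for i, ca in enumerate(result.classes):
        for cb in result.classes[i + 1:]:
            d = centroids[ca] - centroids[cb]
            nd = np.linalg.norm(d)
            if nd < 1e-12:
                continue
            with np.errstate(invalid="ignore"):
                cosines = np.abs(coef @ d) / (norms * nd)
            cosines = np.nan_to_num(cosines)
            order = np.argsort(-cosines)
            for rank, j in enumerate(order):
                rows.append({"class_a": ca, "class_b": cb,
                             "factor": int(j), "cos": float(cosines[j]),
                             "rank": rank})
    return pd.DataFrame(rows)
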
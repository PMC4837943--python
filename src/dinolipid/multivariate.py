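"""Group discovery and marker selection for compositional lipid profiles.

Estimators follow the scikit-learn protocol (``fit`` / ``transform`` /
``get_params``; fitted attributes end in an underscore) and compose with
sklearn pipelines:

* :class:`ParetoScaler` — log10(x·100 + 1) then mean-centering and
  division by the square root of the standard deviation, the standard
  metabolomics variance-stabilising preprocessing.
* :class:`PCAModel` — principal component analysis with per-component
  explained X-variance (R²X) and a deterministic sign convention.
* :class:`PLSDA` — partial least squares discriminant analysis (NIPALS),
  with cross-validated Q² (venetian-blind folds) and a label-permutation
  significance test.
* :class:`OPLSDA` — orthogonal PLS-DA: orthogonal variation is filtered
  from X before a single predictive component is fitted; per-variable
  p(corr) is the Pearson correlation between the predictive score and
  the variable.

The latent-variable algebra is implemented here rather than delegated,
so the cross-validation and permutation machinery can reach inside the
deflation loop.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "ParetoScaler",
    "PCAModel",
    "PLSDA",
    "OPLSDA",
    "welch_test",
    "select_markers",
    "preprocess",
]

_EPS = 1e-12


class ParetoScaler(TransformerMixin, BaseEstimator):
    """log(x+1) transform (base 10, percentage scale) plus Pareto scaling.

    Parameters
    ----------
    log_transform : bool
        Apply ``log10(percent_factor * x + 1)`` before scaling.
    percent_factor : float
        Factor taking the input onto the percentage scale; 100 for
        fractional relative areas, 1 for data already in percent.
    drop_zero_variance : bool
        Drop constant columns (they carry no discriminant information
        and break the scaling); a warning lists them.
    """

    def __init__(
        self,
        log_transform: bool = True,
        percent_factor: float = 100.0,
        drop_zero_variance: bool = True,
    ):
        self.log_transform = log_transform
        self.percent_factor = percent_factor
        self.drop_zero_variance = drop_zero_variance

    def _log(self, X: np.ndarray) -> np.ndarray:
        if not self.log_transform:
            return X
        if (X < 0).any():
            raise ValueError("log(x+1) preprocessing requires non-negative input")
        return np.log10(self.percent_factor * X + 1.0)

    def fit(self, X, y=None) -> "ParetoScaler":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, dtype=float)
        Xl = self._log(X)
        sd = Xl.std(axis=0, ddof=1)
        keep = sd > _EPS
        if not keep.any():
            raise ValueError("all columns have zero variance")
        if self.drop_zero_variance and not keep.all():
            dropped = np.flatnonzero(~keep)
            warnings.warn(
                f"dropping {len(dropped)} zero-variance column(s): {dropped.tolist()}",
                UserWarning,
                stacklevel=2,
            )
        elif not self.drop_zero_variance:
            keep = np.ones_like(keep, dtype=bool)
        self.keep_mask_ = keep
        self.mean_ = Xl[:, keep].mean(axis=0)
        self.scale_ = np.sqrt(np.maximum(sd[keep], _EPS))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float)
        Xl = self._log(X)[:, self.keep_mask_]
        return (Xl - self.mean_) / self.scale_

    def inverse_transform(self, Xt) -> np.ndarray:
        check_is_fitted(self, "mean_")
        Xl = np.asarray(Xt) * self.scale_ + self.mean_
        if not self.log_transform:
            return Xl
        return (10.0 ** Xl - 1.0) / self.percent_factor

    def kept_feature_names(self) -> Optional[np.ndarray]:
        check_is_fitted(self, "mean_")
        names = getattr(self, "feature_names_in_", None)
        return None if names is None else names[self.keep_mask_]


def preprocess(table) -> tuple[np.ndarray, ParetoScaler]:
    """Convenience wrapper: fit a :class:`ParetoScaler` and transform.

    Accepts a feature table object (with ``.data``) or a DataFrame/array
    of non-negative fractions.
    """
    X = getattr(table, "data", table)
    scaler = ParetoScaler().fit(X)
    return scaler.transform(X), scaler


def _fix_signs(loadings: np.ndarray, *score_mats: np.ndarray) -> None:
    """Make the largest-|loading| element of each component positive."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            for m in score_mats:
                m[:, a] *= -1


class PCAModel(TransformerMixin, BaseEstimator):
    """PCA via SVD with explained-variance bookkeeping.

    Deterministic (seed-free); component signs are fixed so the largest
    absolute loading of each component is positive.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "PCAModel":
        X = check_array(X, dtype=float)
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n-1, p)={min(n - 1, p)}"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        k = self.n_components
        self.loadings_ = Vt[:k].T.copy()
        self.scores_ = (U[:, :k] * s[:k]).copy()
        total = float((Xc**2).sum())
        self.r2x_ = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
        _fix_signs(self.loadings_, self.scores_)
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) @ self.loadings_

    @property
    def r2x_cumulative_(self) -> float:
        return float(np.sum(self.r2x_))


# ---------------------------------------------------------------------------
# PLS core (NIPALS, univariate response)


def _pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """Sequential PLS1: returns weights W, loadings P, y-loadings c, scores T."""
    Xd = X.copy()
    W, P, C, T = [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        p = Xd.T @ t / tt
        c = float(y @ t) / tt
        Xd -= np.outer(t, p)
        W.append(w)
        P.append(p)
        C.append(c)
        T.append(t)
    if not W:
        raise ValueError("PLS found no informative component")
    return (np.column_stack(W), np.column_stack(P), np.asarray(C), np.column_stack(T))


def _pls1_coef(W: np.ndarray, P: np.ndarray, C: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, C)


def _venetian_folds(y01: np.ndarray, n_folds: int) -> np.ndarray:
    """Stratified venetian-blind fold assignment.

    Samples are ordered by class and dealt round-robin into folds, so
    every training set retains both classes whenever each class has at
    least two members; folds are reduced otherwise.
    """
    n = len(y01)
    n_folds = int(min(n_folds, n))
    # class-sorted round-robin dealing spreads each class over
    # min(count, n_folds) consecutive folds, so no fold can swallow a
    # class whole once both classes have >= 2 members
    order = np.argsort(y01, kind="stable")
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds
    return folds


def _q2(X: np.ndarray, y01: np.ndarray, n_components: int, n_folds: int) -> float:
    """1 − PRESS/SS from venetian-blind cross-validation of PLS1."""
    folds = _venetian_folds(y01, n_folds)
    yc_all = y01 - y01.mean()
    ss = float(yc_all @ yc_all)
    press = 0.0
    for f in np.unique(folds):
        test = folds == f
        Xtr, ytr = X[~test], y01[~test]
        if len(np.unique(ytr)) < 2:
            raise ValueError("a CV fold lost an entire class; use fewer folds")
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        try:
            W, P, C, _ = _pls1(Xtr - xm, ytr - ym, n_components)
            b = _pls1_coef(W, P, C)
            pred = (X[test] - xm) @ b + ym
        except ValueError:
            pred = np.full(test.sum(), ym)
        press += float(((y01[test] - pred) ** 2).sum())
    return 1.0 - press / ss


class PLSDA(ClassifierMixin, BaseEstimator):
    """Two-class PLS discriminant analysis with Q² and permutation test.

    Parameters
    ----------
    n_components : int
        Latent components fitted (default 2).
    cv_folds : int
        Venetian-blind folds for Q² (default 7).
    n_permutations : int
        Label permutations for the significance of Q²; the p-value uses
        the (1+b)/(1+m) estimator and is therefore never 0.
    random_state : int or None
        Seed for the permutation draw.

    Attributes (after fit)
    ----------------------
    scores_, loadings_, weights_ : latent-space matrices
    r2x_ : per-component fraction of X variance explained
    q2_ : cross-validated predictive fraction (1 − PRESS/SS)
    permutation_p_ : permutation p-value of q2_
    """

    def __init__(
        self,
        n_components: int = 2,
        cv_folds: int = 7,
        n_permutations: int = 200,
        random_state: Optional[int] = None,
    ):
        self.n_components = n_components
        self.cv_folds = cv_folds
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"PLS-DA needs exactly 2 classes, got {len(self.classes_)}")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 2:
            raise ValueError("each class needs at least 2 samples")
        return (y == self.classes_[1]).astype(float)

    def fit(self, X, y) -> "PLSDA":
        X = check_array(X, dtype=float)
        y01 = self._encode(y)
        self._x_mean_ = X.mean(axis=0)
        self._y_mean_ = y01.mean()
        Xc = X - self._x_mean_
        yc = y01 - self._y_mean_
        W, P, C, T = _pls1(Xc, yc, self.n_components)
        self.weights_, self.loadings_, self.y_loadings_, self.scores_ = W, P, C, T
        self.coef_ = _pls1_coef(W, P, C)
        ssx = float((Xc**2).sum())
        self.r2x_ = np.array(
            [float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a]) / ssx
             for a in range(T.shape[1])]
        )
        self.q2_ = _q2(X, y01, self.n_components, self.cv_folds)
        if self.n_permutations > 0:
            rng = np.random.default_rng(self.random_state)
            b = 0
            for _ in range(self.n_permutations):
                yp = rng.permutation(y01)
                if yp.min() == yp.max():  # cannot happen for 2 real classes
                    continue
                if _q2(X, yp, self.n_components, self.cv_folds) >= self.q2_:
                    b += 1
            self.permutation_p_ = (1 + b) / (1 + self.n_permutations)
        else:
            self.permutation_p_ = np.nan
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return (X - self._x_mean_) @ self.coef_ + self._y_mean_

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) >= 0.5).astype(int)]


class OPLSDA(ClassifierMixin, BaseEstimator):
    """Orthogonal PLS-DA: 1 predictive + ``n_orthogonal`` orthogonal components.

    Variation in X orthogonal to the class contrast is removed before
    the single predictive component is fitted.  ``p_corr_`` holds, per
    variable of the (preprocessed) input, the Pearson correlation
    between the predictive score vector and that variable — the marker
    statistic thresholded at |p(corr)| ≥ 0.75 downstream.
    """

    def __init__(self, n_orthogonal: int = 1, random_state: Optional[int] = None):
        self.n_orthogonal = n_orthogonal
        self.random_state = random_state

    def fit(self, X, y) -> "OPLSDA":
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"OPLS-DA needs exactly 2 classes, got {len(self.classes_)}")
        y01 = (y == self.classes_[1]).astype(float)
        if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
            raise ValueError("each class needs at least 2 samples")
        self._x_mean_ = X.mean(axis=0)
        self._y_mean_ = y01.mean()
        Xc = X - self._x_mean_
        yc = y01 - self._y_mean_
        w = Xc.T @ yc
        w /= max(np.linalg.norm(w), _EPS)
        Xd = Xc.copy()
        T_o, P_o, W_o = [], [], []
        for _ in range(self.n_orthogonal):
            t = Xd @ w
            tt = float(t @ t)
            p = Xd.T @ t / max(tt, _EPS)
            w_o = p - float(w @ p) * w
            n_wo = np.linalg.norm(w_o)
            if n_wo < 1e-10:
                break  # no orthogonal variation left
            w_o /= n_wo
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / max(float(t_o @ t_o), _EPS)
            Xd = Xd - np.outer(t_o, p_o)
            T_o.append(t_o)
            P_o.append(p_o)
            W_o.append(w_o)
        W, P, C, T = _pls1(Xd, yc, 1)
        self.weights_ = W[:, 0]
        self.loadings_ = P[:, 0]
        self.y_loading_ = float(C[0])
        self.scores_ = T[:, 0]
        self.orthogonal_scores_ = np.column_stack(T_o) if T_o else np.empty((len(y), 0))
        self.orthogonal_loadings_ = np.column_stack(P_o) if P_o else np.empty((X.shape[1], 0))
        self.orthogonal_weights_ = np.column_stack(W_o) if W_o else np.empty((X.shape[1], 0))
        t_pred = self.scores_
        sd_t = t_pred.std(ddof=1)
        p_corr = np.zeros(X.shape[1])
        sd_x = Xc.std(axis=0, ddof=1)
        ok = (sd_x > _EPS) & (sd_t > _EPS)
        if ok.any():
            cov = (Xc[:, ok] * (t_pred - t_pred.mean())[:, None]).sum(axis=0) / (len(y) - 1)
            p_corr[ok] = cov / (sd_x[ok] * sd_t)
        self.p_corr_ = np.clip(p_corr, -1.0, 1.0)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        Xd = X - self._x_mean_
        for a in range(self.orthogonal_weights_.shape[1]):
            t_o = Xd @ self.orthogonal_weights_[:, a]
            Xd = Xd - np.outer(t_o, self.orthogonal_loadings_[:, a])
        t = Xd @ self.weights_
        return t * self.y_loading_ + self._y_mean_

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) >= 0.5).astype(int)]


def welch_test(g1: Sequence[float], g2: Sequence[float]) -> float:
    """Two-tailed Welch t-test p-value (unequal variances, Satterthwaite df).

    Degenerate case: if both groups are constant, p = 1 when the means
    coincide and p = 0 otherwise.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    if se2 < _EPS:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def select_markers(
    model: OPLSDA,
    X: pd.DataFrame,
    y: Sequence,
    p_corr_threshold: float = 0.75,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Marker table from a fitted OPLS-DA model plus per-variable Welch tests.

    ``X`` holds the original (pre-scaling) variable values used for the
    group means and Welch tests — typically percent relative areas.  A
    variable is a marker when |p(corr)| ≥ ``p_corr_threshold`` and its
    two-tailed Welch p < ``alpha``; ``characterizes`` names the group
    with the higher mean.
    """
    check_is_fitted(model, "p_corr_")
    if X.shape[1] != len(model.p_corr_):
        raise ValueError(
            "X must have the same variables (columns) the model was fitted on"
        )
    y = np.asarray(y)
    g1, g2 = model.classes_
    rows = []
    for j, col in enumerate(X.columns):
        v = X[col].to_numpy(dtype=float)
        m1, m2 = v[y == g1].mean(), v[y == g2].mean()
        p = welch_test(v[y == g1], v[y == g2])
        pc = float(model.p_corr_[j])
        rows.append(
            {
                "variable": col,
                "p_corr": pc,
                "welch_p": p,
                f"mean_{g1}": m1,
                f"mean_{g2}": m2,
                "characterizes": g1 if m1 > m2 else g2,
                "marker": bool(abs(pc) >= p_corr_threshold and p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
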
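"""Latent-variable models: NIPALS PCA, OPLS-DA, and multi-class PLS2-DA.

OPLS-DA splits the predictive variation of an autoscaled metabolite matrix
(the part correlated with the class label) from structured variation
orthogonal to it, yielding a single predictive component whose weights feed
the VIP (variable importance in projection) feature-refinement step. NIPALS
PCA is used for outlier screening via Hotelling T2; PLS2-DA on a class
indicator matrix handles the multi-class stage model.

All estimators follow the scikit-learn API (fit / predict or transform,
get_params / set_params, trailing-underscore fitted attributes) so they can
be cloned and cross-validated with the standard machinery.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin


def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), np.asarray(X.columns), np.asarray(X.index)
    X = np.asarray(X, dtype=float)
    return X, np.arange(X.shape[1]), np.arange(X.shape[0])


class NipalsPCA(BaseEstimator, TransformerMixin):
    """Principal component analysis by NIPALS iteration.

    NIPALS extracts components one at a time by alternating score/loading
    regressions, which makes it tolerant of missing cells (regressions use
    only the observed entries of each row/column). Intended for exploratory
    outlier screening, so components default to at most three.

    Parameters
    ----------
    n_components : int
        Number of components to extract (capped at min(n-1, p)).
    missing_allowed : bool
        Permit NaN cells; when False, NaN raises.
    tol, max_iter : float, int
        Relative convergence tolerance on the score vector and the iteration
        cap. Nearly degenerate eigenvalues slow the power iteration, so the
        cap is generous; each iteration is only two matrix-vector products.
    """

    def __init__(self, n_components: int = 3, missing_allowed: bool = False,
                 tol: float = 1e-12, max_iter: int = 200_000):
        self.n_components = n_components
        self.missing_allowed = missing_allowed
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        Xa, cols, idx = _as_array(X)
        if np.isnan(Xa).any() and not self.missing_allowed:
            raise ValueError("missing values present and missing_allowed=False")
        self.feature_names_in_ = cols
        n, p = Xa.shape
        k = min(self.n_components, n - 1, p)
        mask = ~np.isnan(Xa)
        R = np.where(mask, Xa, 0.0)
        ss_total = float(np.sum(R**2))
        scores, loadings, r2x = [], [], []
        for _ in range(k):
            # start from the column with the largest sum of squares
            j = int(np.argmax(np.sum(R**2, axis=0)))
            t = R[:, j].copy()
            if np.allclose(t, 0):
                break
            if mask.all():
                # complete data: the score direction follows power iteration
                # on the Gram matrix, so iterate there (O(n^2) per step)
                G = R @ R.T
                u = t / np.linalg.norm(t)
                for it in range(self.max_iter):
                    u_new = G @ u
                    u_new /= np.linalg.norm(u_new)
                    if np.linalg.norm(u_new - u) <= self.tol:
                        u = u_new
                        break
                    u = u_new
                else:
                    raise RuntimeError(
                        f"NIPALS PCA failed to converge within {self.max_iter} "
                        f"iterations (relative score change still above tol={self.tol})"
                    )
                pvec = R.T @ u
                pvec /= np.linalg.norm(pvec)
                t = R @ pvec
            else:
                for it in range(self.max_iter):
                    denom = mask.T @ (t**2)
                    denom[denom == 0] = np.finfo(float).eps
                    pvec = (R.T @ t) / denom
                    pvec /= np.linalg.norm(pvec)
                    denom_t = mask @ (pvec**2)
                    denom_t[denom_t == 0] = np.finfo(float).eps
                    t_new = (R @ pvec) / denom_t
                    if np.linalg.norm(t_new - t) <= self.tol * np.linalg.norm(t_new):
                        t = t_new
                        break
                    t = t_new
                else:
                    raise RuntimeError(
                        f"NIPALS PCA failed to converge within {self.max_iter} iterations "
                        f"(relative score change still above tol={self.tol})"
                    )
            R = R - np.where(mask, np.outer(t, pvec), 0.0)
            scores.append(t)
            loadings.append(pvec)
            r2x.append(1.0 - float(np.sum(R**2)) / ss_total)
        self.scores_ = np.column_stack(scores) if scores else np.empty((n, 0))
        self.loadings_ = np.column_stack(loadings) if loadings else np.empty((p, 0))
        self.explained_r2x_ = np.asarray(r2x)
        self.n_samples_ = n
        self.hotelling_t2_ = self._t2(self.scores_)
        return self

    def _t2(self, T: np.ndarray) -> np.ndarray:
        if T.shape[1] == 0:
            return np.zeros(T.shape[0])
        lam = np.sum(T**2, axis=0) / (self.n_samples_ - 1)
        return np.sum(T**2 / lam, axis=1)

    def transform(self, X):
        Xa, _, _ = _as_array(X)
        return Xa @ self.loadings_

    def t2_critical(self, level: float = 0.99) -> float:
        """F-based Hotelling T2 limit at the given confidence level."""
        if not 0.0 < level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        n, a = self.n_samples_, self.scores_.shape[1]
        f = stats.f.ppf(level, a, n - a)
        return a * (n - 1) * (n + 1) / (n * (n - a)) * f


def hotelling_outliers(model: NipalsPCA, sample_ids=None, level: float = 0.99) -> list:
    """Sample ids whose Hotelling T2 exceeds the F-based limit at ``level``."""
    limit = model.t2_critical(level)
    flags = model.hotelling_t2_ > limit
    if sample_ids is None:
        sample_ids = np.arange(len(flags))
    return [s for s, f in zip(sample_ids, flags) if f]


class OPLSDA(BaseEstimator, ClassifierMixin):
    """Orthogonal PLS discriminant analysis for a two-class contrast.

    The class label is encoded {0, 1} and centered (not variance-scaled).
    Each orthogonal component captures X-variation uncorrelated with the
    label and is deflated before the single predictive component is fitted,
    so the predictive score t is orthogonal to every orthogonal score t_o.

    Parameters
    ----------
    n_orth : int or "auto"
        Number of orthogonal components. "auto" adds components while the
        7-fold cross-validated Q2Y improves by at least ``q2_gain_min``,
        capped at ``max_orth``.
    cv_folds, q2_gain_min, max_orth, random_state :
        Controls for the "auto" rule and its internal cross-validation.

    Attributes
    ----------
    weights_ : (p,) unit-norm predictive weight vector w.
    loadings_ : (p,) predictive X-loading p.
    scores_ : (n,) predictive score t.
    y_loading_ : scalar c with y_hat = t * c + y_mean.
    orth_weights_, orth_loadings_, orth_scores_ : orthogonal-component sets.
    r2y_ : fraction of label variance explained on the training data.
    vip_ : per-feature variable importance in projection (mean VIP^2 = 1).
    """

    def __init__(self, n_orth=1, cv_folds: int = 7, q2_gain_min: float = 0.01,
                 max_orth: int = 5, random_state: int = 0):
        self.n_orth = n_orth
        self.cv_folds = cv_folds
        self.q2_gain_min = q2_gain_min
        self.max_orth = max_orth
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        Xa, cols, _ = _as_array(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"OPLSDA requires exactly two classes, got {list(self.classes_)}")
        if min((y == c).sum() for c in self.classes_) < 2:
            raise ValueError("each class needs >= 2 samples")
        y01 = (y == self.classes_[1]).astype(float)
        self.feature_names_in_ = cols
        self.x_mean_ = Xa.mean(axis=0)
        self.y_mean_ = y01.mean()
        Xc = Xa - self.x_mean_
        yc = y01 - self.y_mean_

        if self.n_orth == "auto":
            n_orth = self._auto_n_orth(X, y)
        else:
            n_orth = int(self.n_orth)
        rank = np.linalg.matrix_rank(Xc)
        if n_orth >= rank:
            raise ValueError(f"n_orth={n_orth} must be < rank(X)={rank}")
        self._fit_core(Xc, yc, n_orth)
        self.n_orth_ = n_orth
        self.r2y_ = 1.0 - float(np.sum((yc - self.scores_ * self.y_loading_) ** 2)) / float(np.sum(yc**2))
        p_vars = Xc.shape[1]
        self.vip_ = np.sqrt(p_vars) * np.abs(self.weights_)
        return self

    def _fit_core(self, Xc: np.ndarray, yc: np.ndarray, n_orth: int) -> None:
        Xd = Xc.copy()
        Wo, Po, To = [], [], []
        for _ in range(n_orth):
            w = Xd.T @ yc
            w /= np.linalg.norm(w)
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm_o = np.linalg.norm(w_o)
            if norm_o < 1e-12:  # no orthogonal variation left
                break
            w_o /= norm_o
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            Wo.append(w_o)
            Po.append(p_o)
            To.append(t_o)
        w = Xd.T @ yc
        w /= np.linalg.norm(w)
        t = Xd @ w
        self.weights_ = w
        self.loadings_ = Xd.T @ t / (t @ t)
        self.scores_ = t
        self.y_loading_ = float(yc @ t / (t @ t))
        self.orth_weights_ = np.column_stack(Wo) if Wo else np.empty((Xc.shape[1], 0))
        self.orth_loadings_ = np.column_stack(Po) if Po else np.empty((Xc.shape[1], 0))
        self.orth_scores_ = np.column_stack(To) if To else np.empty((Xc.shape[0], 0))

    def _auto_n_orth(self, X, y) -> int:
        from .validation import q2_cv

        best_k, best_q2 = 0, -np.inf
        for k in range(self.max_orth + 1):
            cand = OPLSDA(n_orth=k, cv_folds=self.cv_folds, random_state=self.random_state)
            try:
                q2 = q2_cv(cand, X, y, folds=self.cv_folds, seed=self.random_state).q2y
            except (ValueError, np.linalg.LinAlgError):
                break
            if q2 >= best_q2 + self.q2_gain_min or k == 0:
                if q2 > best_q2:
                    best_k, best_q2 = k, q2
            else:
                break
        return best_k

    # -- prediction --------------------------------------------------------

    def _check_features(self, X):
        Xa, cols, _ = _as_array(X)
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"metabolites absent from new data: {missing}")
            Xa = X.loc[:, list(self.feature_names_in_)].to_numpy(dtype=float)
        elif Xa.shape[1] != len(self.feature_names_in_):
            raise ValueError(
                f"expected {len(self.feature_names_in_)} features, got {Xa.shape[1]}"
            )
        return Xa

    def transform(self, X):
        """Predictive score of new samples after orthogonal-variation removal."""
        Xc = self._check_features(X) - self.x_mean_
        for a in range(self.orth_weights_.shape[1]):
            t_o = Xc @ self.orth_weights_[:, a]
            Xc = Xc - np.outer(t_o, self.orth_loadings_[:, a])
        return Xc @ self.weights_

    def decision_function(self, X):
        """Continuous y_hat on the encoded {0,1} scale."""
        return self.transform(X) * self.y_loading_ + self.y_mean_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0.5).astype(int)]

    def to_json(self) -> str:
        payload = {
            "metabolite_ids": [str(c) for c in self.feature_names_in_],
            "classes": [str(c) for c in self.classes_],
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "weights": self.weights_.tolist(),
            "loadings": self.loadings_.tolist(),
            "y_loading": self.y_loading_,
            "orth_weights": self.orth_weights_.tolist(),
            "orth_loadings": self.orth_loadings_.tolist(),
            "n_orth": self.n_orth_,
            "r2y": self.r2y_,
            "vip": self.vip_.tolist(),
        }
        return json.dumps(payload, sort_keys=True)


def vip(model: OPLSDA) -> np.ndarray:
    """Variable importance in projection of a fitted OPLS-DA model.

    With a single predictive component and unit-norm weights this reduces to
    sqrt(p) * |w_j|, so the VIP^2 values average to one by construction.
    """
    if not hasattr(model, "vip_"):
        raise ValueError("model is not fitted")
    return model.vip_


def opls_fit(X, y, n_orth=1, **kwargs) -> OPLSDA:
    """Functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(n_orth=n_orth, **kwargs).fit(X, y)


def opls_predict(model: OPLSDA, X_new):
    """Return (predictive scores, continuous y_hat, class labels)."""
    t = model.transform(X_new)
    y_hat = t * model.y_loading_ + model.y_mean_
    return t, y_hat, model.classes_[(y_hat >= 0.5).astype(int)]


class PLSDA(BaseEstimator, ClassifierMixin):
    """Multi-class PLS2 discriminant analysis on a class-indicator matrix.

    NIPALS PLS2 on the dummy-coded Y (one column per class, rows summing to
    one). Used for the multi-class disease-stage model; no orthogonal
    filtering is applied, so this is PLS-DA rather than OPLS-DA.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-10, max_iter: int = 1000):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        Xa, cols, _ = _as_array(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 2:
            small = [str(c) for c, n in zip(self.classes_, counts) if n < 2]
            raise ValueError(f"classes with < 2 samples: {small}")
        self.feature_names_in_ = cols
        Y = np.column_stack([(y == c).astype(float) for c in self.classes_])
        self.x_mean_ = Xa.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xd = Xa - self.x_mean_
        Yd = Y - self.y_mean_
        ssy = float(np.sum(Yd**2))
        W, P, C, T = [], [], [], []
        r2y = []
        for _ in range(self.n_components):
            u = Yd[:, int(np.argmax(np.sum(Yd**2, axis=0)))].copy()
            t_old = None
            for _ in range(self.max_iter):
                w = Xd.T @ u / (u @ u)
                w /= np.linalg.norm(w)
                t = Xd @ w
                c = Yd.T @ t / (t @ t)
                u = Yd @ c / (c @ c)
                if t_old is not None and np.linalg.norm(t - t_old) <= self.tol * np.linalg.norm(t):
                    break
                t_old = t
            p = Xd.T @ t / (t @ t)
            Xd = Xd - np.outer(t, p)
            Yd = Yd - np.outer(t, c)
            W.append(w)
            P.append(p)
            C.append(c)
            T.append(t)
            r2y.append(1.0 - float(np.sum(Yd**2)) / ssy)
        self.x_weights_ = np.column_stack(W)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.column_stack(C)
        self.scores_ = np.column_stack(T)
        self.r2y_cumulative_ = np.asarray(r2y)
        self.r2y_ = float(r2y[-1]) if r2y else 0.0
        return self

    def transform(self, X):
        Xa = np.asarray(X.loc[:, list(self.feature_names_in_)] if isinstance(X, pd.DataFrame) else X,
                        dtype=float)
        Xd = Xa - self.x_mean_
        T = np.empty((Xd.shape[0], self.x_weights_.shape[1]))
        for a in range(self.x_weights_.shape[1]):
            t = Xd @ self.x_weights_[:, a]
            Xd = Xd - np.outer(t, self.x_loadings_[:, a])
            T[:, a] = t
        return T

    def decision_function(self, X):
        return self.transform(X) @ self.y_loadings_.T + self.y_mean_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def fit_multigroup_plsda(X, labels, n_predictive: int = 2) -> PLSDA:
    """Functional wrapper over :class:`PLSDA`."""
    return PLSDA(n_components=n_predictive).fit(X, labels)


def nipals_pca(X, n_components: int = 3, missing_allowed: bool = False) -> NipalsPCA:
    """Functional wrapper over :class:`NipalsPCA`."""
    return NipalsPCA(n_components=n_components, missing_allowed=missing_allowed).fit(X)
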
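"""Sklearn-style estimators for the multivariate part of the QC pipeline.

``RangeScaler`` implements range scaling, x -> (x − min) / (max − min) per
feature, the scaling of choice when metabolite abundances should be compared
relative to their biological range.  ``PlsdaClassifier`` wraps a NIPALS PLS2
regression on one-hot class membership into a classifier with class-specific
regression coefficients and VIP (variable importance in projection) scores.

Both follow the scikit-learn estimator contract (get_params/set_params,
fitted attributes with trailing underscores) and compose with sklearn model
selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class RangeScaler(TransformerMixin, BaseEstimator):
    """Scale each feature to [0, 1] by its training range.

    Test data are scaled with the *training* minimum and maximum and are not
    clipped, so out-of-range test values land outside [0, 1] — the contract
    that keeps cross-validation leakage-free.  A constant training column is
    flagged (``constant_mask_``) and scaled to 0.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_all_finite=True)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        self.range_ = self.max_ - self.min_
        self.constant_mask_ = self.range_ == 0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        X = check_array(X, dtype=float, ensure_all_finite=True)
        denom = np.where(self.constant_mask_, 1.0, self.range_)
        Z = (X - self.min_) / denom
        Z[:, self.constant_mask_] = 0.0
        return Z


class PlsdaClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass PLS discriminant analysis.

    The response is the one-hot class membership matrix; the core fit is a
    NIPALS PLS2 regression (no autoscaling — scale the predictors upstream).
    A sample is assigned to the class with the largest predicted membership.

    Parameters
    ----------
    n_components:
        Number of latent variables.

    Attributes
    ----------
    classes_ : class labels in column order of the response.
    coef_ : (n_features, n_classes) class-specific regression coefficients.
    vip_ : (n_features, n_classes) class-specific VIP scores.  For each
        class the explained response variance per component is computed on
        that class's membership column, so mean_j VIP[j, c]^2 == 1.
    x_scores_, x_weights_, x_loadings_, y_loadings_ : PLS decomposition.
    r2y_, r2x_, r2x_per_component_ : goodness-of-fit summaries.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("PLSDA needs at least two classes")
        Y = np.eye(len(self.classes_))[y_idx]

        n_comp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        pls = PLSRegression(n_components=n_comp, scale=False)
        pls.fit(X, Y)
        self._pls = pls
        self.n_components_ = n_comp
        self.n_features_in_ = X.shape[1]

        self.x_scores_ = pls.x_scores_
        self.x_weights_ = pls.x_weights_
        self.x_loadings_ = pls.x_loadings_
        self.y_loadings_ = pls.y_loadings_
        coef = pls.coef_
        self.coef_ = coef.T if coef.shape == (Y.shape[1], X.shape[1]) else coef

        Yhat = pls.predict(X)
        ss_res = float(((Y - Yhat) ** 2).sum())
        ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
        self.r2y_ = 1.0 - ss_res / ss_tot

        Xc = X - X.mean(axis=0)
        ss_x = float((Xc ** 2).sum())
        t_ss = (self.x_scores_ ** 2).sum(axis=0)  # scores are orthogonal
        p_ss = (self.x_loadings_ ** 2).sum(axis=0)
        self.r2x_per_component_ = (t_ss * p_ss) / ss_x
        self.r2x_ = float(self.r2x_per_component_.sum())

        self.vip_ = self._class_vip(t_ss)
        return self

    def _class_vip(self, t_ss: np.ndarray) -> np.ndarray:
        """VIP_{j,class} = sqrt(p * sum_a ssy_a(class) w_ja^2/||w_a||^2 / sum_a ssy_a)."""
        W = self.x_weights_
        p = W.shape[0]
        w_norm2 = (W ** 2).sum(axis=0)
        w_frac = (W ** 2) / w_norm2  # (p, A)
        vip = np.empty((p, len(self.classes_)))
        for c in range(len(self.classes_)):
            ssy = t_ss * self.y_loadings_[c, :] ** 2  # per-component explained SSY
            total = ssy.sum()
            if total == 0:
                vip[:, c] = 0.0
                continue
            vip[:, c] = np.sqrt(p * (w_frac * ssy).sum(axis=1) / total)
        return vip

    def decision_function(self, X):
        check_is_fitted(self, "_pls")
        X = check_array(X, dtype=float)
        return self._pls.predict(X)

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]
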
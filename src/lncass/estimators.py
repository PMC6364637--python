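"""scikit-learn-style estimators wrapping the LN-CASS models.

:class:`LNCASSRegression` (gaussian response) and :class:`LNCASSClassifier`
(binary response, logit link) fit the flat LN-CASS prior, or the grouped
variant when ``groups`` is given.  :class:`LNCASSGAMClassifier` fits the
hierarchical GAM on covariates scaled to [0, 1].  All follow the
fit/predict/get_params protocol and expose fitted posterior summaries through
trailing-underscore attributes, so they compose with sklearn pipelines and
model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .inference import run_mcmc, summarize
from .models import (
    GAMConfig,
    GroupStructure,
    RegressionDataset,
    build_flat_model,
    build_gam_basis,
    build_grouped_model,
    build_hierarchical_gam,
)
from .priors import LNCASSHyperparams, sigm

__all__ = ["LNCASSRegression", "LNCASSClassifier", "LNCASSGAMClassifier"]


class _LNCASSBase(BaseEstimator):
    def __init__(
        self,
        tau=5.0,
        sigma_lambda=10.0,
        a=None,
        mu_lambda=None,
        groups=None,
        chains=4,
        warmup=1000,
        draws=1000,
        target_accept=0.95,
        random_state=0,
    ):
        self.tau = tau
        self.sigma_lambda = sigma_lambda
        self.a = a
        self.mu_lambda = mu_lambda
        self.groups = groups
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.target_accept = target_accept
        self.random_state = random_state

    def _hyper(self) -> LNCASSHyperparams:
        return LNCASSHyperparams(
            tau=self.tau,
            sigma_lambda=self.sigma_lambda,
            a=self.a,
            mu_lambda=self.mu_lambda,
        )

    _family = "gaussian"

    def _build_model(self, data: RegressionDataset):
        hyper = self._hyper()
        if self.groups is not None:
            gs = (
                self.groups
                if isinstance(self.groups, GroupStructure)
                else GroupStructure(assignment=list(self.groups))
            )
            return build_grouped_model(data, gs, hyper)
        return build_flat_model(data, hyper)

    def _fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=self._family == "gaussian")
        data = RegressionDataset(np.asarray(X, dtype=float), np.asarray(y, dtype=float),
                                 family=self._family)
        model = self._build_model(data)
        self.samples_ = run_mcmc(
            model,
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            seed=self.random_state if self.random_state is not None else 0,
            target_accept=self.target_accept,
        )
        self.summary_ = summarize(self.samples_)
        self.intercept_ = float(self.summary_.coefficients.loc["intercept", "median"])
        self.coef_ = self.summary_.beta_median
        self.inclusion_ = self.summary_.inclusion.to_numpy()
        if self.summary_.rhat is not None:
            self.rhat_max_ = float(self.summary_.rhat.max())
        self.n_features_in_ = data.p
        return self

    def _posterior_mean_eta(self, X):
        der = self.samples_.derived
        beta = der["beta"].reshape(-1, der["beta"].shape[-1])
        b0 = der["beta0"].ravel()
        return b0[None, :] + X @ beta.T  # (n_test, n_draws)


class LNCASSRegression(RegressorMixin, _LNCASSBase):
    """Bayesian sparse linear regression under the LN-CASS prior."""

    _family = "gaussian"

    def fit(self, X, y):
        return self._fit(X, y)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self._posterior_mean_eta(X).mean(axis=1)


class LNCASSClassifier(ClassifierMixin, _LNCASSBase):
    """Bayesian sparse logistic regression under the LN-CASS prior.

    ``predict_proba`` is the posterior-mean predictive probability (the
    logistic of the linear predictor averaged over posterior draws) — the
    full-model prediction, not a plug-in at point estimates.
    """

    _family = "binomial"

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("LNCASSClassifier requires exactly two classes")
        y01 = (y == self.classes_[1]).astype(float)
        return self._fit(X, y01)

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        p1 = sigm(self._posterior_mean_eta(X)).mean(axis=1)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


class LNCASSGAMClassifier(ClassifierMixin, _LNCASSBase):
    """Hierarchical LN-CASS GAM classifier (logit link, hinge basis).

    Covariates must lie in [0, 1] (scale with
    :func:`lncass.preprocess.scale_unit_interval`).  The complexity ladder
    per covariate is: excluded -> linear effect -> nonlinear effect.
    """

    _family = "binomial"

    def __init__(
        self,
        n_knots=5,
        tau=5.0,
        sigma_lambda=10.0,
        a=None,
        mu_lambda=None,
        chains=4,
        warmup=1000,
        draws=1000,
        target_accept=0.95,
        random_state=0,
    ):
        super().__init__(
            tau=tau,
            sigma_lambda=sigma_lambda,
            a=a,
            mu_lambda=mu_lambda,
            groups=None,
            chains=chains,
            warmup=warmup,
            draws=draws,
            target_accept=target_accept,
            random_state=random_state,
        )
        self.n_knots = n_knots

    def _build_model(self, data: RegressionDataset):
        self.gam_config_ = GAMConfig(n_knots=self.n_knots)
        return build_hierarchical_gam(data, self._hyper(), self.gam_config_)

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("LNCASSGAMClassifier requires exactly two classes")
        y01 = (y == self.classes_[1]).astype(float)
        self._fit(X, y01)
        self.lambda_nl_ = self.summary_.extra["lambda_nl_mean"].to_numpy()
        return self

    def _posterior_mean_eta(self, X):
        B = np.concatenate(
            [build_gam_basis(X[:, i], self.gam_config_) for i in range(X.shape[1])],
            axis=1,
        )
        der = self.samples_.derived
        beta = der["beta"].reshape(-1, der["beta"].shape[-1])
        b0 = der["beta0"].ravel()
        return b0[None, :] + B @ beta.T

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        p1 = sigm(self._posterior_mean_eta(X)).mean(axis=1)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]
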
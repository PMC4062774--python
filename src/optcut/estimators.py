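"""Scikit-learn style estimators wrapping the threshold machinery.

``BayesianCutpoint`` fits a Bayesian model per group and exposes the
optimal-threshold posterior; ``FrequentistCutpoint`` wraps the empirical,
Box-Cox, and kernel comparators.  Both are binary classifiers after
fitting: ``predict`` labels a marker value diseased when it exceeds the
estimated threshold, so they compose with sklearn pipelines and model
selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import comparators as _cmp
from .models import MarkerSample, PriorSpec, fit_group
from .threshold import YoudenWeights, sens_spec_at, threshold_posterior

__all__ = ["BayesianCutpoint", "FrequentistCutpoint"]


def _as_marker_sample(X, y) -> MarkerSample:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("expected a single marker column")
        X = X[:, 0]
    elif X.ndim != 1:
        raise ValueError("X must be 1d or a single-column 2d array")
    return MarkerSample(X, np.asarray(y))


class _CutpointBase(ClassifierMixin, BaseEstimator):
    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return (X > self.threshold_).astype(int)

    def decision_function(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return X - self.threshold_


class BayesianCutpoint(_CutpointBase):
    """Bayesian optimal-cutpoint estimator.

    Parameters
    ----------
    family : {"gaussian", "student_t", "dpm"}
        Distribution family fitted independently in each group.
    prevalence, nb_over_nc : float
        Disease prevalence pi and benefit/cost ratio NB/NC defining the
        specificity weight R of the generalized Youden index.
    n_iter, burn_in, thin : int
        MCMC schedule per group chain.
    alpha : float
        1 - alpha is the credible level of both interval methods.
    estimate : {"median", "mode", "mean"}
        Posterior summary reported as ``threshold_``.
    random_state : int
        Seed for both group chains (group 1 uses ``random_state + 1``).

    Attributes
    ----------
    threshold_ : float
        Selected posterior summary of the optimal threshold.
    posterior_ : ThresholdPosterior
        Full posterior with mode/median/mean and both 95% intervals.
    group_posteriors_ : tuple(GroupPosterior, GroupPosterior)
    sens_spec_ : SensSpecPosterior at ``threshold_``.
    """

    def __init__(
        self,
        family: str = "gaussian",
        prevalence: float = 0.5,
        nb_over_nc: float = 1.0,
        n_iter: int = 3000,
        burn_in: int = 1000,
        thin: int = 1,
        alpha: float = 0.05,
        estimate: str = "median",
        prior: PriorSpec | None = None,
        grid_points: int = 512,
        random_state: int = 0,
    ) -> None:
        self.family = family
        self.prevalence = prevalence
        self.nb_over_nc = nb_over_nc
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.alpha = alpha
        self.estimate = estimate
        self.prior = prior
        self.grid_points = grid_points
        self.random_state = random_state

    def fit(self, X, y):
        sample = _as_marker_sample(X, y)
        sample.require_both_groups()
        if self.estimate not in ("mode", "median", "mean"):
            raise ValueError("estimate must be one of mode/median/mean")
        weights = YoudenWeights(self.prevalence, self.nb_over_nc)
        kwargs = dict(
            prior=self.prior,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
        )
        post0 = fit_group(self.family, sample.non_diseased, seed=self.random_state, **kwargs)
        post1 = fit_group(self.family, sample.diseased, seed=self.random_state + 1, **kwargs)
        tp = threshold_posterior(
            post0, post1, weights, alpha=self.alpha, grid_points=self.grid_points
        )
        self.classes_ = np.array([0, 1])
        self.weights_ = weights
        self.group_posteriors_ = (post0, post1)
        self.posterior_ = tp
        self.threshold_ = float(getattr(tp, self.estimate))
        self.sens_spec_ = sens_spec_at(post0, post1, self.threshold_, alpha=self.alpha)
        return self


class FrequentistCutpoint(_CutpointBase):
    """Frequentist comparator cutpoint (empirical / Box-Cox / kernel) with
    an optional stratified percentile bootstrap confidence interval.

    Attributes: ``threshold_`` (point estimate), ``ci_`` ((lo, hi) or None
    when ``n_boot`` = 0), ``result_`` (full ComparatorResult).
    """

    def __init__(
        self,
        method: str = "empirical",
        prevalence: float = 0.5,
        nb_over_nc: float = 1.0,
        n_boot: int = 0,
        level: float = 0.95,
        random_state: int = 0,
    ) -> None:
        self.method = method
        self.prevalence = prevalence
        self.nb_over_nc = nb_over_nc
        self.n_boot = n_boot
        self.level = level
        self.random_state = random_state

    def fit(self, X, y):
        sample = _as_marker_sample(X, y)
        sample.require_both_groups()
        if self.method not in _cmp.COMPARATORS:
            raise ValueError(f"unknown method {self.method!r}")
        weights = YoudenWeights(self.prevalence, self.nb_over_nc)
        if self.n_boot > 0:
            res = _cmp.bootstrap_ci(
                self.method,
                sample,
                weights,
                n_boot=self.n_boot,
                seed=self.random_state,
                level=self.level,
            )
        else:
            point = _cmp.COMPARATORS[self.method](sample, weights)
            res = _cmp.ComparatorResult(self.method, float(point), None, 0, self.random_state)
        self.classes_ = np.array([0, 1])
        self.weights_ = weights
        self.result_ = res
        self.threshold_ = res.estimate
        self.ci_ = res.ci
        return self
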
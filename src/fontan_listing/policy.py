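"""scikit-learn style estimators wrapping the decision rule.

:class:`ListingPolicy` is the user-facing form of the timing rule: set
the six clinical parameters, ``fit`` to compute and validate the
thresholds, ``predict`` to classify patients by their net signal count.
:class:`SignalQualityEstimator` fits the holistic signal quality theta
from historical (comorbidities-at-transplant, outcome) records.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .params import ModelParams
from .sensitivity import OutcomeRecord, estimate_signal_quality
from .thresholds import compute_thresholds, decide

__all__ = ["ListingPolicy", "SignalQualityEstimator"]


class ListingPolicy(BaseEstimator):
    """Three-way transplant-listing rule on the net-signal-count scale.

    Parameters
    ----------
    mu : float
        Rate of clinical decline (new comorbidities per year).
    theta : float
        Signal quality, in (0, 1) and != 1/2.
    r : float
        Discount rate per year.
    delta : float
        Expected waiting time on the list (years).
    lt : float
        Posttransplant life expectancy given a Good outcome (years).
    lnt : float
        Life expectancy without transplant (years); delta < lnt < lt.

    Attributes (after ``fit``)
    --------------------------
    params_ : ModelParams
    thresholds_ : Thresholds
    k_high_, k_low_ : float
        Continuous listing/delisting thresholds.
    window_ : tuple[int, int]
        Integer listing window [ceil(k_low), floor(k_high)].
    classes_ : ndarray of the three labels.

    Examples
    --------
    >>> pol = ListingPolicy(mu=2, theta=0.8, r=0.1, delta=0.5, lt=10, lnt=2).fit()
    >>> round(pol.k_high_, 2), round(pol.k_low_, 2)
    (2.93, 0.18)
    >>> list(pol.predict([0, 2, 3]))
    ['TooUnwell', 'List', 'TooWell']
    """

    def __init__(self, mu=2.0, theta=0.8, r=0.1, delta=0.5, lt=10.0, lnt=2.0):
        self.mu = mu
        self.theta = theta
        self.r = r
        self.delta = delta
        self.lt = lt
        self.lnt = lnt

    def fit(self, X=None, y=None):
        """Validate the parameters and compute the thresholds.

        X and y are ignored; the rule is fully determined by the
        parameters (present for pipeline compatibility).
        """
        self.params_ = ModelParams(
            mu=self.mu, theta=self.theta, r=self.r,
            delta=self.delta, lt=self.lt, lnt=self.lnt,
        )
        self.thresholds_ = compute_thresholds(self.params_)
        self.k_high_ = self.thresholds_.k_high
        self.k_low_ = self.thresholds_.k_low
        self.window_ = self.thresholds_.window
        self.classes_ = np.array(["TooUnwell", "List", "TooWell"])
        return self

    def predict(self, X):
        """Classify integer net signal counts.

        X : array-like of integers, shape (n,) or (n, 1).
        Returns an array of labels "TooWell" / "List" / "TooUnwell".
        """
        check_is_fitted(self, "thresholds_")
        ks = np.asarray(X)
        if ks.ndim == 2 and ks.shape[1] == 1:
            ks = ks[:, 0]
        if ks.ndim == 0:
            ks = ks[None]
        if ks.ndim != 1:
            raise ValueError("expected a 1-d array of net signal counts")
        if not np.all(ks == np.round(ks)):
            raise ValueError("net signal counts must be integers")
        return np.array(
            [decide(int(k), self.thresholds_).value.value for k in ks], dtype=object
        )

    def decide(self, k: int):
        """Full :class:`Decision` for one patient count."""
        check_is_fitted(self, "thresholds_")
        return decide(int(k), self.thresholds_)


class SignalQualityEstimator(BaseEstimator):
    """Estimate the holistic signal quality theta from outcome records.

    Parameters
    ----------
    orientations : sequence of "good"/"bad" per signal, or None for all-"bad".

    Attributes (after ``fit``)
    --------------------------
    signal_quality_ : ndarray
        Per-signal proportion correct (NaN where a signal had no exposure).
    exposures_ : ndarray of exposure counts.
    theta_ : float
        Exposure-weighted composite quality.
    """

    def __init__(self, orientations=None):
        self.orientations = orientations

    def fit(self, X, y):
        """X: (n_patients, n_signals) boolean presence matrix; y: outcomes
        ("Good"/"Bad" strings, or 1 for Good / 0 for Bad)."""
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (patients x signals)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y must have the same number of patients")
        if y.dtype.kind in "biu":
            y = np.where(y.astype(bool), "Good", "Bad")
        records = [
            OutcomeRecord(present=tuple(bool(v) for v in X[i]), outcome=str(y[i]))
            for i in range(X.shape[0])
        ]
        orientations = (
            list(self.orientations) if self.orientations is not None else None
        )
        per_signal, composite = estimate_signal_quality(records, orientations)
        self.signal_quality_ = np.asarray(per_signal, dtype=float)
        self.exposures_ = np.array([int(X[:, j].sum()) for j in range(X.shape[1])])
        self.theta_ = composite
        return self
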
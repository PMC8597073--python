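"""Signal counts and Bayesian beliefs.

A patient's clinical status is summarised by the net signal count
``k = (# Good-indicative signals) - (# Bad-indicative signals) = n - 2b``,
where ``n`` is the checklist length and ``b`` the number of Bad-indicative
signals observed.  With a symmetric prior (1/2) and signals that reflect
the true outcome with probability ``theta``, the belief in a Good
posttransplant outcome for an unlisted patient reduces to a function of
``k`` alone::

    p(k) = (1-theta)^k / (theta^k + (1-theta)^k)

For a *listed* patient the model interchanges ``theta`` and ``1-theta``,
so the probability of a Good posttransplant outcome becomes ``1 - p(k)``.

``k`` is an integer for observed patients but the mapping is defined for
real ``k`` as well; the threshold algebra relies on that.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Orientation",
    "ChecklistEntry",
    "ChecklistAssessment",
    "BeliefState",
    "posterior_good",
    "listed_posterior_good",
    "k_from_p",
    "brute_force_posterior",
    "trans_down",
    "trans_up",
]


class Orientation(str, enum.Enum):
    """Which posttransplant outcome an observed checklist row indicates."""

    GOOD = "good"
    BAD = "bad"


@dataclass(frozen=True)
class ChecklistEntry:
    symptom: str
    present: bool
    orientation: Orientation


@dataclass(frozen=True)
class ChecklistAssessment:
    """A patient's checklist at one review, with its derived net count.

    Every entry contributes one oriented signal as observed: the
    orientation column qualifies the row's observed state (a row such as
    "Central venous pressure >= level Y | No | Good" contributes a
    Good-indicative signal because the *absence* is the informative
    state).
    """

    entries: tuple[ChecklistEntry, ...]
    n: int = field(init=False)
    b: int = field(init=False)
    k: int = field(init=False)

    def __post_init__(self) -> None:
        labels = [e.symptom for e in self.entries]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate symptom label(s) in assessment: {dup}")
        n = len(self.entries)
        b = sum(1 for e in self.entries if e.orientation is Orientation.BAD)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "k", n - 2 * b)


class RegionConvention(str, enum.Enum):
    UNLISTED = "unlisted"
    LISTED = "listed"


@dataclass(frozen=True)
class BeliefState:
    """A (k, belief) pair, recording which orientation convention applies."""

    k: float
    p: float
    region_convention: RegionConvention = RegionConvention.UNLISTED

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError("belief p must lie strictly in (0, 1)")
        if not math.isfinite(self.k):
            raise ValueError("k must be finite")


def _check_theta(theta: float) -> None:
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie strictly in (0, 1)")
    if theta == 0.5:
        raise ValueError("theta=1/2 makes the belief independent of k")


def posterior_good(k: float, theta: float) -> float:
    """Belief in a Good outcome at net signal count ``k`` (unlisted patient).

    Computed in log space for numerical stability at large |k|.
    """
    _check_theta(theta)
    if not math.isfinite(k):
        raise ValueError("k must be finite")
    # p = (1-t)^k / (t^k + (1-t)^k) = 1 / (1 + (t/(1-t))^k)
    x = k * (math.log(theta) - math.log1p(-theta))
    if x > 700.0:
        return math.exp(-x)  # underflow-safe tail
    return 1.0 / (1.0 + math.exp(x))


def listed_posterior_good(k: float, theta: float) -> float:
    """Belief in a Good outcome for a *listed* patient: ``1 - p(k)``."""
    return 1.0 - posterior_good(k, theta)


def k_from_p(p: float, theta: float) -> float:
    """Invert the belief mapping: the real ``k`` with ``posterior_good(k) = p``."""
    _check_theta(theta)
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0, 1): k diverges at p in {0, 1}")
    return math.log((1.0 - p) / p) / (math.log(theta) - math.log1p(-theta))


def brute_force_posterior(b: int, n: int, theta: float, p0: float = 0.5) -> float:
    """Direct Bayes posterior of a Good outcome from raw counts.

    ``b`` of ``n`` signals are Bad-indicative; the likelihood of the
    observed pattern is binomial with success probability ``theta`` under
    the Good hypothesis and ``1 - theta`` under Bad.  Serves as the
    independent oracle for :func:`posterior_good`: for ``p0 = 1/2`` the
    two agree with ``k = n - 2b``.
    """
    _check_theta(theta)
    if not (0 <= b <= n):
        raise ValueError("need 0 <= b <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly in (0, 1)")
    like_good = theta**b * (1.0 - theta) ** (n - b)
    like_bad = (1.0 - theta) ** b * theta ** (n - b)
    return like_good * p0 / (like_good * p0 + like_bad * (1.0 - p0))


def trans_down(p: float, theta: float) -> float:
    """One-step probability of a down move (k -> k-1) at belief ``p``:
    ``2*p*theta + 1 - theta - p``."""
    return 2.0 * p * theta + 1.0 - theta - p


def trans_up(p: float, theta: float) -> float:
    """One-step probability of an up move (k -> k+1) at belief ``p``:
    ``p + theta - 2*theta*p``."""
    return p + theta - 2.0 * theta * p
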
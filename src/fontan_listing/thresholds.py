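"""Closed-form listing and delisting thresholds, and the three-way decision.

The rule delimits three regions on the net-signal-count axis:

* ``k >= ceil(k_high)``  — the patient is too well to list for now;
* ``ceil(k_low) <= k <= floor(k_high)`` — list the patient;
* ``k <= floor(k_low)``  — the patient is too unwell (delist / do not list).

``k_high`` derives from the value of the option to wait before listing:
``beta1`` is the smaller root of the characteristic quadratic

    beta^2 - ((r+mu)/mu) beta + theta(1-theta) = 0,

``Psi`` is a ratio of discount/transition factors built from ``beta1``,
and the boundary belief is ``p_high = [Psi (LT/(LNT-delta) - 1) + 1]^-1``.
``k_low`` derives from the option to delist: the boundary belief is

    p_low = [(r+mu)(delta+LT) - (2r + mu(2+theta)) LNT]
            / [(r+mu) LT + mu (1-2 theta) LNT]

and is mapped to the k scale with the listed-region orientation (the
theta <-> 1-theta interchange), i.e. with the inverted log-odds ratio.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .belief import k_from_p
from .params import ModelParams

__all__ = [
    "Thresholds",
    "Decision",
    "DecisionLabel",
    "beta1",
    "beta2",
    "psi",
    "p_high",
    "p_low",
    "k_high",
    "k_low",
    "compute_thresholds",
    "decide",
]


def beta1(params: ModelParams) -> float:
    """Smaller root of the waiting-option characteristic quadratic."""
    b = (params.r + params.mu) / params.mu
    q = params.theta * (1.0 - params.theta)
    disc = b * b - 4.0 * q
    # (r+mu)/mu > 1 >= 2*sqrt(theta(1-theta)) so the discriminant is positive
    root = (b - math.sqrt(disc)) / 2.0
    # sign checks at 0, theta and 1-theta bracket the smaller root below both
    assert 0.0 < root < min(params.theta, 1.0 - params.theta)
    return root


def beta2(params: ModelParams) -> float:
    """Decay factor of the delisting option: mu*theta*(1-theta)/(r+mu).

    Smaller than both theta and 1-theta, so the option value grows
    without bound as the patient's count falls.
    """
    return params.mu * params.theta * (1.0 - params.theta) / (params.r + params.mu)


def psi(params: ModelParams) -> float:
    """The ratio Psi entering the upper boundary belief."""
    mu, th, r = params.mu, params.theta, params.r
    b1 = beta1(params)
    common = r + mu * (1.0 - b1)
    cross = mu * mu * th * (1.0 - th)
    num = common * (r + mu * th) - cross
    den = common * (r + mu * (1.0 - th)) - cross
    if den == 0.0:
        raise ValueError(
            f"Psi denominator vanished (mu={mu}, theta={th}, r={r}): "
            "parameters sit on a degenerate boundary"
        )
    value = num / den
    if value < 0.0:
        raise ValueError(f"Psi={value} is negative; upper boundary belief undefined")
    return value


def p_high(params: ModelParams) -> float:
    """Upper boundary belief: list once the belief reaches p_high."""
    bracket = psi(params) * (params.lt / (params.lnt - params.delta) - 1.0) + 1.0
    ph = 1.0 / bracket
    if not (0.0 < ph <= 1.0):
        raise ValueError(f"p_high={ph} is not a probability; model not well-defined here")
    return ph


def p_low(params: ModelParams) -> float:
    """Lower boundary belief (delisting), in the listed-region orientation."""
    mu, th, r = params.mu, params.theta, params.r
    num = (r + mu) * (params.delta + params.lt) - (2.0 * r + mu * (2.0 + th)) * params.lnt
    den = (r + mu) * params.lt + mu * (1.0 - 2.0 * th) * params.lnt
    pl = num / den
    if not (0.0 < pl <= 1.0):
        raise ValueError(
            f"p_low={pl:.6g} lies outside (0, 1]: the delisting boundary belief is "
            "not a probability, so the model is not well-defined for these inputs"
        )
    return pl


def k_high(params: ModelParams) -> float:
    """Continuous upper threshold on the net-signal-count scale."""
    return k_from_p(p_high(params), params.theta)


def k_low(params: ModelParams) -> float:
    """Continuous lower threshold; note the inverted log-odds (the
    listed-region p <-> 1-p swap), so the sign flips relative to the
    unlisted mapping."""
    pl = p_low(params)
    if pl == 1.0:
        raise ValueError("p_low=1 maps to an infinite k_low")
    th = params.theta
    return math.log(pl / (1.0 - pl)) / (math.log(th) - math.log1p(-th))


@dataclass(frozen=True)
class Thresholds:
    """All threshold quantities for one parameter set."""

    params: ModelParams
    beta1: float
    beta2: float
    psi: float
    p_high: float
    p_low: float
    k_high: float
    k_low: float

    def __post_init__(self) -> None:
        if not self.k_low < self.k_high:
            raise ValueError(
                f"k_low={self.k_low:.4f} >= k_high={self.k_high:.4f}: "
                "no listing window exists for these parameters"
            )

    @property
    def k_high_floor(self) -> int:
        return math.floor(self.k_high)

    @property
    def k_high_ceil(self) -> int:
        return math.ceil(self.k_high)

    @property
    def k_low_floor(self) -> int:
        return math.floor(self.k_low)

    @property
    def k_low_ceil(self) -> int:
        return math.ceil(self.k_low)

    @property
    def window(self) -> tuple[int, int]:
        """Integer listing window [ceil(k_low), floor(k_high)] (may be empty)."""
        return (self.k_low_ceil, self.k_high_floor)

    def summary(self) -> str:
        lines = [
            f"beta1  = {self.beta1:.2f}",
            f"beta2  = {self.beta2:.2f}",
            f"Psi    = {self.psi:.2f}",
            f"p_high = {self.p_high:.2f}",
            f"p_low  = {self.p_low:.2f}",
            f"k_high = {self.k_high:.2f}  (floor {self.k_high_floor}, ceil {self.k_high_ceil})",
            f"k_low  = {self.k_low:.2f}  (floor {self.k_low_floor}, ceil {self.k_low_ceil})",
            f"listing window: k in [{self.window[0]}, {self.window[1]}]",
        ]
        return "\n".join(lines)


def compute_thresholds(params: ModelParams) -> Thresholds:
    return Thresholds(
        params=params,
        beta1=beta1(params),
        beta2=beta2(params),
        psi=psi(params),
        p_high=p_high(params),
        p_low=p_low(params),
        k_high=k_high(params),
        k_low=k_low(params),
    )


class DecisionLabel(str, enum.Enum):
    TOO_WELL = "TooWell"
    LIST = "List"
    TOO_UNWELL = "TooUnwell"


@dataclass(frozen=True)
class Decision:
    value: DecisionLabel
    k: int
    thresholds: Thresholds


def decide(k: int, thresholds: Thresholds) -> Decision:
    """Classify an integer net signal count into the three regions.

    Integer-threshold ties: a count equal to an exactly-integer k_high is
    still listed (the listing region is defined by k <= k_high); a count
    equal to an exactly-integer k_low is too unwell (that region is
    k <= k_low).  Both follow from the region definitions; the
    floor/ceiling statement of the rule assumes non-integer thresholds.
    """
    if k != int(k):
        raise ValueError("patient net signal counts are integers")
    k = int(k)
    if k <= thresholds.k_low_floor:
        label = DecisionLabel.TOO_UNWELL
    elif k <= thresholds.k_high_floor:
        label = DecisionLabel.LIST
    else:
        label = DecisionLabel.TOO_WELL
    return Decision(value=label, k=k, thresholds=thresholds)
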
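"""Regional value functions and the option-value constants.

The timing rule partitions the net-count axis into six regions; each has
a value function (expected gain in discounted life-years over the
no-transplant baseline, except the delisted region whose value is the
plain residual life expectancy LNT):

* ``vr1`` — list now: ``(1 - p(k)) LT + (delta - LNT)``;
* ``vr2`` — far from the listing boundary, the pure waiting option:
  ``A beta1^k / (theta^k + (1-theta)^k)``;
* ``vr3`` — one signal away from listing: a one-step mixture of ``vr1``
  and ``vr2``;
* ``vo4``/``vr4`` — listed, with the option to delist:
  ``vo4 = B beta2^k / (theta^k + (1-theta)^k)``, ``vr4 = vr1 + vo4``;
* ``vo5``/``vr5`` — listed, one signal from delisting:
  ``vo5 = mu/(r+mu) (p + theta - 2 theta p) LNT``, ``vr5 = vr1 + vo5``;
* ``vr6`` — delisted: ``LNT``.

Orientation convention
----------------------
Every formula above is evaluated verbatim with the unlisted belief
``p(k)``.  The listed-region interchange of ``theta`` and ``1 - theta``
is realised geometrically: the value-matching conditions that pin the
constants hold at the *mirrored* lattice positions ``-k_high`` and
``-k_low`` (mirroring the axis is the same operation as swapping
``p <-> 1-p`` in every formula).  The delisting match is imposed in the
arrangement the closed-form boundary belief actually satisfies,
``vr1 - vo5 = LNT`` (the option value enters on the delisted side of the
equality).  With these conventions all four matching residuals vanish at
the closed-form thresholds; see the methods note for the full discussion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .belief import posterior_good, trans_down, trans_up
from .params import ModelParams
from .thresholds import Thresholds, compute_thresholds

__all__ = ["ValueModel", "solve_constants", "boundary_residuals"]


def _log_denom(k: float, theta: float) -> float:
    """log(theta^k + (1-theta)^k), overflow-safe."""
    return np.logaddexp(k * math.log(theta), k * math.log1p(-theta))


def weighted_power(k: float, base: float, theta: float) -> float:
    """base^k / (theta^k + (1-theta)^k) in log space."""
    return math.exp(k * math.log(base) - _log_denom(k, theta))


@dataclass(frozen=True)
class ValueModel:
    """Parameters, thresholds, and the solved option constants A and B."""

    params: ModelParams
    thresholds: Thresholds
    A: float
    B: float

    # -- matching points (mirrored threshold positions) ------------------
    @property
    def match_high(self) -> float:
        """Lattice position where the listing value-matching holds."""
        return -self.thresholds.k_high

    @property
    def match_low(self) -> float:
        """Lattice position where the delisting value-matching holds."""
        return -self.thresholds.k_low

    # -- region values ----------------------------------------------------
    def vr1(self, k: float) -> float:
        """Value of listing now."""
        p = posterior_good(k, self.params.theta)
        return (1.0 - p) * self.params.lt + (self.params.delta - self.params.lnt)

    def vr2(self, k: float) -> float:
        """Waiting-option value far above the listing boundary."""
        return self.A * weighted_power(k, self.thresholds.beta1, self.params.theta)

    def vr3(self, k: float) -> float:
        """Value one signal away from the listing boundary."""
        p = posterior_good(k, self.params.theta)
        c = self.params.discount_factor
        return c * (
            trans_down(p, self.params.theta) * self.vr1(k - 1.0)
            + trans_up(p, self.params.theta) * self.vr2(k + 1.0)
        )

    def vo4(self, k: float) -> float:
        """Delisting-option value inside the listed region."""
        return self.B * weighted_power(k, self.thresholds.beta2, self.params.theta)

    def vr4(self, k: float) -> float:
        return self.vr1(k) + self.vo4(k)

    def vo5(self, k: float) -> float:
        """Delisting-option value one signal from the delisting boundary."""
        p = posterior_good(k, self.params.theta)
        c = self.params.discount_factor
        return c * trans_up(p, self.params.theta) * self.params.lnt

    def vr5(self, k: float) -> float:
        return self.vr1(k) + self.vo5(k)

    def vr6(self, k: float = 0.0) -> float:
        """Delisted: residual life expectancy, independent of k."""
        return self.params.lnt


def solve_constants(params: ModelParams, thresholds: Thresholds | None = None) -> ValueModel:
    """Solve the option constants A and B from the matching conditions.

    A comes from the smooth continuation requirement one step above the
    listing boundary (linear in A); B from equality of the two
    delisting-option forms one step inside the delisting boundary
    (linear in B).  The remaining two conditions — value matching at the
    boundaries themselves — are *not* used and become the residual checks
    of :func:`boundary_residuals`.
    """
    if thresholds is None:
        thresholds = compute_thresholds(params)
    th = params.theta
    c = params.discount_factor

    kh = -thresholds.k_high  # mirrored matching point
    p1 = posterior_good(kh + 1.0, th)
    g1 = weighted_power(kh + 1.0, thresholds.beta1, th)
    g2 = weighted_power(kh + 2.0, thresholds.beta1, th)
    vr1_kh = (1.0 - posterior_good(kh, th)) * params.lt + (params.delta - params.lnt)
    denom = g1 - c * trans_up(p1, th) * g2
    if abs(denom) < 1e-14 * max(1.0, abs(g1)):
        raise ValueError("singular solve for the waiting-option constant A")
    A = c * trans_down(p1, th) * vr1_kh / denom

    kl = -thresholds.k_low
    pmid = posterior_good(kl - 1.0, th)
    vo5_mid = c * trans_up(pmid, th) * params.lnt
    h_mid = weighted_power(kl - 1.0, thresholds.beta2, th)
    if abs(h_mid) < 1e-300:
        raise ValueError("singular solve for the delisting-option constant B")
    B = vo5_mid / h_mid

    return ValueModel(params=params, thresholds=thresholds, A=A, B=B)


def boundary_residuals(vm: ValueModel) -> dict[str, float]:
    """Signed residuals of the four matching conditions at the closed-form
    thresholds.  All four vanish (to solver precision) for valid
    parameters; the two ``*_smooth`` entries are zero by construction of
    A and B, the two ``*_match`` entries verify that the closed-form
    boundary beliefs solve the matching systems."""
    kh, kl = vm.match_high, vm.match_low
    return {
        "listing_match": vm.vr1(kh) - vm.vr3(kh),
        "listing_smooth": vm.vr2(kh + 1.0) - vm.vr3(kh + 1.0),
        "delisting_match": vm.vr1(kl) - vm.vo5(kl) - vm.params.lnt,
        "delisting_smooth": vm.vo5(kl - 1.0) - vm.vo4(kl - 1.0),
    }
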
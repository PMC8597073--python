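"""Independent numerical recovery of the listing window on the signal lattice.

This module validates the closed-form thresholds without using the
closed-form chain (quadratic root -> Psi -> boundary belief -> k).  For
each boundary it works directly from the value-matching system on the
lattice:

* the second matching condition is solved for the option constant
  (linear in A, resp. B) at a *candidate* boundary position;
* the first matching condition's residual then becomes a function of the
  candidate position alone; its sign changes are located by a scan over
  a wide lattice span and polished by Brent root-finding.

The recovered continuous boundaries must agree with the closed forms,
and the integer stopping/delisting edges with their floors.  The module
also cross-checks the analytic region solutions by fixed-point (Jacobi)
relaxation of the lattice recursions, a contraction with per-sweep
factor at most ``mu/(r+mu)``.

A genuine Bellman value iteration (max of stop payoff and discounted
expected continuation) is deliberately *not* used: the model's matched
solution does not satisfy the global variational inequality (the printed
stopping payoffs mix gain-scale and absolute-scale quantities), so a
max-operator fixed point recovers a different, degenerate stopping set.
The free-boundary solve above is the well-posed numerical counterpart of
the threshold construction.  See the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .belief import posterior_good, trans_down, trans_up
from .params import ModelParams
from .values import weighted_power

__all__ = ["LatticeProblem", "LatticeSolution", "solve_prelisting", "solve_listed"]


@dataclass(frozen=True)
class LatticeProblem:
    """Lattice span and numerical controls for a free-boundary solve."""

    params: ModelParams
    k_min: int = -25
    k_max: int = 25
    tol: float = 1e-10
    max_iter: int = 100_000
    scan_step: float = 0.05

    def __post_init__(self) -> None:
        if self.k_min >= self.k_max:
            raise ValueError("k_min must be < k_max")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class LatticeSolution:
    """Result of one lattice solve."""

    problem: LatticeProblem
    boundary: float              #: continuous threshold on the reported k axis
    stopping_set: list[int]      #: lattice points where stopping is indicated
    values: dict[int, float]     #: matched per-point values (mirrored lattice)
    relaxation_error: float      #: sup-norm gap, analytic vs relaxed recursion
    sup_changes: list[float] = field(default_factory=list)

    @property
    def edge(self) -> int | None:
        """Upper edge (max element) of the stopping set, or None if empty."""
        return max(self.stopping_set) if self.stopping_set else None


def _beta1(params: ModelParams) -> float:
    b = (params.r + params.mu) / params.mu
    return (b - math.sqrt(b * b - 4.0 * params.theta * (1.0 - params.theta))) / 2.0


def _beta2(params: ModelParams) -> float:
    return params.mu * params.theta * (1.0 - params.theta) / (params.r + params.mu)


def _scan_roots(f, lo: float, hi: float, step: float) -> list[float]:
    """All sign-change roots of f on [lo, hi], located by Brent's method."""
    xs = np.arange(lo, hi + step, step)
    vals = np.array([f(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(float(xs[i]))
        elif a * b < 0.0:
            roots.append(float(brentq(f, xs[i], xs[i + 1], xtol=1e-13, rtol=1e-15)))
    return roots


def _listing_residual(params: ModelParams):
    """Residual of the listing value-matching as a function of the
    candidate boundary position kappa on the (mirrored) value lattice."""
    th, c = params.theta, params.discount_factor
    b1 = _beta1(params)

    def vr1(k: float) -> float:
        return (1.0 - posterior_good(k, th)) * params.lt + (params.delta - params.lnt)

    def g(k: float) -> float:
        return weighted_power(k, b1, th)

    def F(kappa: float) -> float:
        p1 = posterior_good(kappa + 1.0, th)
        denom = g(kappa + 1.0) - c * trans_up(p1, th) * g(kappa + 2.0)
        if denom == 0.0:
            return math.nan
        A = c * trans_down(p1, th) * vr1(kappa) / denom
        p0 = posterior_good(kappa, th)
        vr3 = c * (trans_down(p0, th) * vr1(kappa - 1.0) + trans_up(p0, th) * A * g(kappa + 1.0))
        return vr1(kappa) - vr3

    return F, vr1, g


def _delisting_residual(params: ModelParams):
    th, c = params.theta, params.discount_factor

    def vr1(k: float) -> float:
        return (1.0 - posterior_good(k, th)) * params.lt + (params.delta - params.lnt)

    def G(kappa: float) -> float:
        vo5 = c * trans_up(posterior_good(kappa, th), th) * params.lnt
        return vr1(kappa) - vo5 - params.lnt

    return G, vr1


def solve_prelisting(problem: LatticeProblem) -> LatticeSolution:
    """Recover the upper (listing) boundary and the listing stopping set.

    Returns the continuous boundary on the reported axis, the stopping
    set (all lattice counts at or below its floor), the matched per-point
    values, and the sup-norm gap between the analytic continuation
    solution and its Jacobi-relaxed lattice counterpart.
    """
    params = problem.params
    F, vr1, g = _listing_residual(params)
    roots = _scan_roots(F, problem.k_min, problem.k_max, problem.scan_step)
    if not roots:
        raise ValueError("no listing boundary found on the lattice; widen the span")
    if len(roots) > 1:
        raise ValueError(f"listing boundary is not unique on this lattice: {roots}")
    kappa_star = roots[0]
    boundary = -kappa_star  # map back to the reported axis
    if boundary > problem.k_max - 5 or boundary < problem.k_min + 5:
        raise ValueError("boundary within 5 lattice points of the edge; widen the span")

    # matched option constant at the boundary
    th, c = params.theta, params.discount_factor
    p1 = posterior_good(kappa_star + 1.0, th)
    A = (
        c
        * trans_down(p1, th)
        * vr1(kappa_star)
        / (g(kappa_star + 1.0) - c * trans_up(p1, th) * g(kappa_star + 2.0))
    )

    # matched per-point values on the value lattice
    values: dict[int, float] = {}
    for k in range(problem.k_min, problem.k_max + 1):
        if k <= kappa_star:
            values[k] = vr1(k)
        elif k <= kappa_star + 1.0:
            p0 = posterior_good(k, th)
            values[k] = c * (
                trans_down(p0, th) * vr1(k - 1.0) + trans_up(p0, th) * A * g(k + 1.0)
            )
        else:
            values[k] = A * g(k)

    # Jacobi relaxation of the continuation recursion, cross-checked
    lo = math.floor(kappa_star + 1.0) + 1
    hi = problem.k_max
    interior = list(range(lo + 1, hi))
    sup_changes: list[float] = []
    relax_err = 0.0
    if interior:
        v = {k: 0.0 for k in interior}
        left, right = values[lo], 0.0  # analytic anchor; far-field asymptote
        for _ in range(problem.max_iter):
            delta_sup = 0.0
            new = {}
            for k in interior:
                p0 = posterior_good(k, th)
                vm = v.get(k - 1, left) if k - 1 >= lo + 1 else left
                vp = v.get(k + 1, right) if k + 1 <= hi - 1 else right
                nv = c * (trans_down(p0, th) * vm + trans_up(p0, th) * vp)
                delta_sup = max(delta_sup, abs(nv - v[k]))
                new[k] = nv
            v = new
            sup_changes.append(delta_sup)
            if delta_sup < problem.tol:
                break
        else:
            raise ValueError(
                f"lattice relaxation did not converge in {problem.max_iter} sweeps; "
                f"last sup-norm change {sup_changes[-1]:.3e}"
            )
        relax_err = max(abs(v[k] - values[k]) for k in interior)

    stopping = [k for k in range(problem.k_min, problem.k_max + 1) if k <= math.floor(boundary)]
    return LatticeSolution(
        problem=problem,
        boundary=boundary,
        stopping_set=stopping,
        values=values,
        relaxation_error=relax_err,
        sup_changes=sup_changes,
    )


def solve_listed(problem: LatticeProblem) -> LatticeSolution:
    """Recover the lower (delisting) boundary and the delist set.

    The delisting option follows a one-sided recursion (only adverse
    signals are modelled once listed); the analytic geometric solution is
    cross-checked by iterating the recursion across the listed band.
    An empty delist set is returned when the delisting payoff is too
    small for the matching condition to have a solution (e.g. LNT -> 0).
    """
    params = problem.params
    G, vr1 = _delisting_residual(params)
    roots = _scan_roots(G, problem.k_min, problem.k_max, problem.scan_step)
    if not roots:
        return LatticeSolution(
            problem=problem,
            boundary=math.nan,
            stopping_set=[],
            values={},
            relaxation_error=0.0,
        )
    if len(roots) > 1:
        raise ValueError(f"delisting boundary is not unique on this lattice: {roots}")
    kappa_star = roots[0]
    boundary = -kappa_star

    th, c = params.theta, params.discount_factor
    b2 = _beta2(params)
    anchor = kappa_star - 1.0
    B = (
        c
        * trans_up(posterior_good(anchor, th), th)
        * params.lnt
        / weighted_power(anchor, b2, th)
    )

    # one-sided recursion iterated across the listed band, vs analytic form
    values: dict[int, float] = {}
    ks = [k for k in range(problem.k_min, problem.k_max + 1) if k <= kappa_star]
    relax_err = 0.0
    if ks:
        k0 = ks[0]
        v = B * weighted_power(k0, b2, th)
        values[k0] = v
        for k in ks[1:]:
            v = c * trans_down(posterior_good(k, th), th) * v
            values[k] = v
            relax_err = max(relax_err, abs(v - B * weighted_power(k, b2, th)))

    delist = [k for k in range(problem.k_min, problem.k_max + 1) if k <= math.floor(boundary)]
    return LatticeSolution(
        problem=problem,
        boundary=boundary,
        stopping_set=delist,
        values=values,
        relaxation_error=relax_err,
    )
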
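"""Model parameters for the transplant-listing timing model.

The decision rule is driven by six scalars:

``mu``
    rate of clinical decline — expected number of new comorbidities the
    patient develops per year (Poisson intensity of signal arrivals);
``theta``
    signal quality — probability that a checklist signal correctly
    reflects the true posttransplant outcome; must differ from 1/2,
    otherwise signals carry no information and the net-count scale is
    undefined;
``r``
    the decision maker's discount rate per year;
``delta``
    expected waiting time on the list before an organ arrives (years);
``lt``
    posttransplant life expectancy given a Good outcome (years);
``lnt``
    life expectancy without the transplant (years).

The model assumes ``delta < lnt`` (a patient should be expected to
survive the wait) and ``lnt < lt`` (the transplant must be worthwhile),
and fixes the prior belief of a Good outcome at one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["ModelParams", "validate_params", "sample_valid_params"]


@dataclass(frozen=True)
class ModelParams:
    """Validated parameter set; construction enforces the model assumptions."""

    mu: float
    theta: float
    r: float
    delta: float
    lt: float
    lnt: float
    p0: float = 0.5
    #: derived listing cost in life-years: lnt - delta
    cost: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("mu", "theta", "r", "delta", "lt", "lnt", "p0"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if self.mu <= 0:
            raise ValueError("mu must be > 0 (comorbidity arrival rate per year)")
        if self.r <= 0:
            raise ValueError("r must be > 0 (discount rate per year)")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie strictly in (0, 1)")
        if self.theta == 0.5:
            raise ValueError(
                "theta must differ from 1/2: the net signal count k is "
                "undefined at theta=1/2 (signals are uninformative)"
            )
        if self.delta <= 0:
            raise ValueError("delta must be > 0 (expected waiting time in years)")
        if self.delta >= self.lnt:
            raise ValueError("delta must be < LNT (patient must be expected to survive the wait)")
        if self.lnt >= self.lt:
            raise ValueError("LNT must be < LT (transplant must extend life expectancy)")
        if self.p0 != 0.5:
            raise ValueError("the prior belief p0 is fixed at 1/2 in this model")
        object.__setattr__(self, "cost", self.lnt - self.delta)

    @property
    def discount_factor(self) -> float:
        """Per-event discount factor mu/(r+mu) of the embedded signal chain."""
        return self.mu / (self.r + self.mu)


def validate_params(
    mu: float, theta: float, r: float, delta: float, lt: float, lnt: float
) -> ModelParams:
    """Validate the six raw scalars and return a :class:`ModelParams`.

    Raises ``ValueError`` naming the violated assumption.
    """
    return ModelParams(mu=mu, theta=theta, r=r, delta=delta, lt=lt, lnt=lnt)


def sample_valid_params(rng, max_tries: int = 1000) -> ModelParams:
    """Draw one clinically plausible, fully valid parameter set.

    Ranges: theta in (0.55, 0.95) — informative signals better than a coin
    flip; mu in (0.5, 6) comorbidities/year; r in (2%, 20%)/year; lnt in
    (1, 4) years for a failing Fontan; delta a fraction (0.1–0.9) of lnt;
    lt between 5x and 12x lnt. Draws are rejected until the closed-form
    thresholds are well defined (p_high, p_low probabilities, a non-empty
    continuous listing window).
    """
    from .thresholds import compute_thresholds

    for _ in range(max_tries):
        theta = rng.uniform(0.55, 0.95)
        mu = rng.uniform(0.5, 6.0)
        r = rng.uniform(0.02, 0.2)
        lnt = rng.uniform(1.0, 4.0)
        delta = rng.uniform(0.1, 0.9) * lnt
        lt = lnt * rng.uniform(5.0, 12.0)
        try:
            params = ModelParams(mu=mu, theta=theta, r=r, delta=delta, lt=lt, lnt=lnt)
            compute_thresholds(params)
        except ValueError:
            continue
        return params
    raise RuntimeError("could not sample a valid parameter set")
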
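"""Monte Carlo patient trajectories and policy evaluation.

The generator emulates the model's signal process: a latent
posttransplant outcome (Good/Bad, prior 1/2) is drawn once; new signals
arrive at Poisson rate ``mu`` per year; each signal correctly reflects
the latent outcome with probability ``theta``.  A Good-indicative signal
moves the net count k up by one, a Bad-indicative signal moves it down —
one fixed convention for the whole trajectory.  Marginalising the latent
outcome, the one-step move probabilities at belief ``p = posterior_good(k)``
are exactly the model's transition coefficients
``(down, up) = (2p*theta + 1 - theta - p,  p + theta - 2*theta*p)``.

Life-expectancy accounting (memoryless, matching the model's use of LNT
as a residual quantity): an unlisted or delisted patient's residual life
is LNT from that moment; a listed patient waits an exponential time with
mean ``delta`` (configurable to a fixed delay) and dies waiting if no
organ arrives within LNT; at transplant the latent outcome resolves —
Good grants LT residual years, Bad is immediate death.  Realised
discounted life-years are the discounted value (at rate ``r``, from
t = 0) of the residual-life annuity granted at terminal resolution, so
they always lie in [0, LT].

The flip of signal interpretation between the unlisted and listed
regions in the decision theory is *not* reproduced generatively — a
single signal law cannot honour both orientations at once.  The
simulator keeps the fixed convention above and leaves the orientation
swap to the region formulas.  See the methods note.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .belief import ChecklistAssessment, ChecklistEntry, Orientation, posterior_good
from .params import ModelParams
from .thresholds import DecisionLabel, Thresholds, decide

__all__ = [
    "Terminal",
    "Trajectory",
    "PolicyEvaluation",
    "threshold_policy",
    "never_list_policy",
    "immediate_list_policy",
    "simulate_trajectory",
    "evaluate_policy",
    "signal_stream",
    "trajectory_to_frame",
    "generate_checklist_fixture",
]


class Terminal(str, enum.Enum):
    TRANSPLANTED = "Transplanted"
    DIED_WAITING = "DiedWaiting"
    DELISTED = "Delisted"
    NEVER_LISTED = "NeverListed"
    HORIZON_END = "HorizonEnd"


@dataclass
class Trajectory:
    seed: object
    latent_outcome: str                    # "Good" | "Bad"
    event_times: list[float] = field(default_factory=list)
    k_path: list[int] = field(default_factory=list)
    belief_path: list[float] = field(default_factory=list)
    decision_path: list[DecisionLabel] = field(default_factory=list)
    terminal: Terminal = Terminal.HORIZON_END
    discounted_life_years: float = 0.0
    listed_at: float | None = None
    transplanted_at: float | None = None


def threshold_policy(thresholds: Thresholds):
    """The model's three-way rule as a policy callable k -> label."""

    def policy(k: int) -> DecisionLabel:
        return decide(k, thresholds).value

    return policy


def never_list_policy(k: int) -> DecisionLabel:
    return DecisionLabel.TOO_WELL


def immediate_list_policy(k: int) -> DecisionLabel:
    return DecisionLabel.LIST


def _annuity(years: float, r: float) -> float:
    """Discounted value, in years, of living ``years`` starting now."""
    if years <= 0.0:
        return 0.0
    return (1.0 - math.exp(-r * years)) / r


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trajectory(
    params: ModelParams,
    policy,
    horizon: float,
    seed,
    k0: int = 0,
    listed_mode: str = "all_signals",
    fixed_wait: bool = False,
) -> Trajectory:
    """Simulate one patient under a listing policy.

    ``policy`` maps the integer count k to a :class:`DecisionLabel`; it
    is consulted at time zero and after every signal.  ``listed_mode``
    controls signal arrivals after listing: ``"all_signals"`` (default)
    keeps the common signal law; ``"down_only"`` admits only adverse
    moves, mirroring the theory's listed-region assumption.
    ``fixed_wait`` replaces the exponential organ wait by its mean.
    """
    if horizon <= 0.0:
        raise ValueError("horizon must be positive")
    if listed_mode not in ("all_signals", "down_only"):
        raise ValueError("listed_mode must be 'all_signals' or 'down_only'")
    rng = _rng_from(seed)
    traj = Trajectory(seed=seed, latent_outcome="Good" if rng.random() < params.p0 else "Bad")
    good = traj.latent_outcome == "Good"

    k = k0
    t = 0.0
    listed = False
    organ_at = math.inf   # absolute organ arrival time once listed
    dead_at = params.lnt  # absolute death time without transplant (memoryless LNT)

    def consult(now: float) -> DecisionLabel:
        nonlocal listed, organ_at, dead_at
        label = policy(k)
        traj.decision_path.append(label)
        if not listed and label is DecisionLabel.LIST:
            listed = True
            traj.listed_at = now
            wait = params.delta if fixed_wait else rng.exponential(params.delta)
            organ_at = now + wait
            dead_at = now + params.lnt  # residual LNT clock restarts at listing
        elif listed and label is DecisionLabel.TOO_UNWELL:
            listed = False
            organ_at = math.inf
            traj.terminal = Terminal.DELISTED
            traj.discounted_life_years = math.exp(-params.r * now) * _annuity(
                params.lnt, params.r
            )
        return label

    traj.k_path.append(k)
    traj.belief_path.append(posterior_good(k, params.theta))
    consult(0.0)

    while True:
        dt = rng.exponential(1.0 / params.mu) if params.mu > 0 else math.inf
        t_next = t + dt
        # resolution events that precede the next signal
        stop_at = min(organ_at, dead_at, horizon)
        if stop_at < t_next:
            if listed and organ_at <= min(dead_at, horizon):
                traj.transplanted_at = organ_at
                traj.terminal = Terminal.TRANSPLANTED
                residual = params.lt if good else 0.0
                traj.discounted_life_years = math.exp(-params.r * organ_at) * _annuity(
                    residual, params.r
                )
            elif listed and dead_at <= min(organ_at, horizon):
                traj.terminal = Terminal.DIED_WAITING
                traj.discounted_life_years = 0.0
            elif not listed and dead_at <= horizon:
                # never listed within the no-transplant life expectancy
                traj.terminal = Terminal.NEVER_LISTED
                traj.discounted_life_years = _annuity(params.lnt, params.r)
            else:
                traj.terminal = Terminal.HORIZON_END
                traj.discounted_life_years = math.exp(-params.r * horizon) * _annuity(
                    params.lnt, params.r
                )
            return traj
        t = t_next
        correct = rng.random() < params.theta
        up = correct if good else not correct
        if listed and listed_mode == "down_only" and up:
            continue  # favourable signals suppressed in the listed region
        k += 1 if up else -1
        traj.event_times.append(t)
        traj.k_path.append(k)
        traj.belief_path.append(posterior_good(k, params.theta))
        consult(t)
        if traj.terminal is Terminal.DELISTED and not listed:
            return traj


@dataclass
class PolicyEvaluation:
    mean: float
    se: float
    n_reps: int
    terminal_counts: dict[str, int]
    values: np.ndarray


def evaluate_policy(
    params: ModelParams,
    policy,
    n_reps: int,
    horizon: float,
    seed: int,
    **traj_kwargs,
) -> PolicyEvaluation:
    """Mean discounted life-years of a policy, with Monte Carlo standard error.

    Replicate RNGs are spawned from a single seed sequence, so results
    are reproducible and independent of evaluation order.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    child_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    values = np.empty(n_reps)
    counts: dict[str, int] = {}
    for i, ss in enumerate(child_seeds):
        traj = simulate_trajectory(
            params, policy, horizon, np.random.default_rng(ss), **traj_kwargs
        )
        values[i] = traj.discounted_life_years
        counts[traj.terminal.value] = counts.get(traj.terminal.value, 0) + 1
    return PolicyEvaluation(
        mean=float(values.mean()),
        se=float(values.std(ddof=1) / math.sqrt(n_reps)),
        n_reps=n_reps,
        terminal_counts=counts,
        values=values,
    )


def signal_stream(params: ModelParams, n_events: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Free-running signal dynamics for transition-frequency checks.

    Returns (k_before, move) arrays over ``n_events`` signal arrivals of
    a single patient (no policy, no absorption); ``move`` is +1/-1.
    """
    rng = _rng_from(seed)
    good = rng.random() < params.p0
    k = 0
    ks = np.empty(n_events, dtype=int)
    moves = np.empty(n_events, dtype=int)
    for i in range(n_events):
        ks[i] = k
        correct = rng.random() < params.theta
        up = correct if good else not correct
        moves[i] = 1 if up else -1
        k += moves[i]
    return ks, moves


def trajectory_to_frame(traj: Trajectory):
    """Flatten a trajectory to one row per consultation (time 0 plus each
    signal event): columns time, k, belief, decision, plus constant
    columns latent_outcome, terminal, discounted_life_years."""
    import pandas as pd

    times = [0.0] + list(traj.event_times)
    return pd.DataFrame(
        {
            "time": times,
            "k": traj.k_path,
            "belief": traj.belief_path,
            "decision": [d.value for d in traj.decision_path],
            "latent_outcome": traj.latent_outcome,
            "terminal": traj.terminal.value,
            "discounted_life_years": traj.discounted_life_years,
        }
    )


def generate_checklist_fixture(n_good: int, n_bad: int, seed=None) -> ChecklistAssessment:
    """Synthetic checklist with the requested signal composition.

    Symptom labels are generic; a seed shuffles the row order (cosmetic
    only — the net count depends only on the composition).
    """
    if n_good < 0 or n_bad < 0:
        raise ValueError("signal counts must be non-negative")
    entries = [
        ChecklistEntry(symptom=f"good_sign_{i + 1}", present=True, orientation=Orientation.GOOD)
        for i in range(n_good)
    ] + [
        ChecklistEntry(symptom=f"comorbidity_{i + 1}", present=True, orientation=Orientation.BAD)
        for i in range(n_bad)
    ]
    if seed is not None:
        rng = _rng_from(seed)
        order = rng.permutation(len(entries))
        entries = [entries[int(i)] for i in order]
    return ChecklistAssessment(entries=tuple(entries))
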
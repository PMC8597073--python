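"""Parameter sweeps and signal-quality estimation from outcome records."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import ModelParams
from .thresholds import compute_thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "SweepResult",
    "sweep",
    "OutcomeRecord",
    "estimate_signal_quality",
    "simulate_estimation_records",
]

_SWEEPABLE = {"delta", "lnt", "mu"}


@dataclass
class SweepResult:
    """Thresholds along a one-parameter grid, with monotonicity verdicts."""

    parameter: str
    table: pd.DataFrame  # columns: value, k_high, k_low, k_high_floor, k_low_floor
    verdicts: dict[str, bool]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, path) -> None:
        """Step plot of the integer listing and delisting edges along the grid."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
        t = self.table
        axes[0].step(t["value"], t["k_high_floor"], where="mid")
        axes[0].set_ylabel("floor(k_high)")
        axes[0].set_title("listing edge")
        axes[1].step(t["value"], t["k_low_floor"], where="mid")
        axes[1].set_ylabel("floor(k_low)")
        axes[1].set_title("delisting edge")
        for ax in axes:
            ax.set_xlabel(self.parameter)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _monotone(x: np.ndarray, direction: str) -> bool:
    d = np.diff(x[np.isfinite(x)])
    return bool(np.all(d > 0) if direction == "inc" else np.all(d < 0))


def sweep(params: ModelParams, name: str, grid, strict: bool = False) -> SweepResult:
    """Recompute the thresholds along a grid of one parameter.

    Grid points where the parameters (or the delisting belief) are
    invalid are skipped with a warning, or rejected in strict mode; the
    upper threshold is still recorded when only the lower one fails.
    Verdicts report the threshold's direction of travel along the grid
    and whether the integer delisting edge stays put.
    """
    if name not in _SWEEPABLE:
        raise ValueError(f"sweep parameter must be one of {sorted(_SWEEPABLE)}")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing with at least two points")

    rows = []
    for v in grid:
        try:
            p = replace(params, **{name: float(v)})
        except ValueError as exc:
            if strict:
                raise
            logger.warning("skipping %s=%g: %s", name, v, exc)
            continue
        try:
            th = compute_thresholds(p)
            rows.append((v, th.k_high, th.k_low, th.k_high_floor, th.k_low_floor))
        except ValueError as exc:
            if strict:
                raise
            # the upper threshold may still be defined when p_low is not
            try:
                from .thresholds import k_high as _kh

                kh = _kh(p)
                logger.warning("%s=%g: lower threshold undefined (%s)", name, v, exc)
                rows.append((v, kh, math.nan, math.floor(kh), np.nan))
            except ValueError as exc2:
                logger.warning("skipping %s=%g: %s", name, v, exc2)
    table = pd.DataFrame(
        rows, columns=["value", "k_high", "k_low", "k_high_floor", "k_low_floor"]
    )
    kh = table["k_high"].to_numpy()
    kl_floor = table["k_low_floor"].to_numpy(dtype=float)
    verdicts = {
        "k_high_increasing": _monotone(kh, "inc"),
        "k_high_decreasing": _monotone(kh, "dec"),
        "k_low_floor_constant": bool(
            np.unique(kl_floor[np.isfinite(kl_floor)]).size <= 1
        ),
    }
    return SweepResult(parameter=name, table=table, verdicts=verdicts)


@dataclass(frozen=True)
class OutcomeRecord:
    """One historical patient: which checklist signals were present at
    transplant, and the realised outcome ("Good"/"Bad")."""

    present: tuple[bool, ...]
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in ("Good", "Bad"):
            raise ValueError("outcome must be 'Good' or 'Bad'")


def estimate_signal_quality(
    records: list[OutcomeRecord],
    orientations: list[str] | None = None,
) -> tuple[list[float], float]:
    """Per-signal quality and the composite theta from historical records.

    A signal's quality is the proportion of patients who had it whose
    outcome matched its orientation (for a Bad-indicative comorbidity:
    how often the outcome was indeed Bad).  The composite theta is the
    exposure-weighted mean of the per-signal proportions; signals never
    observed present are excluded (logged).  A composite of 1 (or 0)
    degenerates the belief model and is flagged.
    """
    if not records:
        raise ValueError("need at least one record")
    n_signals = len(records[0].present)
    if any(len(rec.present) != n_signals for rec in records):
        raise ValueError("all records must cover the same signal list")
    if orientations is None:
        orientations = ["bad"] * n_signals
    if len(orientations) != n_signals:
        raise ValueError("one orientation per signal required")

    per_signal: list[float] = []
    exposures: list[int] = []
    for j in range(n_signals):
        exposed = [rec for rec in records if rec.present[j]]
        if not exposed:
            logger.warning("signal %d never observed present; excluded", j)
            per_signal.append(math.nan)
            exposures.append(0)
            continue
        target = "Bad" if orientations[j].lower() == "bad" else "Good"
        correct = sum(1 for rec in exposed if rec.outcome == target)
        per_signal.append(correct / len(exposed))
        exposures.append(len(exposed))

    w = np.array(exposures, dtype=float)
    q = np.array(per_signal, dtype=float)
    mask = w > 0
    if not mask.any():
        raise ValueError("no signal had any exposure")
    composite = float((q[mask] * w[mask]).sum() / w[mask].sum())
    if composite in (0.0, 1.0) or composite == 0.5:
        logger.warning(
            "composite theta=%g degenerates the belief model (theta must be "
            "in (0,1) and != 1/2 for decision use)",
            composite,
        )
    return per_signal, composite


def simulate_estimation_records(
    true_theta: float, n_patients: int, n_signals: int, seed
) -> list[OutcomeRecord]:
    """Generate synthetic outcome records with known signal quality.

    Each patient draws a Good/Bad outcome with probability 1/2; each
    (Bad-indicative) signal is present with probability ``true_theta``
    when the outcome is Bad and ``1 - true_theta`` otherwise, so that
    among exposed patients the outcome matches the orientation with
    probability ``true_theta`` exactly.
    """
    if not (0.0 < true_theta < 1.0):
        raise ValueError("true_theta must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_patients):
        outcome = "Bad" if rng.random() < 0.5 else "Good"
        p_present = true_theta if outcome == "Bad" else 1.0 - true_theta
        present = tuple(bool(x) for x in rng.random(n_signals) < p_present)
        records.append(OutcomeRecord(present=present, outcome=outcome))
    return records
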
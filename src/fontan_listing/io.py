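"""File formats: symptom checklists, parameter configs, outcome records,
run manifests.

Checklist dialect (CSV columns, case-insensitive): ``symptom``,
``observed`` (yes|no|na), ``orientation`` (good|bad).  The orientation
qualifies the row *as observed*: every yes/no row contributes exactly one
oriented signal (a "no" can be the informative state, e.g. absence of
severe cirrhosis is Good-indicative); ``na`` rows contribute nothing.
The JSON dialect is a list of objects with the same keys.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .belief import ChecklistAssessment, ChecklistEntry, Orientation
from .params import ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "read_checklist",
    "write_checklist",
    "load_params",
    "save_params",
    "write_manifest",
]

_OBSERVED = {"yes": True, "no": False, "na": None, "n/a": None, "": None}
_ORIENT = {"good": Orientation.GOOD, "bad": Orientation.BAD}


def _entries_from_rows(rows) -> ChecklistAssessment:
    entries = []
    for i, row in enumerate(rows):
        symptom = str(row["symptom"]).strip()
        obs_token = str(row["observed"]).strip().lower()
        if obs_token not in _OBSERVED:
            raise ValueError(
                f"row {i + 1} ({symptom!r}): unknown observed token {obs_token!r} "
                "(expected yes|no|na)"
            )
        orient_token = str(row["orientation"]).strip().lower()
        if obs_token in ("na", "n/a", ""):
            continue
        if orient_token not in _ORIENT:
            raise ValueError(
                f"row {i + 1} ({symptom!r}): unknown orientation token "
                f"{orient_token!r} (expected good|bad)"
            )
        entries.append(
            ChecklistEntry(
                symptom=symptom,
                present=_OBSERVED[obs_token],
                orientation=_ORIENT[orient_token],
            )
        )
    assessment = ChecklistAssessment(entries=tuple(entries))
    n_good = sum(1 for e in assessment.entries if e.orientation is Orientation.GOOD)
    if assessment.n == 0:
        logger.warning("checklist contains no signals; belief stays at the prior")
    logger.info(
        "checklist parsed: n=%d (good=%d, bad=%d), k=%d",
        assessment.n, n_good, assessment.b, assessment.k,
    )
    return assessment


def read_checklist(path, dialect: str | None = None) -> ChecklistAssessment:
    """Read a checklist file (CSV or JSON; inferred from the extension)."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"symptom", "observed", "orientation"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"checklist header must contain {sorted(required)}, got {list(df.columns)}"
            )
        rows = df.to_dict("records")
    elif dialect == "json":
        data = json.loads(path.read_text())
        rows = data["entries"] if isinstance(data, dict) else data
        rows = [{k.lower(): v for k, v in row.items()} for row in rows]
    else:
        raise ValueError("dialect must be 'csv' or 'json'")
    return _entries_from_rows(rows)


def write_checklist(assessment: ChecklistAssessment, path, dialect: str | None = None) -> None:
    """Serialize a checklist; round-trips through :func:`read_checklist`."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    rows = [
        {
            "symptom": e.symptom,
            "observed": "yes" if e.present else "no",
            "orientation": e.orientation.value,
        }
        for e in assessment.entries
    ]
    if dialect == "csv":
        pd.DataFrame(rows, columns=["symptom", "observed", "orientation"]).to_csv(
            path, index=False
        )
    elif dialect == "json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        raise ValueError("dialect must be 'csv' or 'json'")


_PARAM_KEYS = ("mu", "theta", "r", "delta", "lt", "lnt")


def load_params(path) -> ModelParams:
    """Load and validate a parameter config from JSON.

    An optional ``review_interval_years`` key rescales a per-interval
    comorbidity count into the per-year rate ``mu``.
    """
    data = json.loads(Path(path).read_text())
    missing = [k for k in _PARAM_KEYS if k not in data]
    if missing:
        raise ValueError(f"parameter config missing keys: {missing}")
    mu = float(data["mu"])
    interval = float(data.get("review_interval_years", 1.0))
    if interval <= 0:
        raise ValueError("review_interval_years must be positive")
    mu = mu / interval
    return ModelParams(
        mu=mu,
        theta=float(data["theta"]),
        r=float(data["r"]),
        delta=float(data["delta"]),
        lt=float(data["lt"]),
        lnt=float(data["lnt"]),
    )


def save_params(params: ModelParams, path) -> None:
    Path(path).write_text(
        json.dumps({k: getattr(params, k) for k in _PARAM_KEYS}, indent=1)
    )


def write_manifest(path, params: ModelParams, seed=None, command: str = "", extra=None) -> None:
    """Write the JSON run manifest that reproduces an output."""
    from . import __version__

    manifest = {
        "package": "fontan-listing",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": {k: getattr(params, k) for k in _PARAM_KEYS},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1))
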
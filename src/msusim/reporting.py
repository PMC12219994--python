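"""Headline derived metrics and report assembly.

The per-treated-patient benefit (the gain in P(mRS 0-2)) converts to
numbers-needed-to-attend: 1/delta_p patients treated per extra
independent-living outcome; dividing by the treatment-eligible fraction
gives attended confirmed strokes, and further by the dispatch positive
predictive value gives attended dispatches including stroke mimics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .pathway import ScenarioTimes

logger = logging.getLogger(__name__)


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class AttendanceAssumptions:
    """Assumptions converting per-treated benefit to attendance counts."""

    delta_p_independent: float = 0.02
    treatment_rate: float = 0.20
    dispatch_ppv: float = 0.50

    def __post_init__(self) -> None:
        if self.delta_p_independent <= 0:
            raise ReportError("delta_p_independent must be > 0")
        for name in ("treatment_rate", "dispatch_ppv"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ReportError(f"{name} must be in (0, 1], got {v}")


def treated_per_outcome(delta_p: float) -> float:
    """Treated patients per one additional independent-living outcome."""
    if delta_p <= 0:
        raise ReportError(f"delta_p must be > 0, got {delta_p}")
    return 1.0 / delta_p


def attendances_per_outcome(a: AttendanceAssumptions, include_mimics: bool = False) -> float:
    """Attended patients per additional independent-living outcome.

    With ``include_mimics`` the count covers all dispatches (confirmed
    strokes and mimics); without, confirmed strokes only.
    """
    n = 1.0 / (a.delta_p_independent * a.treatment_rate)
    if include_mimics:
        n /= a.dispatch_ppv
    return n


# ---------------------------------------------------------------------------
# Config loading (TOML or JSON)
# ---------------------------------------------------------------------------

def _load_structured(path: Path | str) -> dict:
    p = Path(path)
    if not p.exists():
        raise ReportError(f"config file not found: {p}")
    if p.suffix.lower() == ".toml":
        return tomllib.loads(p.read_text())
    return json.loads(p.read_text())


def load_scenario_times(path: Path | str) -> ScenarioTimes:
    """Load one scenario from a TOML/JSON file keyed by the field names."""
    raw = _load_structured(path)
    names = set(ScenarioTimes.field_names())
    flat: dict[str, float] = {}
    for key, val in raw.items():  # accept either flat keys or one nesting level
        if isinstance(val, dict):
            flat.update({k: v for k, v in val.items() if k in names})
        elif key in names:
            flat[key] = val
    missing = names - set(flat)
    if missing:
        raise ReportError(f"scenario config {path}: missing fields {sorted(missing)}")
    return ScenarioTimes(**flat)


def load_grid_levels(path: Path | str) -> dict[str, tuple[float, ...]]:
    """Load per-field level lists from a TOML/JSON file."""
    raw = _load_structured(path)
    names = set(ScenarioTimes.field_names())
    levels: dict[str, tuple[float, ...]] = {}
    for key, val in raw.items():
        if isinstance(val, dict):
            for k, v in val.items():
                if k in names:
                    levels[k] = tuple(v) if isinstance(v, (list, tuple)) else (v,)
        elif key in names:
            levels[key] = tuple(val) if isinstance(val, (list, tuple)) else (val,)
    missing = names - set(levels)
    if missing:
        raise ReportError(f"levels config {path}: missing fields {sorted(missing)}")
    return levels


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _quantile_block(df: pd.DataFrame, metrics: list[str]) -> list[dict]:
    rows = []
    for m in metrics:
        x = df[m]
        rows.append(
            {
                "section": "geographic_quantiles",
                "key": m,
                "value": float(x.median()),
                "q25": float(x.quantile(0.25)),
                "q75": float(x.quantile(0.75)),
                "min": float(x.min()),
                "max": float(x.max()),
            }
        )
    return rows


def run_report(
    out_csv: Path | str,
    scenario_summary: Optional[pd.DataFrame] = None,
    benefit_rows: Optional[pd.DataFrame] = None,
    optimiser_trace: Optional[pd.DataFrame] = None,
    assumptions: AttendanceAssumptions = AttendanceAssumptions(),
    config: Optional[dict] = None,
) -> pd.DataFrame:
    """Assemble the combined report CSV from upstream result tables.

    Sections: across-scenario summary, base-case geographic quantiles,
    optimiser trace, and the headline numbers-needed-to-attend block
    (reported unrounded and rounded).  Identical inputs give a
    byte-identical file.
    """
    records: list[dict] = []
    if scenario_summary is not None:
        if len(scenario_summary) == 0:
            raise ReportError("scenario summary is empty")
        for metric, row in scenario_summary.iterrows():
            rec = {"section": "scenario_summary", "key": metric}
            rec.update({k: float(v) for k, v in row.items()})
            records.append(rec)
    if benefit_rows is not None:
        if len(benefit_rows) == 0:
            raise ReportError("benefit table is empty")
        metrics = [c for c in benefit_rows.columns if c.startswith(("mixed_", "nlvo_", "lvo_", "delta_t"))]
        records.extend(_quantile_block(benefit_rows, metrics))
    if optimiser_trace is not None:
        if len(optimiser_trace) == 0:
            raise ReportError("optimiser trace is empty")
        for _, row in optimiser_trace.iterrows():
            records.append(
                {
                    "section": "optimiser_trace",
                    "key": str(row["unit_id"]),
                    "k": int(row["k"]),
                    "value": float(row["gain_after_k"]),
                }
            )

    npo = treated_per_outcome(assumptions.delta_p_independent)
    att = attendances_per_outcome(assumptions, include_mimics=False)
    att_m = attendances_per_outcome(assumptions, include_mimics=True)
    for key, val in (
        ("treated_per_outcome", npo),
        ("attended_confirmed_strokes_per_outcome", att),
        ("attended_dispatches_per_outcome", att_m),
    ):
        records.append({"section": "headline_nnt", "key": key, "value": val, "rounded": round(val)})

    report = pd.DataFrame.from_records(records)
    cfg = dict(config or {})
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
    logger.info("report: %d rows, config hash %s", len(report), cfg_hash)
    report.to_csv(out_csv, index=False)
    return report
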
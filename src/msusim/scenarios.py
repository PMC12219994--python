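"""Full-factorial scenario analysis of MSU benefit.

A *scenario* is one assignment of the ten non-travel process durations.
The engine builds the Cartesian grid of levels, evaluates the benefit of
MSU care over usual care for every demand unit (per cohort: nLVO, LVO and
the 70:30 treated mix), and summarises across scenarios.

Sign convention (one convention for everything): positive = MSU advantage.
Outcome deltas are MSU minus usual; time deltas are usual minus MSU.

The full national grid is 46,656 scenarios.  The sweep exploits the fact
that every reported national average is linear in per-demand-unit metrics
and that usual-care metrics depend on only six of the ten scenario fields
(MSU metrics on five): per-side national means are cached per distinct
field combination (648 usual, 288 MSU) and each scenario's deltas are
differences of cached means.  Equality with direct per-scenario evaluation
is asserted in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geography import Geography, msu_route, usual_care_route
from .outcomes import OutcomeLibrary, interpolate_cumulative
from .pathway import ScenarioTimes, TreatmentWindows


class ScenarioError(ValueError):
    pass


#: Scenario-grid levels of the national analysis (minutes).
PAPER_GRID_LEVELS: dict[str, tuple[float, ...]] = {
    "onset_to_call": (0, 60, 120, 180),
    "call_to_ambulance": (15, 30, 45),
    "ambulance_on_scene": (20, 30, 45),
    "door_to_needle": (30, 45),
    "transfer_net_delay": (30, 60, 90),
    "door_to_puncture_usual": (60, 90, 120),
    "call_to_msu_dispatch": (0, 15, 30, 45),
    "msu_arrival_to_ivt": (15, 30, 45),
    "msu_on_scene_post_ivt": (5, 15),
    "door_to_puncture_msu": (30, 60, 90),
}

_USUAL_FIELDS = (
    "onset_to_call",
    "call_to_ambulance",
    "ambulance_on_scene",
    "door_to_needle",
    "transfer_net_delay",
    "door_to_puncture_usual",
)
_MSU_FIELDS = (
    "onset_to_call",
    "call_to_msu_dispatch",
    "msu_arrival_to_ivt",
    "msu_on_scene_post_ivt",
    "door_to_puncture_msu",
)

METRICS = (
    "nlvo_delta_utility",
    "nlvo_delta_p_independent",
    "lvo_delta_utility",
    "lvo_delta_p_independent",
    "mixed_delta_utility",
    "mixed_delta_p_independent",
    "delta_t_ivt",
    "delta_t_mt",
)


@dataclass(frozen=True)
class ScenarioGrid:
    """Cartesian product of per-field levels, in deterministic row-major
    order over the canonical field order of :class:`ScenarioTimes`."""

    levels: dict[str, tuple[float, ...]]
    scenarios: tuple[ScenarioTimes, ...] = field(init=False)

    def __post_init__(self) -> None:
        names = ScenarioTimes.field_names()
        unknown = set(self.levels) - set(names)
        if unknown:
            raise ScenarioError(f"unknown scenario fields: {sorted(unknown)}")
        missing = set(names) - set(self.levels)
        if missing:
            raise ScenarioError(f"missing levels for fields: {sorted(missing)}")
        for name, lv in self.levels.items():
            if len(lv) == 0:
                raise ScenarioError(f"field {name!r} has an empty level list")
        combos = itertools.product(*(self.levels[n] for n in names))
        object.__setattr__(
            self, "scenarios", tuple(ScenarioTimes(**dict(zip(names, c))) for c in combos)
        )

    def __len__(self) -> int:
        return len(self.scenarios)


def build_grid(levels: Mapping[str, Sequence[float]]) -> ScenarioGrid:
    """Build the full-factorial grid from per-field level lists."""
    return ScenarioGrid(levels={k: tuple(v) for k, v in levels.items()})


# ---------------------------------------------------------------------------
# Precomputed routing tables
# ---------------------------------------------------------------------------

class RoutingTables:
    """Per-demand-unit travel legs for both care models, as arrays.

    Computed once per (geography, active base set); scenario evaluation is
    then pure array arithmetic.
    """

    def __init__(self, geography: Geography, active_bases: Optional[Iterable[str]] = None):
        self.geography = geography
        bases = set(active_bases) if active_bases is not None else geography.default_msu_bases
        if not bases:
            raise ScenarioError("no active MSU bases")
        self.active_bases = frozenset(bases)

        n = len(geography.demand_ids)
        self.demand_ids = np.asarray(geography.demand_ids)
        self.admissions = geography.admissions.to_numpy(dtype=float)
        self.tt_first = np.empty(n)
        self.needs_transfer = np.empty(n, dtype=bool)
        self.inter_hospital = np.zeros(n)
        self.outbound = np.empty(n)
        self.return_leg = np.empty(n)
        for i, d in enumerate(geography.demand_ids):
            u = usual_care_route(d, geography)
            self.tt_first[i] = u.travel_to_first
            self.needs_transfer[i] = u.needs_transfer
            if u.needs_transfer:
                self.inter_hospital[i] = u.inter_hospital
            m = msu_route(d, geography, bases)
            self.outbound[i] = m.outbound
            self.return_leg[i] = m.return_leg

    def with_bases(self, active_bases: Iterable[str]) -> "RoutingTables":
        """Copy with a different base set; only the outbound leg changes."""
        new = object.__new__(RoutingTables)
        new.__dict__.update(self.__dict__)
        bases = sorted(set(active_bases))
        if not bases:
            raise ScenarioError("no active MSU bases")
        new.active_bases = frozenset(bases)
        d2u = self.geography.travel.demand_to_unit
        new.outbound = d2u[bases].to_numpy(dtype=float).min(axis=1)
        return new

    # -- per-side time composition (vectorised over demand units) -------
    def usual_times(self, s: ScenarioTimes) -> tuple[np.ndarray, np.ndarray]:
        pre = s.onset_to_call + s.call_to_ambulance + s.ambulance_on_scene
        t_ivt = pre + self.tt_first + s.door_to_needle
        t_mt = (
            pre
            + self.tt_first
            + s.door_to_puncture_usual
            + self.needs_transfer * (s.transfer_net_delay + self.inter_hospital)
        )
        return t_ivt, t_mt

    def msu_times(self, s: ScenarioTimes) -> tuple[np.ndarray, np.ndarray]:
        t_ivt = s.onset_to_call + s.call_to_msu_dispatch + self.outbound + s.msu_arrival_to_ivt
        t_mt = t_ivt + s.msu_on_scene_post_ivt + self.return_leg + s.door_to_puncture_msu
        return t_ivt, t_mt


# ---------------------------------------------------------------------------
# Vectorised outcome evaluation for one care model
# ---------------------------------------------------------------------------

def _cohort_metrics(
    t_ivt: np.ndarray,
    t_mt: np.ndarray,
    lib: OutcomeLibrary,
    windows: TreatmentWindows,
) -> dict[str, np.ndarray]:
    """Per-demand-unit utility and P(mRS 0-2) for nLVO, LVO and the mix."""
    w = lib.utility_weights
    ivt_ok = t_ivt <= windows.ivt_max
    mt_ok = t_mt <= windows.mt_max

    def _eval(ref, t):
        cum = interpolate_cumulative(ref, t)
        probs = np.diff(cum, prepend=0.0, axis=1)
        return probs @ w, cum[:, 2]

    u_nlvo_tr, p_nlvo_tr = _eval(lib.refs["nLVO_IVT"], t_ivt)
    unt_n = lib.untreated["nLVO"]
    nlvo_u = np.where(ivt_ok, u_nlvo_tr, unt_n.utility(w))
    nlvo_p = np.where(ivt_ok, p_nlvo_tr, unt_n.p_independent)

    u_lvo_ivt, p_lvo_ivt = _eval(lib.refs["LVO_IVT"], t_ivt)
    u_lvo_mt, p_lvo_mt = _eval(lib.refs["LVO_MT"], t_mt)
    unt_l = lib.untreated["LVO"]

    lvo_u = np.full_like(t_ivt, unt_l.utility(w))
    lvo_p = np.full_like(t_ivt, unt_l.p_independent)
    only_ivt = ivt_ok & ~mt_ok
    only_mt = mt_ok & ~ivt_ok
    both = ivt_ok & mt_ok
    lvo_u[only_ivt] = u_lvo_ivt[only_ivt]
    lvo_p[only_ivt] = p_lvo_ivt[only_ivt]
    lvo_u[only_mt] = u_lvo_mt[only_mt]
    lvo_p[only_mt] = p_lvo_mt[only_mt]
    if lib.combination_rule == "mt_dominates":
        take_mt = both
    else:  # best_of: higher utility wins, MT on ties
        take_mt = both & (u_lvo_mt >= u_lvo_ivt)
    take_ivt = both & ~take_mt
    lvo_u[take_mt] = u_lvo_mt[take_mt]
    lvo_p[take_mt] = p_lvo_mt[take_mt]
    lvo_u[take_ivt] = u_lvo_ivt[take_ivt]
    lvo_p[take_ivt] = p_lvo_ivt[take_ivt]

    return {
        "nlvo_utility": nlvo_u,
        "nlvo_p_independent": nlvo_p,
        "lvo_utility": lvo_u,
        "lvo_p_independent": lvo_p,
        "mixed_utility": lib.p_nlvo * nlvo_u + lib.p_lvo * lvo_u,
        "mixed_p_independent": lib.p_nlvo * nlvo_p + lib.p_lvo * lvo_p,
    }


def evaluate_scenario(
    geography: Geography | RoutingTables,
    s: ScenarioTimes,
    lib: OutcomeLibrary,
    windows: TreatmentWindows = TreatmentWindows(),
    active_bases: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-demand-unit benefit of MSU care over usual care for one scenario.

    Returns one row per demand unit with outcome deltas (MSU minus usual)
    and time deltas (usual minus MSU) so that positive always means MSU
    advantage.
    """
    rt = geography if isinstance(geography, RoutingTables) else RoutingTables(geography, active_bases)
    tu_ivt, tu_mt = rt.usual_times(s)
    tm_ivt, tm_mt = rt.msu_times(s)
    mu = _cohort_metrics(tu_ivt, tu_mt, lib, windows)
    mm = _cohort_metrics(tm_ivt, tm_mt, lib, windows)
    return pd.DataFrame(
        {
            "demand_id": rt.demand_ids,
            "admissions": rt.admissions,
            "nlvo_delta_utility": mm["nlvo_utility"] - mu["nlvo_utility"],
            "nlvo_delta_p_independent": mm["nlvo_p_independent"] - mu["nlvo_p_independent"],
            "lvo_delta_utility": mm["lvo_utility"] - mu["lvo_utility"],
            "lvo_delta_p_independent": mm["lvo_p_independent"] - mu["lvo_p_independent"],
            "mixed_delta_utility": mm["mixed_utility"] - mu["mixed_utility"],
            "mixed_delta_p_independent": mm["mixed_p_independent"] - mu["mixed_p_independent"],
            "delta_t_ivt": tu_ivt - tm_ivt,
            "delta_t_mt": tu_mt - tm_mt,
        }
    )


def national_average(
    rows: pd.DataFrame,
    admissions: Optional[np.ndarray | pd.Series] = None,
    weighting: str = "unweighted",
) -> pd.Series:
    """Mean benefit across demand units, optionally admission-weighted."""
    if len(rows) == 0:
        raise ScenarioError("benefit table is empty")
    if weighting not in ("unweighted", "admission_weighted"):
        raise ScenarioError(f"unknown weighting {weighting!r}")
    metrics = [c for c in METRICS if c in rows.columns]
    if weighting == "unweighted":
        return rows[metrics].mean()
    w = np.asarray(admissions if admissions is not None else rows["admissions"], dtype=float)
    if w.sum() <= 0:
        raise ScenarioError("admission weights sum to zero")
    return pd.Series({m: float(np.average(rows[m], weights=w)) for m in metrics})


# ---------------------------------------------------------------------------
# Full-grid sweep with per-side caching
# ---------------------------------------------------------------------------

def sweep_grid(
    geography: Geography | RoutingTables,
    grid: ScenarioGrid,
    lib: OutcomeLibrary,
    windows: TreatmentWindows = TreatmentWindows(),
    active_bases: Optional[Iterable[str]] = None,
    weighting: str = "unweighted",
) -> pd.DataFrame:
    """National-average benefit for every scenario in the grid.

    Returns one row per scenario: the ten field levels plus every METRICS
    column.  Linearity of the national mean lets per-side means be cached
    per distinct usual-care / MSU field combination.
    """
    rt = geography if isinstance(geography, RoutingTables) else RoutingTables(geography, active_bases)
    if weighting not in ("unweighted", "admission_weighted"):
        raise ScenarioError(f"unknown weighting {weighting!r}")
    w = rt.admissions if weighting == "admission_weighted" else None
    if w is not None and w.sum() <= 0:
        raise ScenarioError("admission weights sum to zero")

    def _mean(x: np.ndarray) -> float:
        return float(np.average(x, weights=w))

    usual_cache: dict[tuple, np.ndarray] = {}
    msu_cache: dict[tuple, np.ndarray] = {}
    side_keys = (
        "nlvo_utility",
        "nlvo_p_independent",
        "lvo_utility",
        "lvo_p_independent",
        "mixed_utility",
        "mixed_p_independent",
    )

    records = []
    for s in grid.scenarios:
        d = s.as_dict()
        ku = tuple(d[f] for f in _USUAL_FIELDS)
        km = tuple(d[f] for f in _MSU_FIELDS)
        if ku not in usual_cache:
            t_ivt, t_mt = rt.usual_times(s)
            m = _cohort_metrics(t_ivt, t_mt, lib, windows)
            usual_cache[ku] = np.array(
                [_mean(m[k]) for k in side_keys] + [_mean(t_ivt), _mean(t_mt)]
            )
        if km not in msu_cache:
            t_ivt, t_mt = rt.msu_times(s)
            m = _cohort_metrics(t_ivt, t_mt, lib, windows)
            msu_cache[km] = np.array(
                [_mean(m[k]) for k in side_keys] + [_mean(t_ivt), _mean(t_mt)]
            )
        mu, mm = usual_cache[ku], msu_cache[km]
        rec = dict(d)
        rec.update(zip(METRICS[:6], (mm - mu)[:6]))
        rec["delta_t_ivt"] = mu[6] - mm[6]
        rec["delta_t_mt"] = mu[7] - mm[7]
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

BENEFIT_THRESHOLDS = (0.0, 0.01, 0.02, 0.03, 0.04)


def summarize_grid(
    results: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    thresholds: Sequence[float] = BENEFIT_THRESHOLDS,
) -> pd.DataFrame:
    """Across-scenario summary per metric: median, IQR, range, and the
    fraction of scenarios with benefit at or above each threshold.

    Quantiles use linear interpolation between order statistics.
    """
    if len(results) == 0:
        raise ScenarioError("no scenario results to summarise")
    metrics = list(metrics) if metrics is not None else [c for c in METRICS if c in results.columns]
    out = {}
    for m in metrics:
        x = results[m].to_numpy(dtype=float)
        row = {
            "median": float(np.median(x)),
            "q25": float(np.quantile(x, 0.25)),
            "q75": float(np.quantile(x, 0.75)),
            "min": float(x.min()),
            "max": float(x.max()),
        }
        for thr in thresholds:
            row[f"frac_ge_{thr:g}"] = float((x >= thr).mean())
        out[m] = row
    return pd.DataFrame(out).T


def grouped_parameter_effect(
    results: pd.DataFrame,
    field_name: str,
    metrics: Optional[Sequence[str]] = None,
) -> dict[float, pd.DataFrame]:
    """Partition the sweep by one scenario field's level and summarise each
    partition (the per-parameter sensitivity view)."""
    if field_name not in ScenarioTimes.field_names():
        raise ScenarioError(f"unknown scenario field {field_name!r}")
    if field_name not in results.columns:
        raise ScenarioError(f"sweep results lack column {field_name!r}")
    return {
        float(level): summarize_grid(part, metrics=metrics)
        for level, part in results.groupby(field_name, sort=True)
    }


def benefit_histograms(
    rows: pd.DataFrame,
    admissions: Optional[np.ndarray | pd.Series] = None,
    bin_width: float = 0.005,
    weighting: str = "unweighted",
    metrics: Sequence[str] = ("mixed_delta_utility", "mixed_delta_p_independent"),
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Histograms of per-demand-unit benefit, by count or admission mass.

    Returns per metric ``(bin_edges, mass)``; total mass equals the number
    of rows (unweighted) or the total admissions (admission_weighted).
    """
    if bin_width <= 0:
        raise ScenarioError("bin_width must be positive")
    if weighting == "admission_weighted":
        w = np.asarray(admissions if admissions is not None else rows["admissions"], dtype=float)
    elif weighting == "unweighted":
        w = None
    else:
        raise ScenarioError(f"unknown weighting {weighting!r}")
    out = {}
    for m in metrics:
        x = rows[m].to_numpy(dtype=float)
        lo = np.floor(x.min() / bin_width) * bin_width
        hi = np.ceil(x.max() / bin_width) * bin_width
        n_bins = max(int(round((hi - lo) / bin_width)), 1)
        edges = lo + bin_width * np.arange(n_bins + 1)
        counts, edges = np.histogram(x, bins=edges, weights=w)
        out[m] = (edges, counts)
    return out
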
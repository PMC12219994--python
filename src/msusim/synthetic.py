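"""Synthetic geographies with the statistical structure of the England inputs.

The generator emulates the national data the model is normally run on:
small demand units (one per ~1,500 residents) with Poisson-distributed
annual stroke admissions (mean 2.47 per unit per year), a hospital network
in which only a minority of units are comprehensive stroke centres, and
travel times that are symmetric and metric.  Demand is drawn from a mixture
of urban clusters over a uniform rural background so that CSCs, which are
sampled with probability proportional to local demand density, end up in
dense population centres — the qualitative siting pattern of the real
network.  Travel time is straight-line distance at constant speed, so the
matrices satisfy the triangle inequality exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geography import (
    DemandUnit,
    Geography,
    GeographyError,
    StrokeUnit,
    TravelMatrix,
    UnitType,
)

#: England-wide mean stroke admissions per demand unit per year
#: (242,874 admissions over 3 years across 32,843 areas).
DEFAULT_ADMISSIONS_MEAN = 2.47


@dataclass(frozen=True)
class SyntheticGeographyParams:
    """Parameters of the synthetic-geography generator.

    ``n_demand`` demand units and ``n_units`` stroke units (of which
    ``n_csc`` are CSCs) are placed in a square of side ``region_size_km``;
    travel time in minutes is Euclidean distance divided by ``speed_kmh``.
    Admissions are Poisson with mean ``admissions_mean_per_year`` per year,
    aggregated over ``years`` years and reported as a per-year rate.
    """

    n_demand: int
    n_units: int
    n_csc: int
    region_size_km: float = 600.0
    speed_kmh: float = 60.0
    admissions_mean_per_year: float = DEFAULT_ADMISSIONS_MEAN
    years: int = 3
    seed: int = 0
    n_clusters: int = 8
    urban_fraction: float = 0.7
    cluster_sd_km: float = 20.0

    def __post_init__(self) -> None:
        if self.n_demand < 1 or self.n_units < 1:
            raise GeographyError("n_demand and n_units must be positive")
        if not (1 <= self.n_csc <= self.n_units):
            raise GeographyError(
                f"n_csc must be in [1, n_units]; got n_csc={self.n_csc}, n_units={self.n_units}"
            )
        if self.region_size_km <= 0 or self.speed_kmh <= 0:
            raise GeographyError("region_size_km and speed_kmh must be positive")
        if self.admissions_mean_per_year <= 0 or self.years < 1:
            raise GeographyError("admissions mean and years must be positive")


def _travel_minutes(a: np.ndarray, b: np.ndarray, speed_kmh: float) -> np.ndarray:
    d_km = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    return d_km / speed_kmh * 60.0


def generate_geography(params: SyntheticGeographyParams) -> Geography:
    """Generate a reproducible synthetic geography from ``params``."""
    rng = np.random.default_rng(params.seed)
    L = params.region_size_km

    # demand locations: urban clusters + uniform background
    centres = rng.uniform(0, L, size=(params.n_clusters, 2))
    n_urban = int(round(params.urban_fraction * params.n_demand))
    which = rng.integers(0, params.n_clusters, size=n_urban)
    urban = centres[which] + rng.normal(0, params.cluster_sd_km, size=(n_urban, 2))
    rural = rng.uniform(0, L, size=(params.n_demand - n_urban, 2))
    demand_xy = np.clip(np.vstack([urban, rural]), 0, L)
    demand_xy = demand_xy[rng.permutation(params.n_demand)]

    # stroke units sit where people are: at jittered demand locations
    host = rng.choice(params.n_demand, size=params.n_units, replace=False)
    unit_xy = np.clip(demand_xy[host] + rng.normal(0, 2.0, size=(params.n_units, 2)), 0, L)

    # CSCs biased toward high local demand density
    radius = max(L / 10.0, 1.0)
    d_unit_demand = np.hypot(
        unit_xy[:, None, 0] - demand_xy[None, :, 0],
        unit_xy[:, None, 1] - demand_xy[None, :, 1],
    )
    density = (d_unit_demand < radius).sum(axis=1).astype(float) + 1.0
    p = density / density.sum()
    csc_idx = set(rng.choice(params.n_units, size=params.n_csc, replace=False, p=p))

    width = len(str(max(params.n_demand, params.n_units)))
    demand_ids = [f"D{i:0{width}d}" for i in range(params.n_demand)]
    unit_ids = [f"U{i:0{width}d}" for i in range(params.n_units)]

    counts = rng.poisson(params.admissions_mean_per_year * params.years, size=params.n_demand)
    demand_units = [
        DemandUnit(demand_id=did, admissions_per_year=c / params.years)
        for did, c in zip(demand_ids, counts)
    ]
    stroke_units = [
        StrokeUnit(
            unit_id=uid,
            unit_type=UnitType.CSC if i in csc_idx else UnitType.PSC,
            msu_base=i in csc_idx,
        )
        for i, uid in enumerate(unit_ids)
    ]

    d2u = pd.DataFrame(
        _travel_minutes(demand_xy, unit_xy, params.speed_kmh),
        index=demand_ids,
        columns=unit_ids,
    )
    u2u_vals = _travel_minutes(unit_xy, unit_xy, params.speed_kmh)
    u2u_vals = (u2u_vals + u2u_vals.T) / 2.0  # exact symmetry despite fp rounding
    np.fill_diagonal(u2u_vals, 0.0)
    u2u = pd.DataFrame(u2u_vals, index=unit_ids, columns=unit_ids)

    return Geography(demand_units, stroke_units, TravelMatrix(d2u, u2u))


def england_like_preset(seed: int = 0, n_demand: int = 2000) -> Geography:
    """A scaled-down England-like default geography.

    2,000 demand units stand in for the 32,843 national areas; the hospital
    network keeps the real counts (101 stroke units, 23 of them CSCs) in a
    ~600 km region, so catchment structure — not national admission volume —
    is preserved.
    """
    params = SyntheticGeographyParams(
        n_demand=n_demand,
        n_units=101,
        n_csc=23,
        region_size_km=600.0,
        speed_kmh=60.0,
        seed=seed,
    )
    return generate_geography(params)
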
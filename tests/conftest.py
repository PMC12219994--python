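import numpy as np
import pandas as pd
import pytest

from msusim import (
    DemandUnit,
    Geography,
    StrokeUnit,
    TravelMatrix,
    UnitType,
    load_outcome_library,
)


def make_geography(demand_times, unit_types, unit_to_unit=None, admissions=None, msu_bases=None):
    """Build a small geography from explicit travel times.

    demand_times: {demand_id: {unit_id: minutes}}
    unit_types: {unit_id: "PSC"|"CSC"}
    unit_to_unit: {(a, b): minutes} (symmetrised; zero diagonal implied)
    """
    unit_ids = sorted(unit_types)
    demand_ids = sorted(demand_times)
    if msu_bases is None:
        msu_bases = {u for u, t in unit_types.items() if t == "CSC"}
    units = [
        StrokeUnit(unit_id=u, unit_type=UnitType(unit_types[u]), msu_base=u in msu_bases)
        for u in unit_ids
    ]
    demands = [
        DemandUnit(demand_id=d, admissions_per_year=(admissions or {}).get(d, 1.0))
        for d in demand_ids
    ]
    d2u = pd.DataFrame(
        [[float(demand_times[d][u]) for u in unit_ids] for d in demand_ids],
        index=demand_ids,
        columns=unit_ids,
    )
    uu = np.zeros((len(unit_ids), len(unit_ids)))
    for (a, b), t in (unit_to_unit or {}).items():
        i, j = unit_ids.index(a), unit_ids.index(b)
        uu[i, j] = uu[j, i] = float(t)
    u2u = pd.DataFrame(uu, index=unit_ids, columns=unit_ids)
    return Geography(demands, units, TravelMatrix(d2u, u2u))


def random_geography(rng, n_demand=10, n_units=8, n_csc=3, scale=60.0):
    """Random metric geography from points in the plane."""
    pts_d = rng.uniform(0, scale, size=(n_demand, 2))
    pts_u = rng.uniform(0, scale, size=(n_units, 2))
    unit_ids = [f"U{i}" for i in range(n_units)]
    demand_ids = [f"D{i}" for i in range(n_demand)]
    csc = set(rng.choice(n_units, size=n_csc, replace=False))
    unit_types = {u: ("CSC" if i in csc else "PSC") for i, u in enumerate(unit_ids)}
    demand_times = {
        d: {u: float(np.hypot(*(pts_d[i] - pts_u[j]))) for j, u in enumerate(unit_ids)}
        for i, d in enumerate(demand_ids)
    }
    unit_to_unit = {
        (unit_ids[i], unit_ids[j]): float(np.hypot(*(pts_u[i] - pts_u[j])))
        for i in range(n_units)
        for j in range(i + 1, n_units)
    }
    admissions = {d: float(rng.poisson(2.47) + 0.1) for d in demand_ids}
    return make_geography(demand_times, unit_types, unit_to_unit, admissions)


@pytest.fixture(scope="session")
def lib():
    return load_outcome_library()


@pytest.fixture
def toy_geography():
    """One demand unit, a PSC 10 min away and CSCs at 25 and 40 min;
    PSC -> nearest CSC inter-hospital time 20 min."""
    return make_geography(
        demand_times={"d1": {"P1": 10.0, "C1": 25.0, "C2": 40.0}},
        unit_types={"P1": "PSC", "C1": "CSC", "C2": "CSC"},
        unit_to_unit={("P1", "C1"): 20.0, ("P1", "C2"): 35.0, ("C1", "C2"): 30.0},
    )
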
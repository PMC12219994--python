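"""Spatial substrate of the model: demand units, stroke units and travel times.

A *demand unit* is a small census area (in England, an LSOA of roughly 1,500
residents) with an annual count of stroke admissions.  A *stroke unit* is
either a primary stroke centre (PSC, thrombolysis only) or a comprehensive
stroke centre (CSC, thrombolysis and thrombectomy).  Routing uses only the
two travel-time matrices, so the model is geometry-free: coordinates, when
present, are metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-6


class GeographyError(ValueError):
    """Raised for invalid geography data or infeasible routing requests."""


class UnitType(str, Enum):
    PSC = "PSC"
    CSC = "CSC"


@dataclass(frozen=True)
class StrokeUnit:
    """An acute stroke unit.

    CSCs provide both IVT and MT; PSCs provide IVT only, so MT patients
    admitted to a PSC need an inter-hospital transfer.  ``msu_base`` marks
    the unit as a default mobile-stroke-unit base (conventionally the CSCs).
    """

    unit_id: str
    unit_type: UnitType
    msu_base: bool = False

    @property
    def is_csc(self) -> bool:
        return self.unit_type is UnitType.CSC


@dataclass(frozen=True)
class DemandUnit:
    demand_id: str
    admissions_per_year: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.admissions_per_year) or self.admissions_per_year < 0:
            raise GeographyError(
                f"demand unit {self.demand_id!r}: admissions_per_year must be "
                f"finite and >= 0, got {self.admissions_per_year}"
            )


@dataclass(frozen=True)
class UsualRoute:
    """Destination(s) under usual care: nearest unit, plus an onward
    transfer to the CSC nearest to that unit when the first unit is a PSC."""

    first_unit: str
    travel_to_first: float
    needs_transfer: bool
    transfer_unit: Optional[str] = None
    inter_hospital: Optional[float] = None


@dataclass(frozen=True)
class MsuRoute:
    """MSU dispatch legs: base → scene (outbound) and scene → nearest CSC
    (return leg, taken after on-scene IVT for patients needing MT)."""

    base_unit: str
    outbound: float
    destination_csc: str
    return_leg: float


class TravelMatrix:
    """Demand→unit and unit→unit travel times in minutes.

    Entries must be finite and nonnegative; the unit→unit matrix must have a
    zero diagonal and be symmetric within ``SYMMETRY_TOL`` (asymmetry beyond
    tolerance is tolerated with a warning, since published matrices may be
    direction-averaged).
    """

    def __init__(
        self,
        demand_to_unit: pd.DataFrame,
        unit_to_unit: pd.DataFrame,
        *,
        strict_symmetry: bool = False,
    ) -> None:
        self.demand_to_unit = demand_to_unit.astype(float)
        self.unit_to_unit = unit_to_unit.astype(float)
        self._validate(strict_symmetry)

    def _validate(self, strict_symmetry: bool) -> None:
        for name, df in (
            ("demand_to_unit", self.demand_to_unit),
            ("unit_to_unit", self.unit_to_unit),
        ):
            vals = df.to_numpy()
            if not np.all(np.isfinite(vals)):
                raise GeographyError(f"{name}: travel times must be finite")
            if (vals < 0).any():
                i, j = np.argwhere(vals < 0)[0]
                raise GeographyError(
                    f"{name}: negative travel time at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                )
        uu = self.unit_to_unit
        if list(uu.index) != list(uu.columns):
            raise GeographyError("unit_to_unit: row and column unit ids differ")
        diag = np.diag(uu.to_numpy())
        if np.abs(diag).max(initial=0.0) > SYMMETRY_TOL:
            raise GeographyError("unit_to_unit: diagonal must be zero")
        asym = np.abs(uu.to_numpy() - uu.to_numpy().T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            msg = f"unit_to_unit matrix asymmetric (max |t_ij - t_ji| = {asym:.3g} min)"
            if strict_symmetry:
                raise GeographyError(msg)
            logger.warning("%s; continuing (direction-averaged matrices are common)", msg)


class Geography:
    """Demand units, stroke units and travel matrices, cross-validated.

    At least one CSC must exist (otherwise no patient can ever receive MT
    and the usual-care transfer rule is undefined).
    """

    def __init__(
        self,
        demand_units: Sequence[DemandUnit],
        stroke_units: Sequence[StrokeUnit],
        travel: TravelMatrix,
    ) -> None:
        self.demand_units = list(demand_units)
        self.stroke_units = list(stroke_units)
        self.travel = travel

        self.demand_ids = [d.demand_id for d in self.demand_units]
        self.unit_ids = [u.unit_id for u in self.stroke_units]
        if len(set(self.demand_ids)) != len(self.demand_ids):
            raise GeographyError("duplicate demand_id")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise GeographyError("duplicate unit_id")
        self._units_by_id = {u.unit_id: u for u in self.stroke_units}

        if not any(u.is_csc for u in self.stroke_units):
            raise GeographyError("geography must contain at least one CSC")

        if list(travel.demand_to_unit.index) != self.demand_ids:
            raise GeographyError("demand_to_unit rows do not match demand units")
        for name, cols in (
            ("demand_to_unit", travel.demand_to_unit.columns),
            ("unit_to_unit", travel.unit_to_unit.columns),
        ):
            if list(cols) != self.unit_ids:
                raise GeographyError(f"{name} columns do not match stroke units")

    # -- basic accessors -------------------------------------------------
    def unit(self, unit_id: str) -> StrokeUnit:
        return self._units_by_id[unit_id]

    @property
    def csc_ids(self) -> list[str]:
        return [u.unit_id for u in self.stroke_units if u.is_csc]

    @property
    def default_msu_bases(self) -> set[str]:
        bases = {u.unit_id for u in self.stroke_units if u.msu_base}
        return bases

    @property
    def admissions(self) -> pd.Series:
        return pd.Series(
            [d.admissions_per_year for d in self.demand_units],
            index=self.demand_ids,
            name="admissions_per_year",
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_csc = len(self.csc_ids)
        return (
            f"Geography({len(self.demand_units)} demand units, "
            f"{len(self.stroke_units)} stroke units [{n_csc} CSC])"
        )


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

def _argmin_with_id_tiebreak(times: pd.Series) -> tuple[str, float]:
    """Minimum travel time; ties broken by lexicographically smallest id."""
    t_min = times.min()
    winners = sorted(times.index[times == t_min])
    return winners[0], float(t_min)


def nearest_unit(
    demand_id: str,
    geography: Geography,
    unit_filter: Optional[Callable[[StrokeUnit], bool]] = None,
) -> tuple[str, float]:
    """Nearest stroke unit to a demand unit, optionally filtered.

    Ties in travel time are broken by the lexicographically smallest
    unit_id so routing is deterministic.
    """
    row = geography.travel.demand_to_unit.loc[demand_id]
    if unit_filter is not None:
        keep = [u.unit_id for u in geography.stroke_units if unit_filter(u)]
        if not keep:
            raise GeographyError(f"no eligible unit for demand {demand_id!r}")
        row = row[keep]
    return _argmin_with_id_tiebreak(row)


def nearest_csc_to_unit(unit_id: str, geography: Geography) -> tuple[str, float]:
    """CSC nearest to a given stroke unit (inter-hospital matrix)."""
    row = geography.travel.unit_to_unit.loc[unit_id, geography.csc_ids]
    return _argmin_with_id_tiebreak(row)


def usual_care_route(demand_id: str, geography: Geography) -> UsualRoute:
    """Usual-care destination: nearest unit of any type; PSC admissions get
    an onward transfer to the CSC nearest to that PSC."""
    first, t_first = nearest_unit(demand_id, geography)
    if geography.unit(first).is_csc:
        return UsualRoute(first_unit=first, travel_to_first=t_first, needs_transfer=False)
    transfer, t_transfer = nearest_csc_to_unit(first, geography)
    return UsualRoute(
        first_unit=first,
        travel_to_first=t_first,
        needs_transfer=True,
        transfer_unit=transfer,
        inter_hospital=t_transfer,
    )


def msu_route(
    demand_id: str, geography: Geography, active_bases: Iterable[str]
) -> MsuRoute:
    """MSU dispatch: outbound from the closest active base; after on-scene
    IVT, MT patients travel from the scene to the demand unit's nearest CSC
    (which need not be the base)."""
    bases = sorted(set(active_bases))
    if not bases:
        raise GeographyError("no MSU base: active_bases is empty")
    for b in bases:
        if b not in geography._units_by_id:
            raise GeographyError(f"unknown MSU base {b!r}")
    row = geography.travel.demand_to_unit.loc[demand_id, bases]
    base, outbound = _argmin_with_id_tiebreak(row)
    dest, return_leg = nearest_unit(demand_id, geography, lambda u: u.is_csc)
    return MsuRoute(base_unit=base, outbound=outbound, destination_csc=dest, return_leg=return_leg)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_csv(path: Path, what: str, index_col: Optional[int] = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise GeographyError(f"{what} file not found: {path}")
    try:
        return pd.read_csv(path, index_col=index_col)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise GeographyError(f"failed to parse {what} file {path}: {exc}") from exc


def load_geography(
    demand_csv: Path | str,
    units_csv: Path | str,
    demand_travel_csv: Path | str,
    unit_travel_csv: Path | str,
) -> Geography:
    """Load a geography from four CSV files.

    ``demand_csv``: demand_id, admissions_per_year.
    ``units_csv``: unit_id, unit_type (PSC|CSC), msu_base (0|1).
    Travel CSVs: first column demand_id (or unit_id), one column per
    unit_id, values in minutes.
    """
    demand_df = _read_csv(Path(demand_csv), "demand")
    units_df = _read_csv(Path(units_csv), "units")

    for col in ("demand_id", "admissions_per_year"):
        if col not in demand_df.columns:
            raise GeographyError(f"demand file {demand_csv}: missing column {col!r}")
    for col in ("unit_id", "unit_type", "msu_base"):
        if col not in units_df.columns:
            raise GeographyError(f"units file {units_csv}: missing column {col!r}")

    demand_units = []
    for i, rec in enumerate(demand_df.itertuples(index=False)):
        try:
            demand_units.append(
                DemandUnit(demand_id=str(rec.demand_id), admissions_per_year=float(rec.admissions_per_year))
            )
        except (GeographyError, ValueError) as exc:
            raise GeographyError(f"demand file {demand_csv}, row {i + 2}: {exc}") from exc

    stroke_units = []
    for i, rec in enumerate(units_df.itertuples(index=False)):
        try:
            utype = UnitType(str(rec.unit_type))
        except ValueError as exc:
            raise GeographyError(
                f"units file {units_csv}, row {i + 2}: unknown unit type {rec.unit_type!r}"
            ) from exc
        stroke_units.append(
            StrokeUnit(unit_id=str(rec.unit_id), unit_type=utype, msu_base=bool(int(rec.msu_base)))
        )

    d2u = _read_csv(Path(demand_travel_csv), "demand travel matrix", index_col=0)
    u2u = _read_csv(Path(unit_travel_csv), "unit travel matrix", index_col=0)
    d2u.index = d2u.index.astype(str)
    u2u.index = u2u.index.astype(str)
    d2u.columns = d2u.columns.astype(str)
    u2u.columns = u2u.columns.astype(str)

    try:
        travel = TravelMatrix(d2u, u2u)
        return Geography(demand_units, stroke_units, travel)
    except GeographyError as exc:
        raise GeographyError(
            f"invalid geography (files {demand_travel_csv}, {unit_travel_csv}): {exc}"
        ) from exc


def save_geography(geography: Geography, out_dir: Path | str) -> dict[str, Path]:
    """Write the four-CSV representation read by :func:`load_geography`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "demand": out / "demand.csv",
        "units": out / "units.csv",
        "demand_travel": out / "travel_demand_to_unit.csv",
        "unit_travel": out / "travel_unit_to_unit.csv",
    }
    pd.DataFrame(
        {
            "demand_id": geography.demand_ids,
            "admissions_per_year": [d.admissions_per_year for d in geography.demand_units],
        }
    ).to_csv(paths["demand"], index=False)
    pd.DataFrame(
        {
            "unit_id": geography.unit_ids,
            "unit_type": [u.unit_type.value for u in geography.stroke_units],
            "msu_base": [int(u.msu_base) for u in geography.stroke_units],
        }
    ).to_csv(paths["units"], index=False)
    geography.travel.demand_to_unit.rename_axis("demand_id").to_csv(paths["demand_travel"])
    geography.travel.unit_to_unit.rename_axis("unit_id").to_csv(paths["unit_travel"])
    return paths
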
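"""Pathway time composition for usual care and MSU care.

Onset→IVT and onset→MT times are sums of scenario-defined process durations
(common to all patients) and travel legs (specific to each demand unit and
care model).  Three timelines exist: usual care via a PSC with an onward
transfer for MT, usual care direct to a CSC, and MSU care with on-scene IVT
followed by conveyance to the nearest CSC for MT.

The transfer-related net MT delay is a single bundled parameter: door-in/
door-out time at the first hospital minus the door-to-puncture saving that
transferred patients enjoy at the CSC.  It is added once, between arrival
at the PSC and the inter-hospital leg, leaving door-to-puncture unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Optional

from .geography import MsuRoute, UsualRoute


class PathwayError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioTimes:
    """The ten non-travel process durations (minutes) defining one scenario."""

    onset_to_call: float
    call_to_ambulance: float
    ambulance_on_scene: float
    door_to_needle: float
    transfer_net_delay: float
    door_to_puncture_usual: float
    call_to_msu_dispatch: float
    msu_arrival_to_ivt: float
    msu_on_scene_post_ivt: float
    door_to_puncture_msu: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0 and v < float("inf")):
                raise PathwayError(f"scenario field {f.name} must be finite and >= 0, got {v}")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


#: Base-case process durations used for the geographic analysis.
BASE_CASE = ScenarioTimes(
    onset_to_call=60,
    call_to_ambulance=20,
    ambulance_on_scene=30,
    door_to_needle=45,
    transfer_net_delay=60,
    door_to_puncture_usual=90,
    call_to_msu_dispatch=15,
    msu_arrival_to_ivt=30,
    msu_on_scene_post_ivt=5,
    door_to_puncture_msu=60,
)


@dataclass(frozen=True)
class TreatmentWindows:
    """Maximum onset-to-treatment times: 4.5 h for IVT, 8 h for MT.

    Comparisons are inclusive (a time exactly at the window is treatable).
    """

    ivt_max: float = 270.0
    mt_max: float = 480.0

    def __post_init__(self) -> None:
        if self.ivt_max <= 0 or self.mt_max <= 0:
            raise PathwayError("treatment windows must be positive")


@dataclass(frozen=True)
class TreatmentTimes:
    care_model: str  # "usual" | "msu"
    t_ivt: Optional[float]
    t_mt: Optional[float]
    ivt_eligible: bool = False
    mt_eligible: bool = False
    transfer_used: bool = False


def times_usual_care(route: UsualRoute, s: ScenarioTimes) -> TreatmentTimes:
    """Compose usual-care onset→IVT and onset→MT times for one demand unit.

    IVT is given at the first hospital; MT at the first hospital if it is a
    CSC, otherwise after the transfer delay plus the inter-hospital leg.
    Eligibility flags are left unset; apply :func:`apply_windows`.
    """
    prehospital = s.onset_to_call + s.call_to_ambulance + s.ambulance_on_scene
    t_ivt = prehospital + route.travel_to_first + s.door_to_needle
    if route.needs_transfer:
        if route.inter_hospital is None:
            raise PathwayError("transfer route lacks inter_hospital time")
        t_mt = (
            prehospital
            + route.travel_to_first
            + s.transfer_net_delay
            + route.inter_hospital
            + s.door_to_puncture_usual
        )
    else:
        t_mt = prehospital + route.travel_to_first + s.door_to_puncture_usual
    return TreatmentTimes(
        care_model="usual", t_ivt=t_ivt, t_mt=t_mt, transfer_used=route.needs_transfer
    )


def times_msu_care(route: MsuRoute, s: ScenarioTimes) -> TreatmentTimes:
    """Compose MSU-care times: on-scene IVT, then conveyance to the nearest
    CSC for MT."""
    t_ivt = s.onset_to_call + s.call_to_msu_dispatch + route.outbound + s.msu_arrival_to_ivt
    t_mt = t_ivt + s.msu_on_scene_post_ivt + route.return_leg + s.door_to_puncture_msu
    return TreatmentTimes(care_model="msu", t_ivt=t_ivt, t_mt=t_mt, transfer_used=False)


def apply_windows(t: TreatmentTimes, w: TreatmentWindows = TreatmentWindows()) -> TreatmentTimes:
    """Set eligibility flags from the treatment windows (inclusive).

    Times are retained for reporting even when a treatment is out of window.
    """
    return replace(
        t,
        ivt_eligible=t.t_ivt is not None and t.t_ivt <= w.ivt_max,
        mt_eligible=t.t_mt is not None and t.t_mt <= w.mt_max,
    )
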
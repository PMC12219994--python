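"""Greedy selection of MSU base locations.

Bases are added one at a time, each chosen to maximise the mean utility
gain of MSU care over usual care among treated patients (admission-weighted
by default).  Because each patient is served by their minimum-outbound
active base, adding a base can never worsen any patient's MSU time, so the
objective is nondecreasing in the selected set; increments typically shrink
(diminishing returns).  An exhaustive enumerator over small candidate sets
serves as an independent optimality reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np

from .geography import Geography
from .outcomes import OutcomeLibrary
from .pathway import BASE_CASE, ScenarioTimes, TreatmentWindows
from .scenarios import RoutingTables, ScenarioError, evaluate_scenario, national_average


class SitingError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionTrace:
    """Greedy selection order and the objective after each addition."""

    selected: tuple[str, ...]
    gain_after_k: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.selected)


def objective_gain(
    geography: Geography | RoutingTables,
    bases: Iterable[str],
    scenario: ScenarioTimes = BASE_CASE,
    lib: Optional[OutcomeLibrary] = None,
    windows: TreatmentWindows = TreatmentWindows(),
    weighting: str = "admission_weighted",
) -> float:
    """Mean mixed-cohort utility gain of MSU care over usual care."""
    bases = set(bases)
    if not bases:
        raise SitingError("objective requires a nonempty base set")
    if lib is None:
        from .outcomes import load_outcome_library

        lib = load_outcome_library()
    rt = geography if isinstance(geography, RoutingTables) else RoutingTables(geography, bases)
    if rt.active_bases != frozenset(bases):
        rt = rt.with_bases(bases)
    rows = evaluate_scenario(rt, scenario, lib, windows)
    return float(national_average(rows, weighting=weighting)["mixed_delta_utility"])


def greedy_select(
    geography: Geography,
    candidates: Sequence[str],
    k_max: int,
    scenario: ScenarioTimes = BASE_CASE,
    lib: Optional[OutcomeLibrary] = None,
    windows: TreatmentWindows = TreatmentWindows(),
    weighting: str = "admission_weighted",
) -> SelectionTrace:
    """Sequentially add the candidate maximising the objective.

    Ties are broken by the lexicographically smallest unit_id, making the
    trace deterministic.
    """
    candidates = sorted(set(candidates))
    if k_max > len(candidates):
        raise SitingError(f"k_max={k_max} exceeds {len(candidates)} candidates")
    if k_max < 0:
        raise SitingError("k_max must be >= 0")
    if lib is None:
        from .outcomes import load_outcome_library

        lib = load_outcome_library()
    if not candidates or k_max == 0:
        return SelectionTrace(selected=(), gain_after_k=())

    rt0 = RoutingTables(geography, {candidates[0]})  # template; outbound recomputed per set
    selected: list[str] = []
    gains: list[float] = []
    remaining = list(candidates)
    while len(selected) < k_max:
        best_gain, best_cand = None, None
        for c in remaining:  # candidates pre-sorted, so first max wins ties
            g = objective_gain(
                rt0.with_bases(selected + [c]), selected + [c], scenario, lib, windows, weighting
            )
            if best_gain is None or g > best_gain:
                best_gain, best_cand = g, c
        selected.append(best_cand)
        gains.append(best_gain)
        remaining.remove(best_cand)
    return SelectionTrace(selected=tuple(selected), gain_after_k=tuple(gains))


def exhaustive_select(
    geography: Geography,
    candidates: Sequence[str],
    k: int,
    scenario: ScenarioTimes = BASE_CASE,
    lib: Optional[OutcomeLibrary] = None,
    windows: TreatmentWindows = TreatmentWindows(),
    weighting: str = "admission_weighted",
    max_subsets: int = 10_000,
) -> tuple[tuple[str, ...], float]:
    """Globally optimal size-``k`` base set by enumeration (test oracle).

    Refuses instances with more than ``max_subsets`` subsets.
    """
    candidates = sorted(set(candidates))
    if not (1 <= k <= len(candidates)):
        raise SitingError(f"k must be in [1, {len(candidates)}], got {k}")
    n_subsets = comb(len(candidates), k)
    if n_subsets > max_subsets:
        raise SitingError(
            f"refusing exhaustive search over {n_subsets} subsets (> {max_subsets})"
        )
    if lib is None:
        from .outcomes import load_outcome_library

        lib = load_outcome_library()
    rt0 = RoutingTables(geography, {candidates[0]})
    best: tuple[Optional[tuple[str, ...]], Optional[float]] = (None, None)
    for subset in itertools.combinations(candidates, k):  # lexicographic order
        g = objective_gain(rt0.with_bases(subset), subset, scenario, lib, windows, weighting)
        if best[1] is None or g > best[1]:
            best = (subset, g)
    return best  # type: ignore[return-value]


def restricted_run(
    geography: Geography,
    restriction: str,
    k_max: Optional[int] = None,
    scenario: ScenarioTimes = BASE_CASE,
    lib: Optional[OutcomeLibrary] = None,
    windows: TreatmentWindows = TreatmentWindows(),
    weighting: str = "admission_weighted",
) -> SelectionTrace:
    """Greedy run with candidates restricted to CSCs or open to any unit."""
    if restriction == "csc_only":
        candidates = geography.csc_ids
    elif restriction == "any_unit":
        candidates = geography.unit_ids
    else:
        raise SitingError(f"unknown restriction {restriction!r}; use csc_only or any_unit")
    if not candidates:
        raise SitingError("restriction yields no candidates")
    if k_max is None:
        k_max = len(candidates)
    return greedy_select(geography, candidates, k_max, scenario, lib, windows, weighting)
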
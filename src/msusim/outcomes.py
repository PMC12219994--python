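"""Time-dependent mRS outcome model.

Treatment effectiveness decays with onset-to-treatment time.  For each
patient-treatment cohort (nLVO treated with IVT, LVO with IVT, LVO with MT)
the model holds a reference mRS distribution for treatment at onset (t = 0)
and one at the time of no effect (6.3 h for IVT, 8.0 h for MT).  The
distribution at an intermediate time is obtained by interpolating each
cumulative probability P(mRS <= k) linearly *in log-odds* between the two
endpoints:

    logit c_k(t) = (1 - t/T) * logit c_k(0) + (t/T) * logit c_k(T)

for thresholds k = 0..5 (c_6 = 1 always), with t clamped to [0, T].
Patients outside every treatment window receive the untreated distribution.

Outcome summaries are mean health utility (mRS-level weights from published
EQ-5D valuations; death carries the table value, here 0) and the
independent-living proportion P(mRS 0-2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .pathway import TreatmentTimes

_EPS = 1e-10  # cumulative clipping bound before logit
_SUM_TOL = 1e-9

N_MRS = 7  # mRS 0..6


class OutcomeModelError(ValueError):
    pass


def _as_probs(p, what: str = "distribution") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (N_MRS,):
        raise OutcomeModelError(f"{what}: expected {N_MRS} probabilities, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or (arr < 0).any():
        raise OutcomeModelError(f"{what}: probabilities must be finite and >= 0")
    if abs(arr.sum() - 1.0) > _SUM_TOL:
        raise OutcomeModelError(f"{what}: probabilities sum to {arr.sum():.12f}, not 1")
    return arr


@dataclass(frozen=True)
class MrsDistribution:
    """A probability distribution over mRS 0-6."""

    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", _as_probs(self.p))

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.p)

    def utility(self, weights: np.ndarray) -> float:
        return float(self.p @ np.asarray(weights, dtype=float))

    @property
    def p_independent(self) -> float:
        """P(mRS 0-2), the independent-living surrogate."""
        return float(self.p[:3].sum())


@dataclass(frozen=True)
class CohortReference:
    """Endpoint distributions and no-effect time for one cohort-treatment."""

    dist_t0: MrsDistribution
    dist_no_effect: MrsDistribution
    t_no_effect: float

    def __post_init__(self) -> None:
        if self.t_no_effect <= 0:
            raise OutcomeModelError(f"t_no_effect must be > 0, got {self.t_no_effect}")


CombinationRule = Literal["best_of", "mt_dominates"]


@dataclass(frozen=True)
class OutcomeLibrary:
    """Reference distributions, utility weights and cohort mix."""

    refs: dict[str, CohortReference]  # keys: nLVO_IVT, LVO_IVT, LVO_MT
    untreated: dict[str, MrsDistribution]  # keys: nLVO, LVO
    utility_weights: np.ndarray
    p_nlvo: float = 0.70
    p_lvo: float = 0.30
    combination_rule: CombinationRule = "best_of"

    def __post_init__(self) -> None:
        missing = {"nLVO_IVT", "LVO_IVT", "LVO_MT"} - set(self.refs)
        if missing:
            raise OutcomeModelError(f"outcome library missing cohorts: {sorted(missing)}")
        if {"nLVO", "LVO"} - set(self.untreated):
            raise OutcomeModelError("outcome library missing untreated distributions")
        w = np.asarray(self.utility_weights, dtype=float)
        if w.shape != (N_MRS,) or not np.all(np.isfinite(w)):
            raise OutcomeModelError("utility_weights must be 7 finite values")
        object.__setattr__(self, "utility_weights", w)
        if abs(self.p_nlvo + self.p_lvo - 1.0) > _SUM_TOL:
            raise OutcomeModelError(
                f"cohort mix must sum to 1: p_nLVO={self.p_nlvo}, p_LVO={self.p_lvo}"
            )
        if self.combination_rule not in ("best_of", "mt_dominates"):
            raise OutcomeModelError(f"unknown combination rule {self.combination_rule!r}")


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def _logit(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, _EPS, 1.0 - _EPS)
    return np.log(c / (1.0 - c))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def interpolate_cumulative(ref: CohortReference, t: np.ndarray) -> np.ndarray:
    """Cumulative mRS probabilities at times ``t`` (vectorised).

    Returns shape ``(len(t), 7)``; the last threshold is pinned to 1.
    Times are clamped to [0, t_no_effect].
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    frac = np.clip(t / ref.t_no_effect, 0.0, 1.0)[:, None]
    l0 = _logit(ref.dist_t0.cumulative[:6])[None, :]
    l1 = _logit(ref.dist_no_effect.cumulative[:6])[None, :]
    cum = np.empty((t.shape[0], N_MRS))
    cum[:, :6] = _inv_logit((1.0 - frac) * l0 + frac * l1)
    # exact endpoint recovery (clipped logits would otherwise leave ~1e-10 residue)
    at0 = frac[:, 0] == 0.0
    at1 = frac[:, 0] == 1.0
    cum[at0, :6] = ref.dist_t0.cumulative[:6]
    cum[at1, :6] = ref.dist_no_effect.cumulative[:6]
    cum[:, 6] = 1.0
    return cum


def interpolate_distribution(ref: CohortReference, t: float) -> MrsDistribution:
    """mRS distribution for treatment at time ``t`` minutes after onset."""
    if t < 0:
        raise OutcomeModelError(f"treatment time must be >= 0, got {t}")
    if t == 0.0:
        return ref.dist_t0
    if t >= ref.t_no_effect:
        return ref.dist_no_effect
    cum = interpolate_cumulative(ref, np.array([t]))[0]
    return MrsDistribution(np.diff(cum, prepend=0.0))


# ---------------------------------------------------------------------------
# Cohort outcomes
# ---------------------------------------------------------------------------

def outcome_nlvo(t: TreatmentTimes, lib: OutcomeLibrary) -> MrsDistribution:
    """nLVO outcome: IVT at t_ivt if in window, else untreated."""
    if t.ivt_eligible and t.t_ivt is not None:
        return interpolate_distribution(lib.refs["nLVO_IVT"], t.t_ivt)
    return lib.untreated["nLVO"]


def outcome_lvo(t: TreatmentTimes, lib: OutcomeLibrary) -> MrsDistribution:
    """LVO outcome under the configured IVT/MT combination rule.

    If both treatments are in window, ``best_of`` picks whichever of the
    interpolated IVT and MT distributions has the higher utility;
    ``mt_dominates`` always takes the MT distribution.
    """
    ivt_ok = t.ivt_eligible and t.t_ivt is not None
    mt_ok = t.mt_eligible and t.t_mt is not None
    if not ivt_ok and not mt_ok:
        return lib.untreated["LVO"]
    if ivt_ok and not mt_ok:
        return interpolate_distribution(lib.refs["LVO_IVT"], t.t_ivt)
    if mt_ok and not ivt_ok:
        return interpolate_distribution(lib.refs["LVO_MT"], t.t_mt)
    d_mt = interpolate_distribution(lib.refs["LVO_MT"], t.t_mt)
    if lib.combination_rule == "mt_dominates":
        return d_mt
    d_ivt = interpolate_distribution(lib.refs["LVO_IVT"], t.t_ivt)
    w = lib.utility_weights
    return d_ivt if d_ivt.utility(w) > d_mt.utility(w) else d_mt


def utility(dist: MrsDistribution, weights) -> float:
    """Mean health utility of a distribution: sum_k p_k * w_k."""
    return dist.utility(np.asarray(weights, dtype=float))


def p_independent(dist: MrsDistribution) -> float:
    """Independent-living proportion P(mRS 0-2)."""
    return dist.p_independent


def mix_cohorts(
    d_nlvo: MrsDistribution, d_lvo: MrsDistribution, mix: tuple[float, float] = (0.7, 0.3)
) -> MrsDistribution:
    """Mixture distribution for the combined treated population."""
    a, b = mix
    if abs(a + b - 1.0) > _SUM_TOL:
        raise OutcomeModelError(f"cohort mix must sum to 1, got {mix}")
    return MrsDistribution(a * d_nlvo.p + b * d_lvo.p)


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

def _library_from_dict(raw: dict) -> OutcomeLibrary:
    refs = {}
    for name, block in raw["cohorts"].items():
        try:
            refs[name] = CohortReference(
                dist_t0=MrsDistribution(block["dist_t0"]),
                dist_no_effect=MrsDistribution(block["dist_no_effect"]),
                t_no_effect=float(block["t_no_effect_min"]),
            )
        except OutcomeModelError as exc:
            raise OutcomeModelError(f"cohort {name!r}: {exc}") from exc
    untreated = {}
    for name, p in raw["untreated"].items():
        try:
            untreated[name] = MrsDistribution(p)
        except OutcomeModelError as exc:
            raise OutcomeModelError(f"untreated cohort {name!r}: {exc}") from exc
    mix = raw.get("cohort_mix", {"p_nLVO": 0.7, "p_LVO": 0.3})
    return OutcomeLibrary(
        refs=refs,
        untreated=untreated,
        utility_weights=np.asarray(raw["utility_weights"], dtype=float),
        p_nlvo=float(mix["p_nLVO"]),
        p_lvo=float(mix["p_LVO"]),
        combination_rule=raw.get("combination_rule", "best_of"),
    )


def load_outcome_library(path: Optional[Path | str] = None) -> OutcomeLibrary:
    """Load an outcome library from JSON; the packaged default when ``path``
    is None."""
    if path is None:
        text = resources.files("msusim.data").joinpath("outcome_library.json").read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise OutcomeModelError(f"outcome library file not found: {p}")
        text = p.read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise OutcomeModelError(f"outcome library is not valid JSON: {exc}") from exc
    return _library_from_dict(raw)
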
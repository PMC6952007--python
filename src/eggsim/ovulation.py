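"""Ovulatory-cycle simulation: internal cycle length, lags, clutches and pauses.

A hen's internal ovulatory cycle is usually longer than the 24 h external
(light) cycle.  The excess — the *lag* between successive ovipositions —
accumulates across a laying sequence; when the cumulative lag would exceed a
threshold of about 8–9 h the hen takes a pause day and starts a new clutch.
The internal cycle length (ICL) starts well above 24 h at first egg, decays
towards (or below) 24 h around peak production, and rises again with
reproductive senescence; this single curve generates the characteristic
rise of clutch lengths to a long "prime" sequence near peak and their decline
thereafter.

Clock time of lay is anchored, for the first egg of a clutch, to the time the
photoperiod ended on the previous day (SD about 3 h); later eggs in the clutch
are laid progressively later by the cumulative lag (SD about 0.2 h per egg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .flock import HenParams

__all__ = [
    "ICLCurve",
    "SequenceState",
    "OvipositionRecord",
    "icl",
    "step_day",
    "oviposition_time",
    "classify_egg",
    "simulate_hen",
    "constant_lag_curve",
]

QUALITIES = ("normal", "soft_shell", "internal")


@dataclass(frozen=True)
class ICLCurve:
    """Internal-cycle-length curve: exponential decay plus linear senescence.

    icl(t) = baseline_h + (24 + initial_excess_h - baseline_h) * exp(-decay_rate * t)
             + senescence_slope_h_per_d * t

    with t in days since first egg, so icl(0) = 24 + initial_excess_h.
    ``baseline_h`` is the asymptotic minimum region the curve decays towards
    (it may sit below 24 h, in which case lags floor at zero and the hen can
    lay indefinitely long sequences until senescence raises the curve again).
    """

    baseline_h: float
    initial_excess_h: float
    decay_rate: float
    senescence_slope_h_per_d: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_excess_h <= 0:
            raise ValueError("initial_excess_h must be > 0")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be > 0")
        if self.senescence_slope_h_per_d < 0:
            raise ValueError("senescence_slope_h_per_d must be >= 0")
        if 24.0 + self.initial_excess_h < self.baseline_h:
            raise ValueError("baseline_h cannot exceed the value at first egg")


def constant_lag_curve(lag_h: float) -> ICLCurve:
    """An ICL curve with a constant lag (icl = 24 + lag for all t).

    Constructed by setting the first-egg value equal to the baseline so the
    decay term vanishes identically; handy for closed-form clutch oracles.
    """
    if lag_h <= 0:
        raise ValueError("lag_h must be > 0")
    return ICLCurve(
        baseline_h=24.0 + lag_h,
        initial_excess_h=lag_h,
        decay_rate=1.0,
        senescence_slope_h_per_d=0.0,
    )


def icl(t_d: float | np.ndarray, curve: ICLCurve) -> float | np.ndarray:
    """Internal cycle length (h) at ``t_d`` days since first egg."""
    t = np.asarray(t_d, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_d must be >= 0")
    out = (
        curve.baseline_h
        + (24.0 + curve.initial_excess_h - curve.baseline_h) * np.exp(-curve.decay_rate * t)
        + curve.senescence_slope_h_per_d * t
    )
    return float(out) if np.isscalar(t_d) else out


@dataclass
class SequenceState:
    """Mutable per-hen laying-sequence state."""

    cumulative_lag_h: float = 0.0
    eggs_in_current_clutch: int = 0
    days_since_first_egg: int = 0
    in_pause: bool = False


def step_day(
    state: SequenceState,
    curve: ICLCurve,
    lag_threshold_h: float,
    rng: np.random.Generator | None = None,
    lag_floor_h: float = 0.0,
    external_cycle_h: float = 24.0,
) -> tuple[SequenceState, bool, float]:
    """Advance one day; return (state, laid_today, lag_today_h).

    The day's lag is ``max(icl(t) - external_cycle, lag_floor)``.  The first
    egg of a clutch carries no lag (a lag is an interval *between*
    ovipositions).  A subsequent egg is laid while the cumulative lag stays
    within the threshold; otherwise the hen pauses for the day, the lag resets,
    and the next egg opens a new clutch.
    """
    if lag_threshold_h <= 0:
        raise ValueError("lag_threshold_h must be > 0")
    t = state.days_since_first_egg
    lag = max(icl(t, curve) - external_cycle_h, lag_floor_h)
    if state.eggs_in_current_clutch == 0:
        state.cumulative_lag_h = 0.0
        state.eggs_in_current_clutch = 1
        state.in_pause = False
        laid = True
    elif state.cumulative_lag_h + lag > lag_threshold_h:
        state.cumulative_lag_h = 0.0
        state.eggs_in_current_clutch = 0
        state.in_pause = True
        laid = False
    else:
        state.cumulative_lag_h += lag
        state.eggs_in_current_clutch += 1
        state.in_pause = False
        laid = True
    state.days_since_first_egg += 1
    return state, laid, lag


def oviposition_time(
    position_in_clutch: int,
    photoperiod_end_h: float,
    cumulative_lag_h: float,
    sd_first_h: float = 3.0,
    sd_lag_h: float = 0.2,
    rng: np.random.Generator | None = None,
    anchor_offset_h: float = 0.0,
    clutch_anchor_h: float | None = None,
) -> tuple[float, float]:
    """Clock time of lay (possibly > 24 h, i.e. spilling into the next day).

    Returns ``(time_h, anchor_h)``.  For the first egg of a clutch
    (``position_in_clutch == 1``) a fresh anchor is drawn:
    ``photoperiod_end + offset + Normal(0, sd_first)``; subsequent eggs are
    laid at ``anchor + cumulative_lag + Normal(0, sd_lag)``.  The caller keeps
    the anchor for the rest of the clutch.  Un-wrapped times within a clutch
    strictly increase whenever the cumulative lag does.
    """
    if sd_first_h < 0 or sd_lag_h < 0:
        raise ValueError("time-of-lay SDs must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    if position_in_clutch == 1 or clutch_anchor_h is None:
        anchor = photoperiod_end_h + anchor_offset_h + rng.normal(0.0, 1.0) * sd_first_h
    else:
        anchor = clutch_anchor_h
    if position_in_clutch == 1:
        return anchor, anchor
    time_h = anchor + cumulative_lag_h + rng.normal(0.0, 1.0) * sd_lag_h
    return time_h, anchor


def classify_egg(
    rng: np.random.Generator, p_internal: float, p_soft_shell: float
) -> str:
    """Draw an egg-quality flag: 'internal', 'soft_shell' or 'normal'.

    Internal eggs are ovulations that never reach the nest: they count toward
    ovulation rate but not rate of lay or egg-mass output.  Soft-shelled eggs
    are laid (counted) but excluded from saleable output.
    """
    for name, p in (("p_internal", p_internal), ("p_soft_shell", p_soft_shell)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if p_internal + p_soft_shell > 1.0:
        raise ValueError("p_internal + p_soft_shell must be <= 1")
    u = rng.uniform()
    if u < p_internal:
        return "internal"
    if u < p_internal + p_soft_shell:
        return "soft_shell"
    return "normal"


@dataclass(frozen=True)
class OvipositionRecord:
    """One ovulation/oviposition event with its predicted component masses."""

    hen_id: int
    day: int  # days since simulation start (0-based)
    time_of_lay_h: float  # clock time in [0, 24)
    clutch_index: int
    position_in_clutch: int
    quality: str
    yolk_g: float
    albumen_g: float
    shell_g: float

    @property
    def egg_weight_g(self) -> float:
        return self.yolk_g + self.albumen_g + self.shell_g


def simulate_hen(
    hen: "HenParams",
    horizon_d: int,
    rng: np.random.Generator | int | None,
    start_age_d: int = 120,
    photoperiod_end_h: float = 16.0,
    anchor_offset_h: float = 0.0,
    sd_first_h: float = 3.0,
    sd_lag_h: float = 0.2,
    lag_floor_h: float = 0.0,
    external_cycle_h: float = 24.0,
) -> list[OvipositionRecord]:
    """Simulate one hen's ovipositions over ``horizon_d`` days.

    Day 0 corresponds to hen age ``start_age_d``; no egg appears before the
    hen's age at first egg.  Deterministic given the generator state.
    """
    if horizon_d < 1:
        raise ValueError("horizon_d must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    from .egg_model import egg_components  # local import avoids cycle at module load

    records: list[OvipositionRecord] = []
    first_day = int(hen.afe_d) - start_age_d
    if first_day >= horizon_d:
        return records
    state = SequenceState()
    clutch_index = 0
    anchor: float | None = None
    for day in range(max(first_day, 0), horizon_d):
        state, laid, _lag = step_day(
            state,
            hen.icl,
            hen.lag_threshold_h,
            rng,
            lag_floor_h=lag_floor_h,
            external_cycle_h=external_cycle_h,
        )
        if not laid:
            continue
        if state.eggs_in_current_clutch == 1:
            clutch_index += 1
        time_h, anchor = oviposition_time(
            state.eggs_in_current_clutch,
            photoperiod_end_h,
            state.cumulative_lag_h,
            sd_first_h=sd_first_h,
            sd_lag_h=sd_lag_h,
            rng=rng,
            anchor_offset_h=anchor_offset_h,
            clutch_anchor_h=anchor,
        )
        absolute_h = 24.0 * day + time_h
        rec_day = int(absolute_h // 24.0)
        quality = classify_egg(rng, hen.p_internal, hen.p_soft_shell)
        age_d = start_age_d + day
        comps = egg_components(age_d, hen.egg_curve, hen.egg_size_factor)
        records.append(
            OvipositionRecord(
                hen_id=hen.hen_id,
                day=rec_day,
                time_of_lay_h=absolute_h % 24.0,
                clutch_index=clutch_index,
                position_in_clutch=state.eggs_in_current_clutch,
                quality=quality,
                yolk_g=comps.yolk_g,
                albumen_g=comps.albumen_g,
                shell_g=comps.shell_g,
            )
        )
    return records
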
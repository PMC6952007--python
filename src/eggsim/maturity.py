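"""Sexual-maturity prediction: age at first egg (AFE) from lighting programs.

Lighting is the dominant environmental determinant of age at first egg in
full-fed pullets.  Two routes are provided:

* **Commercial layers** — an empirical four-component model: (1) a genetic
  baseline for birds held on a constant photoperiod, (2) an adjustment for the
  age at which the flock is transferred to its final photoperiod, (3) a gate
  for the age window over which photosensitivity is acquired, and (4) a
  spontaneously-maturing subpopulation that matures under the initial
  photoperiod regardless of later changes.  The flock mean is the mixture of
  the responsive and spontaneous subpopulations.

* **Broiler breeders** — breeders retain photorefractoriness, so their mean
  age at 50 % lay is predicted from a three-equation form combining body
  weight at 20 wk and the rearing light program.

The published coefficient values behind both routes are in cited primary
sources, not reproducible here; the functional forms below are structural
stand-ins with config-supplied coefficients.  The shipped defaults are
calibration placeholders chosen to give layer AFE around 143 d and breeder
AFE around 175 d.  Recalibrate against flock records before quantitative use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "LightingProgram",
    "MaturityModelParams",
    "BreederMaturityCoeffs",
    "predict_afe_layer",
    "predict_afe_breeder",
    "sample_afe",
]


@dataclass(frozen=True)
class LightingProgram:
    """An ordered lighting schedule: (age in days, photoperiod in h/d) steps.

    The program is piecewise constant: the photoperiod set at each step holds
    until the next step.  Ages must be strictly increasing and photoperiods
    within [0, 24].
    """

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValueError("LightingProgram needs at least one step")
        ages = [a for a, _ in self.steps]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("LightingProgram step ages must be strictly increasing")
        for age_d, photo_h in self.steps:
            if not 0.0 <= photo_h <= 24.0:
                raise ValueError(
                    f"photoperiod_h must be in [0, 24], got {photo_h} at age {age_d}"
                )

    @property
    def initial_photoperiod_h(self) -> float:
        return self.steps[0][1]

    @property
    def final_photoperiod_h(self) -> float:
        return self.steps[-1][1]

    @property
    def final_transfer_age_d(self) -> float:
        """Age at transfer to the final photoperiod (first step age if constant)."""
        return self.steps[-1][0]

    @property
    def is_constant(self) -> bool:
        return len(self.steps) == 1


@dataclass(frozen=True)
class BreederMaturityCoeffs:
    """Three-equation broiler-breeder maturity form.

    eq. 1: body-weight component  m1 = intercept1_d + bw20_coeff * BW20(g)
    eq. 2: lighting component     m2 = intercept2_d + lighting_coeff * (P_final - P_initial)
    eq. 3: combination            AFE50 = intercept3_d + m1 + m2
    """

    intercept1_d: float = 230.0
    bw20_coeff: float = -0.025  # d per g; heavier pullets mature earlier
    intercept2_d: float = 3.0
    lighting_coeff: float = -0.5  # d per h of photoperiod increment
    intercept3_d: float = 0.0


@dataclass(frozen=True)
class MaturityModelParams:
    """Coefficients for both maturity routes plus a fallback AFE distribution.

    ``constant_photoperiod_baseline``: mean AFE on a constant photoperiod P is
    ``intercept_d + slope_d_per_h * min(P, saturation_h)`` — the advance is
    proportional to photoperiod up to a saturation near 13 h.

    ``transfer_slope_d_per_d`` shifts the responsive subpopulation's AFE
    linearly in the age at transfer to the final photoperiod, relative to
    ``transfer_reference_age_d``.  Transfers before ``sensitivity_onset_d`` act
    as if made at onset (the pullet is not yet photosensitive).

    ``spontaneous_fraction`` of the flock matures on the initial photoperiod.
    """

    baseline_intercept_d: float = 175.0
    baseline_slope_d_per_h: float = -2.5
    baseline_saturation_h: float = 13.0
    transfer_slope_d_per_d: float = 0.10
    transfer_reference_age_d: float = 119.0
    sensitivity_onset_d: float = 63.0
    sensitivity_acquired_d: float = 126.0
    spontaneous_fraction: float = 0.05
    breeder: BreederMaturityCoeffs = field(default_factory=BreederMaturityCoeffs)
    # fallback distribution used when no lighting program is supplied
    afe_mean_d: float = 141.0
    afe_sd_d: float = 7.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spontaneous_fraction <= 1.0:
            raise ValueError("spontaneous_fraction must be in [0, 1]")
        if self.afe_sd_d < 0:
            raise ValueError("afe_sd_d must be >= 0")

    def constant_baseline(self, photoperiod_h: float) -> float:
        """Mean AFE (d) for birds held on a constant photoperiod from hatch."""
        eff = min(photoperiod_h, self.baseline_saturation_h)
        return self.baseline_intercept_d + self.baseline_slope_d_per_h * eff


class MaturityConfigError(ValueError):
    """A maturity-model coefficient set is missing or invalid."""


def _require(params: MaturityModelParams, name: str) -> None:
    if getattr(params, name, None) is None:
        raise MaturityConfigError(f"maturity model component missing: {name}")


def predict_afe_layer(program: LightingProgram, params: MaturityModelParams) -> float:
    """Mean age at first egg (d) of a full-fed layer flock under ``program``.

    Mixture of two subpopulations: the photoresponsive majority, whose AFE is
    the constant-photoperiod baseline at the *final* photoperiod adjusted for
    age at transfer (gated by the sensitivity-onset age), and the spontaneous
    fraction maturing on the *initial* photoperiod.
    """
    for name in (
        "baseline_intercept_d",
        "transfer_slope_d_per_d",
        "sensitivity_onset_d",
        "spontaneous_fraction",
    ):
        _require(params, name)
    if program.is_constant:
        return params.constant_baseline(program.final_photoperiod_h)
    t_eff = max(program.final_transfer_age_d, params.sensitivity_onset_d)
    afe_responsive = params.constant_baseline(
        program.final_photoperiod_h
    ) + params.transfer_slope_d_per_d * (t_eff - params.transfer_reference_age_d)
    afe_spontaneous = params.constant_baseline(program.initial_photoperiod_h)
    f = params.spontaneous_fraction
    return (1.0 - f) * afe_responsive + f * afe_spontaneous


def predict_afe_breeder(
    bw20_g: float, program: LightingProgram, params: MaturityModelParams
) -> float:
    """Mean age (d) at 50 % lay for a broiler-breeder flock.

    Combines body weight at 20 wk with the rearing light program through the
    three-equation form in :class:`BreederMaturityCoeffs`.  Heavier flocks at
    20 wk mature earlier (``bw20_coeff`` < 0 by default).
    """
    if bw20_g <= 0:
        raise ValueError(f"bw20_g must be positive, got {bw20_g}")
    c = params.breeder
    m1 = c.intercept1_d + c.bw20_coeff * bw20_g
    m2 = c.intercept2_d + c.lighting_coeff * (
        program.final_photoperiod_h - program.initial_photoperiod_h
    )
    return c.intercept3_d + m1 + m2


def sample_afe(
    mean_d: float,
    sd_d: float,
    n: int,
    rng: np.random.Generator | int | None = None,
    floor_d: float = 110.0,
) -> np.ndarray:
    """Draw ``n`` per-hen ages at first egg (whole days).

    Normal(mean, sd) truncated below at ``floor_d`` (no pre-pubertal ages),
    rounded to the nearest whole day.  ``sd_d = 0`` returns ``n`` copies of
    the mean.  Identical generator state gives bit-identical draws.
    """
    if sd_d < 0:
        raise ValueError("sd_d must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sd_d == 0:
        vals = np.full(n, float(mean_d))
    else:
        a = (floor_d - mean_d) / sd_d
        vals = stats.truncnorm.rvs(a, np.inf, loc=mean_d, scale=sd_d, size=n, random_state=rng)
    return np.rint(np.maximum(vals, floor_d)).astype(int)
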
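"""Egg-component curves: yolk, albumen and shell mass as functions of hen age.

Egg weight is the sum of its three components, and the yolk drives the rest:
yolk mass follows a saturating (Gompertz) curve of hen age, albumen mass is an
allometric power function of yolk mass, and shell mass is a fixed proportion
of the contents (yolk + albumen).  Strains differ in their parameter values;
shipped defaults are calibrated so composed period-mean egg weights track the
published layer/breeder trajectories (layers ~57 g at 25 wk rising to ~65 g
at 55 wk; breeders heavier and rising faster).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EggComponents",
    "YolkCurve",
    "AlbumenAllometry",
    "ComponentCurveParams",
    "yolk_weight",
    "egg_components",
    "LAYER_EGG_CURVE",
    "BREEDER_EGG_CURVE",
]


@dataclass(frozen=True)
class EggComponents:
    """Masses (g) of the three egg components; egg weight is their sum."""

    yolk_g: float
    albumen_g: float
    shell_g: float

    def __post_init__(self) -> None:
        for name in ("yolk_g", "albumen_g", "shell_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def egg_weight_g(self) -> float:
        return self.yolk_g + self.albumen_g + self.shell_g


@dataclass(frozen=True)
class YolkCurve:
    """Gompertz curve of yolk mass (g) on hen age (d from hatch)."""

    asymptote_g: float
    rate_per_d: float
    inflection_age_d: float

    def __post_init__(self) -> None:
        if self.asymptote_g <= 0:
            raise ValueError("asymptote_g must be > 0")
        if self.rate_per_d <= 0:
            raise ValueError("rate_per_d must be > 0")


@dataclass(frozen=True)
class AlbumenAllometry:
    """Albumen mass = allometry_a * yolk_g ** allometry_b."""

    allometry_a: float
    allometry_b: float


@dataclass(frozen=True)
class ComponentCurveParams:
    yolk: YolkCurve
    albumen: AlbumenAllometry
    shell_fraction_of_contents: float = 0.095

    def __post_init__(self) -> None:
        if not 0.0 < self.shell_fraction_of_contents < 0.2:
            raise ValueError("shell_fraction_of_contents must be in (0, 0.2)")


def yolk_weight(age_d: float | np.ndarray, params: ComponentCurveParams) -> float | np.ndarray:
    """Yolk mass (g) at hen age ``age_d``: non-decreasing, bounded by the asymptote."""
    c = params.yolk
    return c.asymptote_g * np.exp(-np.exp(-c.rate_per_d * (np.asarray(age_d, float) - c.inflection_age_d)))


def egg_components(
    age_d: float, params: ComponentCurveParams, size_factor: float = 1.0
) -> EggComponents:
    """Predict the three component masses for an egg laid at hen age ``age_d``.

    ``size_factor`` is a per-hen multiplicative egg-size scalar (flock-level
    variability); it scales all three components uniformly so the composition
    (yolk:albumen:shell proportions) is preserved.
    """
    y = float(yolk_weight(age_d, params))
    a = params.albumen.allometry_a * y ** params.albumen.allometry_b
    s = params.shell_fraction_of_contents * (y + a)
    return EggComponents(size_factor * y, size_factor * a, size_factor * s)


# Strain defaults: analytic calibrations of the Gompertz/allometry parameters to
# published period-mean egg-weight trajectories (see docs/methods.md for the
# anchor points and algebra).  Replace with strain-specific fits when available.
LAYER_EGG_CURVE = ComponentCurveParams(
    yolk=YolkCurve(asymptote_g=18.2, rate_per_d=0.00904, inflection_age_d=27.0),
    albumen=AlbumenAllometry(allometry_a=13.74, allometry_b=0.387),
    shell_fraction_of_contents=0.095,
)

BREEDER_EGG_CURVE = ComponentCurveParams(
    yolk=YolkCurve(asymptote_g=23.5, rate_per_d=0.00988, inflection_age_d=70.8),
    albumen=AlbumenAllometry(allometry_a=5.835, allometry_b=0.6497),
    shell_fraction_of_contents=0.09,
)
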
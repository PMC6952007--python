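"""Factorial daily nutrient requirements: egg components, maintenance, growth.

The daily requirement of a hen is the sum of the amounts needed for yolk,
albumen, shell, body growth (pre-lay only) and maintenance.  Egg-side
requirements use fixed nutrient contents per gram of component:

* energy: 2.5 kJ/g yolk, 2.6 kJ/g albumen, 1.2 kJ/g shell
* ideal protein: 0.21 g/g yolk, 0.13 g/g albumen, 0.004 g/g shell
* nitrogen (for amino acids): 27 mg/g yolk, 17 mg/g albumen

Dietary protein/amino-acid amounts are the retained amounts divided by the
feed-to-egg utilisation efficiency (default 0.80).  Yolk deposition is a
continuous process: each follicle accretes 2 g/d, so an egg's yolk demand is
spread over the days preceding its ovulation, and concurrent follicles' demands
overlap and sum.  Maintenance is based on the body protein content at first
egg — body lipid does not need to be maintained — and is therefore constant
over the laying period; no obligatory protein growth is assumed once lay
begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .egg_model import EggComponents
from .ovulation import OvipositionRecord

__all__ = [
    "NutrientConstants",
    "NutrientRequirement",
    "MaintenanceParams",
    "GrowthParams",
    "DEFAULT_AA_PROFILE",
    "egg_energy",
    "egg_ideal_protein",
    "egg_nitrogen_mg",
    "egg_amino_acids",
    "schedule_yolk_demand",
    "maintenance",
    "growth_requirement",
    "total_requirement",
    "hen_requirement_series",
    "RequirementSeries",
]

# Whole-egg protein amino-acid pattern, mg amino acid per mg nitrogen
# (egg protein = 6.25 x N).  A replaceable default: the model treats this
# profile as configuration.
DEFAULT_AA_PROFILE: dict[str, float] = {
    "lysine": 0.44,
    "methionine": 0.19,
    "cystine": 0.15,
    "threonine": 0.31,
    "tryptophan": 0.10,
    "isoleucine": 0.33,
    "leucine": 0.54,
    "valine": 0.43,
    "arginine": 0.38,
    "phenylalanine": 0.34,
    "histidine": 0.15,
}

_PROTEIN_MG_PER_MG_N = 6.25


def _aa_from_protein(ip_g: float, profile: Mapping[str, float]) -> dict[str, float]:
    """Split an ideal-protein amount into amino acids via the profile."""
    return {aa: ip_g * m / _PROTEIN_MG_PER_MG_N for aa, m in profile.items()}


@dataclass(frozen=True)
class NutrientConstants:
    """Printed nutrient contents of egg components and conversion constants."""

    energy_kj_per_g: Mapping[str, float] = field(
        default_factory=lambda: {"yolk": 2.5, "albumen": 2.6, "shell": 1.2}
    )
    ideal_protein_g_per_g: Mapping[str, float] = field(
        default_factory=lambda: {"yolk": 0.21, "albumen": 0.13, "shell": 0.004}
    )
    nitrogen_mg_per_g: Mapping[str, float] = field(
        default_factory=lambda: {"yolk": 27.0, "albumen": 17.0}
    )
    aa_profile_mg_per_mg_n: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_PROFILE)
    )
    efficiency_feed_to_egg: float = 0.80
    yolk_deposition_g_per_d: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency_feed_to_egg <= 1.0:
            raise ValueError("efficiency_feed_to_egg must be in (0, 1]")
        if self.yolk_deposition_g_per_d <= 0:
            raise ValueError("yolk_deposition_g_per_d must be > 0")


@dataclass(frozen=True)
class NutrientRequirement:
    """A daily nutrient demand: energy, ideal protein and per-amino-acid grams."""

    energy_kj_per_d: float
    ideal_protein_g_per_d: float
    amino_acids_g_per_d: Mapping[str, float] = field(default_factory=dict)

    def __add__(self, other: "NutrientRequirement") -> "NutrientRequirement":
        keys = set(self.amino_acids_g_per_d) | set(other.amino_acids_g_per_d)
        return NutrientRequirement(
            self.energy_kj_per_d + other.energy_kj_per_d,
            self.ideal_protein_g_per_d + other.ideal_protein_g_per_d,
            {
                k: self.amino_acids_g_per_d.get(k, 0.0) + other.amino_acids_g_per_d.get(k, 0.0)
                for k in keys
            },
        )

    @classmethod
    def zero(cls) -> "NutrientRequirement":
        return cls(0.0, 0.0, {})


@dataclass(frozen=True)
class MaintenanceParams:
    """Maintenance scaled on body protein mass: coeff * (BP_kg) ** exponent.

    The function and its coefficients are a design choice (only the basis,
    body protein at first egg, is fixed by the theory); defaults give a
    commercial layer (~0.25 kg BP) about 1.0 MJ effective energy and 2.3 g
    ideal protein per day for maintenance.
    """

    energy_kj_per_kg_bp: float = 4000.0
    protein_g_per_kg_bp: float = 9.0
    bp_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.energy_kj_per_kg_bp < 0 or self.protein_g_per_kg_bp < 0:
            raise ValueError("maintenance coefficients must be >= 0")
        if not 0.0 < self.bp_exponent <= 1.2:
            raise ValueError("bp_exponent must be in (0, 1.2]")


@dataclass(frozen=True)
class GrowthParams:
    """Pre-lay growth: linear approach of body protein to its at-lay value.

    ``ovary_oviduct_g`` is an extra protein allowance for reproductive-tract
    development, deposited over the same pre-lay window.  ``efficiency`` maps
    retained protein to its dietary equivalent.  ``energy_kj_per_g_protein``
    is the effective-energy cost of depositing a gram of body protein.
    """

    ovary_oviduct_g: float = 40.0
    efficiency: float = 0.80
    energy_kj_per_g_protein: float = 50.0


def egg_energy(c: EggComponents, k: NutrientConstants | None = None) -> float:
    """Energy (kJ) needed to form one egg's components."""
    k = k or NutrientConstants()
    e = k.energy_kj_per_g
    return e["yolk"] * c.yolk_g + e["albumen"] * c.albumen_g + e["shell"] * c.shell_g


def egg_ideal_protein(
    c: EggComponents, k: NutrientConstants | None = None, efficiency: float | None = None
) -> float:
    """Dietary ideal protein (g) needed to form one egg's components."""
    k = k or NutrientConstants()
    eff = k.efficiency_feed_to_egg if efficiency is None else efficiency
    p = k.ideal_protein_g_per_g
    retained = p["yolk"] * c.yolk_g + p["albumen"] * c.albumen_g + p["shell"] * c.shell_g
    return retained / eff


def egg_nitrogen_mg(c: EggComponents, k: NutrientConstants | None = None) -> float:
    """Total nitrogen (mg) in one egg's yolk and albumen."""
    k = k or NutrientConstants()
    n = k.nitrogen_mg_per_g
    return n["yolk"] * c.yolk_g + n["albumen"] * c.albumen_g


def egg_amino_acids(
    c: EggComponents, k: NutrientConstants | None = None, efficiency: float | None = None
) -> dict[str, float]:
    """Dietary amino acids (g) for one egg, from component nitrogen contents."""
    k = k or NutrientConstants()
    eff = k.efficiency_feed_to_egg if efficiency is None else efficiency
    n_mg = egg_nitrogen_mg(c, k)
    return {aa: m * n_mg / 1000.0 / eff for aa, m in k.aa_profile_mg_per_mg_n.items()}


def schedule_yolk_demand(
    records: Sequence[OvipositionRecord],
    horizon_d: int,
    k: NutrientConstants | None = None,
    ovulation_offset_d: int = 1,
) -> np.ndarray:
    """Per-day yolk deposition (g/d) implied by upcoming ovipositions.

    Each egg's yolk (mass y) is accreted at the fixed daily rate over the
    ceil(y / rate) days before its ovulation day (lay day minus
    ``ovulation_offset_d``), with the first (earliest) day carrying the
    remainder so the schedule conserves mass.  Demands of concurrently growing
    follicles sum.  Deposition scheduled before day 0 (follicles already
    growing at simulation start) is dropped.
    """
    k = k or NutrientConstants()
    rate = k.yolk_deposition_g_per_d
    out = np.zeros(horizon_d)
    for rec in records:
        y = rec.yolk_g
        if y <= 0:
            continue
        n_days = math.ceil(y / rate)
        ov_day = rec.day - ovulation_offset_d
        start = ov_day - n_days
        remainder = y - rate * (n_days - 1)
        for i, d in enumerate(range(start, ov_day)):
            if 0 <= d < horizon_d:
                out[d] += remainder if i == 0 else rate
    return out


def maintenance(
    body_protein_g: float,
    p: MaintenanceParams | None = None,
    k: NutrientConstants | None = None,
) -> NutrientRequirement:
    """Daily maintenance requirement of a hen with ``body_protein_g`` of BP."""
    if body_protein_g < 0:
        raise ValueError("body_protein_g must be >= 0")
    p = p or MaintenanceParams()
    k = k or NutrientConstants()
    scale = (body_protein_g / 1000.0) ** p.bp_exponent if body_protein_g > 0 else 0.0
    energy = p.energy_kj_per_kg_bp * scale
    ip = p.protein_g_per_kg_bp * scale
    return NutrientRequirement(energy, ip, _aa_from_protein(ip, k.aa_profile_mg_per_mg_n))


def growth_requirement(
    age_d: float,
    afe_d: float,
    remaining_bp_gain_g: float,
    p: GrowthParams | None = None,
    k: NutrientConstants | None = None,
) -> NutrientRequirement:
    """Pre-lay daily growth requirement; exactly zero on and after first egg.

    The remaining body-protein gain (including any reproductive-tract
    allowance folded in by the caller) is spread linearly over the days left
    to first egg; retained protein is divided by the growth efficiency to give
    the dietary amount.
    """
    p = p or GrowthParams()
    k = k or NutrientConstants()
    if age_d >= afe_d or remaining_bp_gain_g <= 0:
        return NutrientRequirement.zero()
    gain_per_d = remaining_bp_gain_g / (afe_d - age_d)
    ip = gain_per_d / p.efficiency
    energy = p.energy_kj_per_g_protein * gain_per_d
    return NutrientRequirement(energy, ip, _aa_from_protein(ip, k.aa_profile_mg_per_mg_n))


def total_requirement(
    yolk_deposited_g: float,
    albumen_g: float,
    shell_g: float,
    body_protein_g: float,
    k: NutrientConstants | None = None,
    maint: MaintenanceParams | None = None,
    growth: NutrientRequirement | None = None,
) -> NutrientRequirement:
    """One hen-day's total requirement: egg parts + maintenance + growth.

    ``yolk_deposited_g`` is the day's scheduled follicular deposition (not the
    laid egg's whole yolk); albumen and shell are the masses being formed that
    day.  The sum of the parts equals the total by construction.
    """
    k = k or NutrientConstants()
    comps = EggComponents(yolk_deposited_g, albumen_g, shell_g)
    egg = NutrientRequirement(
        egg_energy(comps, k), egg_ideal_protein(comps, k), egg_amino_acids(comps, k)
    )
    total = egg + maintenance(body_protein_g, maint, k)
    if growth is not None:
        total = total + growth
    return total


@dataclass
class RequirementSeries:
    """Daily requirement arrays for one hen, split into egg-side and priority
    (maintenance + growth) shares.

    Arrays have length ``horizon_d``.  The split matters for constrained
    intake: maintenance and growth are met first, and egg output scales with
    whatever limiting nutrient remains.
    """

    energy_kj: np.ndarray
    ideal_protein_g: np.ndarray
    amino_acids_g: dict[str, np.ndarray]
    egg_energy_kj: np.ndarray
    egg_ideal_protein_g: np.ndarray
    egg_amino_acids_g: dict[str, np.ndarray]
    priority_energy_kj: np.ndarray
    priority_ideal_protein_g: np.ndarray
    priority_amino_acids_g: dict[str, np.ndarray]
    body_protein_g: np.ndarray


def hen_requirement_series(
    records: Sequence[OvipositionRecord],
    afe_d: float,
    body_protein_afe_g: float,
    horizon_d: int,
    start_age_d: int = 120,
    body_protein_start_g: float | None = None,
    k: NutrientConstants | None = None,
    maint: MaintenanceParams | None = None,
    growth: GrowthParams | None = None,
    albumen_shell_lead_d: int = 1,
    ovulation_offset_d: int = 1,
) -> RequirementSeries:
    """Build a hen's daily requirement series from her oviposition records.

    Yolk demand follows the follicular deposition schedule; albumen and shell
    demand fall on the day ``albumen_shell_lead_d`` before lay (the egg is
    assembled in the oviduct the day before oviposition).  Internally-laid ova
    incur yolk demand but no albumen or shell.  Body protein rises linearly
    from its start value to the at-first-egg value, then stays constant, so
    maintenance is constant over lay.
    """
    k = k or NutrientConstants()
    maint = maint or MaintenanceParams()
    growth = growth or GrowthParams()
    eff = k.efficiency_feed_to_egg

    yolk_dep = schedule_yolk_demand(records, horizon_d, k, ovulation_offset_d)
    alb = np.zeros(horizon_d)
    shell = np.zeros(horizon_d)
    for rec in records:
        if rec.quality == "internal":
            continue
        d = rec.day - albumen_shell_lead_d
        if 0 <= d < horizon_d:
            alb[d] += rec.albumen_g
            shell[d] += rec.shell_g

    ages = start_age_d + np.arange(horizon_d)
    if body_protein_start_g is None:
        body_protein_start_g = body_protein_afe_g
    if afe_d > start_age_d:
        frac = np.clip((ages - start_age_d) / (afe_d - start_age_d), 0.0, 1.0)
    else:
        frac = np.ones(horizon_d)
    bp = body_protein_start_g + frac * (body_protein_afe_g - body_protein_start_g)

    ek = k.energy_kj_per_g
    ip = k.ideal_protein_g_per_g
    nmg = k.nitrogen_mg_per_g
    egg_e = ek["yolk"] * yolk_dep + ek["albumen"] * alb + ek["shell"] * shell
    egg_ip = (ip["yolk"] * yolk_dep + ip["albumen"] * alb + ip["shell"] * shell) / eff
    n_mg = nmg["yolk"] * yolk_dep + nmg["albumen"] * alb
    egg_aa = {aa: m * n_mg / 1000.0 / eff for aa, m in k.aa_profile_mg_per_mg_n.items()}

    scale = (bp / 1000.0) ** maint.bp_exponent
    maint_e = maint.energy_kj_per_kg_bp * scale
    maint_ip = maint.protein_g_per_kg_bp * scale

    growth_ip = np.zeros(horizon_d)
    growth_e = np.zeros(horizon_d)
    pre = ages < afe_d
    if pre.any() and afe_d > start_age_d:
        total_gain = (body_protein_afe_g - body_protein_start_g) + growth.ovary_oviduct_g
        gain_per_d = total_gain / (afe_d - start_age_d)
        if gain_per_d > 0:
            growth_ip[pre] = gain_per_d / growth.efficiency
            growth_e[pre] = growth.energy_kj_per_g_protein * gain_per_d

    prio_ip = maint_ip + growth_ip
    prio_e = maint_e + growth_e
    prio_aa = {
        aa: prio_ip * m / _PROTEIN_MG_PER_MG_N for aa, m in k.aa_profile_mg_per_mg_n.items()
    }
    total_aa = {aa: egg_aa[aa] + prio_aa[aa] for aa in egg_aa}
    return RequirementSeries(
        energy_kj=egg_e + prio_e,
        ideal_protein_g=egg_ip + prio_ip,
        amino_acids_g=total_aa,
        egg_energy_kj=egg_e,
        egg_ideal_protein_g=egg_ip,
        egg_amino_acids_g=egg_aa,
        priority_energy_kj=prio_e,
        priority_ideal_protein_g=prio_ip,
        priority_amino_acids_g=prio_aa,
        body_protein_g=bp,
    )
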
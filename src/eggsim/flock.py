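"""Monte Carlo flock: sample per-hen parameters, simulate, aggregate.

Every hen in the flock draws her own parameter vector (age at first egg, ICL
curve, lag threshold, egg-size factor, body protein at first egg, egg-quality
probabilities) independently from truncated normal distributions described by
a mean and SD per parameter.  Integrating the individual ovulation curves
reproduces the characteristic flock laying curve: the rise to peak is shaped
by the spread of maturity ages and the prime-sequence lengths; persistency
after peak by the rate at which individual sequences shorten.

Rates of lay are reported per 100 hens housed (no mortality model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .egg_model import ComponentCurveParams, LAYER_EGG_CURVE, BREEDER_EGG_CURVE
from .maturity import sample_afe
from .ovulation import ICLCurve, OvipositionRecord, simulate_hen
from .requirements import (
    GrowthParams,
    MaintenanceParams,
    NutrientConstants,
    RequirementSeries,
    hen_requirement_series,
)

__all__ = [
    "ParamDist",
    "HenParams",
    "FlockConfig",
    "FlockResult",
    "generate_flock",
    "simulate_flock",
    "summarize_periods",
    "egg_output_g",
    "layer_flock_config",
    "breeder_flock_config",
]


@dataclass(frozen=True)
class ParamDist:
    """A truncated-normal parameter distribution: Normal(mean, sd) on [lower, upper]."""

    mean: float
    sd: float = 0.0
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, float(np.clip(self.mean, self.lower, self.upper)))
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


@dataclass(frozen=True)
class HenParams:
    """The full per-individual parameter vector of one simulated hen."""

    hen_id: int
    afe_d: int
    icl: ICLCurve
    lag_threshold_h: float
    egg_size_factor: float
    body_protein_afe_g: float
    p_internal: float
    p_soft_shell: float
    egg_curve: ComponentCurveParams


# parameter draw order is fixed so flocks are reproducible across runs
_PARAM_ORDER = (
    "afe_d",
    "icl_baseline_h",
    "icl_initial_excess_h",
    "icl_decay_rate",
    "icl_senescence_slope_h_per_d",
    "lag_threshold_h",
    "egg_size_factor",
    "body_protein_afe_g",
    "p_internal",
    "p_soft_shell",
)


@dataclass(frozen=True)
class FlockConfig:
    """Flock-level simulation configuration: distributions plus shared settings."""

    n_hens: int
    seed: int
    strain: str = "layer"
    params: dict[str, ParamDist] = field(default_factory=dict)
    egg_curve: ComponentCurveParams = LAYER_EGG_CURVE
    start_age_d: int = 120
    photoperiod_end_h: float = 16.0
    anchor_offset_h: float = 0.0
    sd_first_h: float = 3.0
    sd_lag_h: float = 0.2
    lag_floor_h: float = 0.0
    external_cycle_h: float = 24.0
    afe_floor_d: float = 110.0
    body_protein_start_g: float = 210.0

    def __post_init__(self) -> None:
        if self.n_hens < 1:
            raise ValueError("n_hens must be >= 1")
        missing = [p for p in _PARAM_ORDER if p not in self.params]
        if missing:
            raise ValueError(f"FlockConfig.params missing distributions for: {missing}")


def layer_flock_config(n_hens: int = 200, seed: int = 0, **overrides) -> FlockConfig:
    """Default commercial-layer flock: early maturity, long sequences, slow senescence."""
    params = {
        "afe_d": ParamDist(141.0, 7.0, lower=110.0),
        "icl_baseline_h": ParamDist(23.9, 0.30),
        "icl_initial_excess_h": ParamDist(3.0, 0.8, lower=0.05),
        "icl_decay_rate": ParamDist(0.08, 0.02, lower=0.005),
        "icl_senescence_slope_h_per_d": ParamDist(0.006, 0.002, lower=0.0),
        "lag_threshold_h": ParamDist(8.5, 0.5, lower=1.0),
        "egg_size_factor": ParamDist(1.0, 0.06, lower=0.5),
        "body_protein_afe_g": ParamDist(254.0, 12.0, lower=50.0),
        "p_internal": ParamDist(0.01, 0.0, lower=0.0, upper=1.0),
        "p_soft_shell": ParamDist(0.02, 0.0, lower=0.0, upper=1.0),
    }
    params.update(overrides.pop("params", {}))
    return FlockConfig(
        n_hens=n_hens,
        seed=seed,
        strain="layer",
        params=params,
        egg_curve=LAYER_EGG_CURVE,
        body_protein_start_g=210.0,
        **overrides,
    )


def breeder_flock_config(n_hens: int = 200, seed: int = 0, **overrides) -> FlockConfig:
    """Default broiler-breeder flock: later maturity, shorter sequences, faster senescence."""
    params = {
        "afe_d": ParamDist(175.0, 9.0, lower=120.0),
        "icl_baseline_h": ParamDist(26.0, 0.6),
        "icl_initial_excess_h": ParamDist(3.0, 0.8, lower=0.05),
        "icl_decay_rate": ParamDist(0.08, 0.02, lower=0.005),
        "icl_senescence_slope_h_per_d": ParamDist(0.022, 0.005, lower=0.0),
        "lag_threshold_h": ParamDist(8.5, 0.5, lower=1.0),
        "egg_size_factor": ParamDist(1.0, 0.06, lower=0.5),
        "body_protein_afe_g": ParamDist(494.0, 20.0, lower=50.0),
        "p_internal": ParamDist(0.02, 0.0, lower=0.0, upper=1.0),
        "p_soft_shell": ParamDist(0.025, 0.0, lower=0.0, upper=1.0),
    }
    params.update(overrides.pop("params", {}))
    return FlockConfig(
        n_hens=n_hens,
        seed=seed,
        strain="breeder",
        params=params,
        egg_curve=BREEDER_EGG_CURVE,
        body_protein_start_g=360.0,
        **overrides,
    )


def generate_flock(cfg: FlockConfig) -> list[HenParams]:
    """Draw ``cfg.n_hens`` independent hens; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    n = cfg.n_hens
    draws: dict[str, np.ndarray] = {}
    for name in _PARAM_ORDER:
        dist = cfg.params[name]
        if name == "afe_d":
            draws[name] = sample_afe(dist.mean, dist.sd, n, rng, floor_d=cfg.afe_floor_d)
        else:
            draws[name] = dist.sample(n, rng)
    hens = []
    for i in range(n):
        hens.append(
            HenParams(
                hen_id=i,
                afe_d=int(draws["afe_d"][i]),
                icl=ICLCurve(
                    baseline_h=min(
                        draws["icl_baseline_h"][i],
                        24.0 + draws["icl_initial_excess_h"][i],
                    ),
                    initial_excess_h=draws["icl_initial_excess_h"][i],
                    decay_rate=draws["icl_decay_rate"][i],
                    senescence_slope_h_per_d=draws["icl_senescence_slope_h_per_d"][i],
                ),
                lag_threshold_h=draws["lag_threshold_h"][i],
                egg_size_factor=draws["egg_size_factor"][i],
                body_protein_afe_g=draws["body_protein_afe_g"][i],
                p_internal=draws["p_internal"][i],
                p_soft_shell=draws["p_soft_shell"][i],
                egg_curve=cfg.egg_curve,
            )
        )
    return hens


@dataclass
class FlockResult:
    """Per-hen simulation outputs plus lazy daily/period aggregation.

    ``laid`` / ``saleable_mass_g`` / ``laid_mass_g`` are (n_hens, horizon)
    arrays over calendar days; requirement arrays are stored per hen in
    ``series``.
    """

    cfg: FlockConfig
    hens: list[HenParams]
    horizon_d: int
    records: list[OvipositionRecord]
    series: list[RequirementSeries]
    laid: np.ndarray  # count of laid (normal + soft-shell) eggs per hen-day
    laid_mass_g: np.ndarray
    saleable_mass_g: np.ndarray
    _daily: pd.DataFrame | None = None

    @property
    def n_hens(self) -> int:
        return len(self.hens)

    def records_frame(self) -> pd.DataFrame:
        cols = [
            "hen_id",
            "day",
            "time_of_lay_h",
            "clutch_index",
            "position_in_clutch",
            "quality",
            "yolk_g",
            "albumen_g",
            "shell_g",
        ]
        data = {c: [getattr(r, c) for r in self.records] for c in cols}
        df = pd.DataFrame(data, columns=cols)
        df["egg_weight_g"] = df["yolk_g"] + df["albumen_g"] + df["shell_g"]
        return df

    def daily_summary(self) -> pd.DataFrame:
        if self._daily is not None:
            return self._daily
        n, h = self.n_hens, self.horizon_d
        eggs = self.laid.sum(axis=0)
        mass = self.laid_mass_g.sum(axis=0)
        rate = eggs / n * 100.0
        mean_w = np.divide(mass, eggs, out=np.full(h, np.nan), where=eggs > 0)
        df = pd.DataFrame(
            {
                "day": np.arange(h),
                "age_d": self.cfg.start_age_d + np.arange(h),
                "eggs_laid": eggs,
                "rate_of_lay": rate,
                "mean_egg_weight_g": mean_w,
                "egg_output_g_per_bird_d": mass / n,
                "saleable_output_g_per_bird_d": self.saleable_mass_g.sum(axis=0) / n,
                "energy_kj_per_d": np.mean([s.energy_kj for s in self.series], axis=0),
                "ideal_protein_g_per_d": np.mean(
                    [s.ideal_protein_g for s in self.series], axis=0
                ),
                "body_protein_g": np.mean([s.body_protein_g for s in self.series], axis=0),
            }
        )
        for aa in self.series[0].amino_acids_g:
            df[f"aa_{aa}_g_per_d"] = np.mean(
                [s.amino_acids_g[aa] for s in self.series], axis=0
            )
        self._daily = df
        return df


def simulate_flock(
    hens: list[HenParams],
    horizon_d: int,
    cfg: FlockConfig,
    constants: NutrientConstants | None = None,
    maint: MaintenanceParams | None = None,
    growth: GrowthParams | None = None,
) -> FlockResult:
    """Run every hen and assemble a :class:`FlockResult`.

    Each hen gets an independent child random stream spawned from the flock
    seed, so results are reproducible and independent of hen order.
    """
    constants = constants or NutrientConstants()
    n = len(hens)
    laid = np.zeros((n, horizon_d))
    laid_mass = np.zeros((n, horizon_d))
    saleable = np.zeros((n, horizon_d))
    all_records: list[OvipositionRecord] = []
    series: list[RequirementSeries] = []
    for i, hen in enumerate(hens):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1, hen.hen_id]))
        recs = simulate_hen(
            hen,
            horizon_d,
            rng,
            start_age_d=cfg.start_age_d,
            photoperiod_end_h=cfg.photoperiod_end_h,
            anchor_offset_h=cfg.anchor_offset_h,
            sd_first_h=cfg.sd_first_h,
            sd_lag_h=cfg.sd_lag_h,
            lag_floor_h=cfg.lag_floor_h,
            external_cycle_h=cfg.external_cycle_h,
        )
        for r in recs:
            if r.day >= horizon_d:
                continue
            if r.quality != "internal":
                laid[i, r.day] += 1
                laid_mass[i, r.day] += r.egg_weight_g
                if r.quality == "normal":
                    saleable[i, r.day] += r.egg_weight_g
        all_records.extend(recs)
        series.append(
            hen_requirement_series(
                recs,
                afe_d=hen.afe_d,
                body_protein_afe_g=hen.body_protein_afe_g,
                horizon_d=horizon_d,
                start_age_d=cfg.start_age_d,
                body_protein_start_g=min(cfg.body_protein_start_g, hen.body_protein_afe_g),
                k=constants,
                maint=maint,
                growth=growth,
            )
        )
    return FlockResult(
        cfg=cfg,
        hens=hens,
        horizon_d=horizon_d,
        records=all_records,
        series=series,
        laid=laid,
        laid_mass_g=laid_mass,
        saleable_mass_g=saleable,
    )


def egg_output_g(rate_of_lay_per_100: float, egg_weight_g: float) -> float:
    """Egg output (g/bird/d) from a laying rate (eggs/100 birds/d) and egg weight."""
    return rate_of_lay_per_100 / 100.0 * egg_weight_g


def summarize_periods(
    daily: pd.DataFrame, period_weeks: list[tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Aggregate a daily summary into age-period means.

    Periods are (first, last) age in weeks, inclusive (a hen is in week w from
    age 7*(w-1) to 7*w - 1 d).  Period egg weight is egg-count-weighted; egg
    output is recomputed as (rate / 100) x egg weight, so every row satisfies
    the output identity by construction.
    """
    if period_weeks is None:
        period_weeks = [(21, 30), (31, 40), (41, 50), (51, 60)]
    rows = []
    for lo, hi in period_weeks:
        sel = daily[(daily["age_d"] >= (lo - 1) * 7) & (daily["age_d"] < hi * 7)]
        if sel.empty:
            continue
        eggs = sel["eggs_laid"].sum()
        mass = (sel["eggs_laid"] * sel["mean_egg_weight_g"].fillna(0.0)).sum()
        egg_w = mass / eggs if eggs > 0 else np.nan
        rate = sel["rate_of_lay"].mean()
        rows.append(
            {
                "period": f"{lo} to {hi}",
                "body_protein_g": sel["body_protein_g"].mean(),
                "rate_of_lay": rate,
                "egg_weight_g": egg_w,
                "egg_output_g_per_bird_d": egg_output_g(rate, egg_w) if eggs > 0 else 0.0,
                "energy_kj_per_d": sel["energy_kj_per_d"].mean(),
                "ideal_protein_g_per_d": sel["ideal_protein_g_per_d"].mean(),
            }
        )
    return pd.DataFrame(rows)
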
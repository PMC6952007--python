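"""Feed intake prediction and economic optimization of dietary nutrient density.

Food intake is an *output* of the model, not an input: a hen attempts to eat
enough of the feed on offer to meet the requirement of whichever nutrient is
first limiting — the "desired" intake is the maximum over nutrients of
requirement / dietary density.  Actual intake may be capped by feed bulk or,
for broiler breeders, by the manager's daily allocation.  When intake falls
short, maintenance (and pre-lay growth) is met first and egg output scales
with the limiting nutrient remaining.

An individual's response to a limiting nutrient is linear up to her genetic
potential, then flat; the flock response — the integral of many individuals'
linear-plateau responses — is smooth and curvilinear, which is why populations
have optimum economic nutrient densities rather than "requirements".  The
optimizer searches dietary densities by coordinate descent on a refining grid,
re-using a single simulated flock across evaluations (common random numbers).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .flock import FlockConfig, FlockResult, generate_flock, simulate_flock
from .requirements import NutrientRequirement

__all__ = [
    "Feed",
    "EconomicInputs",
    "FeedEvaluation",
    "desired_intake",
    "actual_intake",
    "performance_under_intake",
    "margin_over_feed_cost",
    "evaluate_feed",
    "optimize_diet",
]

ENERGY = "energy"


@dataclass(frozen=True)
class Feed:
    """A feed described by nutrient densities, price and a bulk-intake cap."""

    energy_mj_per_kg: float
    nutrient_g_per_kg: Mapping[str, float] = field(default_factory=dict)
    price_per_kg: float = 0.0
    max_intake_g_per_d: float = np.inf
    name: str = "feed"

    def __post_init__(self) -> None:
        if self.energy_mj_per_kg <= 0:
            raise ValueError("energy_mj_per_kg must be > 0")
        if self.price_per_kg < 0:
            raise ValueError("price_per_kg must be >= 0")
        if self.max_intake_g_per_d <= 0:
            raise ValueError("max_intake_g_per_d must be > 0")

    def density(self, nutrient: str) -> float:
        """Density in g/kg (or MJ/kg for 'energy')."""
        if nutrient == ENERGY:
            return self.energy_mj_per_kg
        return float(self.nutrient_g_per_kg.get(nutrient, 0.0))

    def with_density(self, nutrient: str, value: float, price_per_kg: float | None = None) -> "Feed":
        if nutrient == ENERGY:
            return replace(
                self,
                energy_mj_per_kg=value,
                price_per_kg=self.price_per_kg if price_per_kg is None else price_per_kg,
            )
        dens = dict(self.nutrient_g_per_kg)
        dens[nutrient] = value
        return replace(
            self,
            nutrient_g_per_kg=dens,
            price_per_kg=self.price_per_kg if price_per_kg is None else price_per_kg,
        )


@dataclass(frozen=True)
class EconomicInputs:
    """Revenue assumptions and the optimization objective."""

    egg_price_per_kg: float = 2.0
    objective: str = "margin_over_feed_cost"
    allocation_g_per_d: float | None = None  # breeder-style daily feed allocation

    def __post_init__(self) -> None:
        if self.egg_price_per_kg < 0:
            raise ValueError("egg_price_per_kg must be >= 0")
        if self.objective not in ("margin_over_feed_cost", "feed_conversion", "egg_number"):
            raise ValueError(f"unknown objective: {self.objective}")


def _ratio_g(req_amount: float, nutrient: str, feed: Feed) -> float:
    """Feed (g) needed to supply ``req_amount`` of one nutrient."""
    if req_amount <= 0:
        return 0.0
    dens = feed.density(nutrient)
    if dens <= 0:
        raise ValueError(f"feed supplies no {nutrient} but it is required")
    if nutrient == ENERGY:
        return req_amount / 1000.0 / dens * 1000.0  # kJ -> MJ -> kg -> g
    return req_amount / dens * 1000.0


def desired_intake(req: NutrientRequirement, feed: Feed) -> float:
    """Feed intake (g/d) needed to meet the first-limiting nutrient.

    The maximum over energy, ideal protein and every required amino acid of
    requirement / density.  Zero requirement gives zero desired intake.
    """
    ratios = [
        _ratio_g(req.energy_kj_per_d, ENERGY, feed),
        _ratio_g(req.ideal_protein_g_per_d, "ideal_protein", feed),
    ]
    for aa, amount in req.amino_acids_g_per_d.items():
        ratios.append(_ratio_g(amount, aa, feed))
    return max(ratios)


def actual_intake(
    desired_g_per_d: float, feed: Feed, allocation_g_per_d: float | None = None
) -> float:
    """Realized intake: desired, capped by feed bulk and any daily allocation."""
    if desired_g_per_d < 0:
        raise ValueError("desired_g_per_d must be >= 0")
    out = min(desired_g_per_d, feed.max_intake_g_per_d)
    if allocation_g_per_d is not None:
        out = min(out, allocation_g_per_d)
    return out


def performance_under_intake(
    actual_g_per_d: float,
    feed: Feed,
    maintenance_req: NutrientRequirement,
    egg_req: NutrientRequirement,
) -> float:
    """Fraction of potential egg output realizable at ``actual_g_per_d`` intake.

    For each nutrient, the supply left after maintenance is available for egg
    formation; the realized fraction is the minimum over nutrients of
    available / egg requirement, clipped to [0, 1].
    """
    if actual_g_per_d < 0:
        raise ValueError("actual_g_per_d must be >= 0")
    fracs = []
    pairs = [
        (ENERGY, maintenance_req.energy_kj_per_d, egg_req.energy_kj_per_d),
        (
            "ideal_protein",
            maintenance_req.ideal_protein_g_per_d,
            egg_req.ideal_protein_g_per_d,
        ),
    ]
    for aa, amount in egg_req.amino_acids_g_per_d.items():
        pairs.append((aa, maintenance_req.amino_acids_g_per_d.get(aa, 0.0), amount))
    for nutrient, maint_amt, egg_amt in pairs:
        if egg_amt <= 0:
            continue
        dens = feed.density(nutrient)
        if nutrient == ENERGY:
            supply = actual_g_per_d / 1000.0 * dens * 1000.0  # g -> kg -> MJ -> kJ
        else:
            supply = actual_g_per_d / 1000.0 * dens
        fracs.append((supply - maint_amt) / egg_amt)
    if not fracs:
        return 1.0
    return float(np.clip(min(fracs), 0.0, 1.0))


@dataclass
class FeedEvaluation:
    """Flock-level economic outcome of offering one feed over the horizon."""

    feed: Feed
    intake_g_per_hen: float  # total feed over the horizon
    potential_egg_mass_g_per_hen: float
    realized_egg_mass_g_per_hen: float
    realized_saleable_g_per_hen: float
    realized_eggs_per_hen: float
    feed_cost_per_hen: float
    revenue_per_hen: float
    margin_per_hen: float
    mean_realized_fraction: float

    @property
    def feed_conversion(self) -> float:
        """kg feed per kg saleable egg (lower is better)."""
        if self.realized_saleable_g_per_hen <= 0:
            return np.inf
        return self.intake_g_per_hen / self.realized_saleable_g_per_hen

    def objective_value(self, econ: EconomicInputs) -> float:
        if econ.objective == "margin_over_feed_cost":
            return self.margin_per_hen
        if econ.objective == "feed_conversion":
            return -self.feed_conversion
        return self.realized_eggs_per_hen


def _nutrient_list(result: FlockResult, feed: Feed) -> list[str]:
    aas = list(result.series[0].amino_acids_g.keys())
    return [ENERGY, "ideal_protein", *aas]


def evaluate_feed(
    result: FlockResult,
    feed: Feed,
    econ: EconomicInputs,
    deficit_mode: str = "egg_size",
) -> FeedEvaluation:
    """Evaluate one feed against an already-simulated flock, hen by hen.

    Desired intake, the bulk/allocation cap and the realized fraction are
    computed per hen-day from that hen's own requirement series, so the flock
    response aggregates individual linear-plateau responses.  ``deficit_mode``
    states how a shortfall is expressed: ``egg_size`` shrinks eggs (egg count
    unchanged), ``pause_insertion`` drops whole eggs (expected count scaled).
    """
    if deficit_mode not in ("egg_size", "pause_insertion"):
        raise ValueError(f"unknown deficit_mode: {deficit_mode}")
    n, h = result.n_hens, result.horizon_d
    total = {
        ENERGY: np.stack([s.energy_kj for s in result.series]),
        "ideal_protein": np.stack([s.ideal_protein_g for s in result.series]),
    }
    prio = {
        ENERGY: np.stack([s.priority_energy_kj for s in result.series]),
        "ideal_protein": np.stack([s.priority_ideal_protein_g for s in result.series]),
    }
    egg = {
        ENERGY: np.stack([s.egg_energy_kj for s in result.series]),
        "ideal_protein": np.stack([s.egg_ideal_protein_g for s in result.series]),
    }
    for aa in result.series[0].amino_acids_g:
        total[aa] = np.stack([s.amino_acids_g[aa] for s in result.series])
        prio[aa] = np.stack([s.priority_amino_acids_g[aa] for s in result.series])
        egg[aa] = np.stack([s.egg_amino_acids_g[aa] for s in result.series])

    desired = np.zeros((n, h))
    for nut, req in total.items():
        dens = feed.density(nut)
        if dens <= 0:
            if np.any(req > 0):
                raise ValueError(f"feed supplies no {nut} but it is required")
            continue
        if nut == ENERGY:
            desired = np.maximum(desired, req / dens)  # kJ / (MJ/kg) == g numerically
        else:
            desired = np.maximum(desired, req / dens * 1000.0)
    if econ.allocation_g_per_d is not None:
        # restricted feeding: the flock cleans up its daily allocation
        actual = np.full((n, h), min(econ.allocation_g_per_d, feed.max_intake_g_per_d))
    else:
        actual = np.minimum(desired, feed.max_intake_g_per_d)

    frac = np.ones((n, h))
    for nut in total:
        egg_amt = egg[nut]
        dens = feed.density(nut)
        if dens <= 0:
            continue
        supply = actual * dens / 1000.0 if nut != ENERGY else actual * dens  # kJ
        avail = supply - prio[nut]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(egg_amt > 0, avail / np.where(egg_amt > 0, egg_amt, 1.0), np.inf)
        frac = np.minimum(frac, f)
    frac = np.clip(frac, 0.0, 1.0)

    realized_mass = frac * result.laid_mass_g
    realized_saleable = frac * result.saleable_mass_g
    if deficit_mode == "pause_insertion":
        realized_eggs = (frac * result.laid).sum() / n
    else:
        realized_eggs = result.laid.sum() / n
    intake = actual.sum() / n
    cost = intake / 1000.0 * feed.price_per_kg
    revenue = realized_saleable.sum() / n / 1000.0 * econ.egg_price_per_kg
    return FeedEvaluation(
        feed=feed,
        intake_g_per_hen=intake,
        potential_egg_mass_g_per_hen=result.laid_mass_g.sum() / n,
        realized_egg_mass_g_per_hen=realized_mass.sum() / n,
        realized_saleable_g_per_hen=realized_saleable.sum() / n,
        realized_eggs_per_hen=realized_eggs,
        feed_cost_per_hen=cost,
        revenue_per_hen=revenue,
        margin_per_hen=revenue - cost,
        mean_realized_fraction=float(frac[result.laid_mass_g > 0].mean())
        if np.any(result.laid_mass_g > 0)
        else 1.0,
    )


def margin_over_feed_cost(result: FlockResult, feed: Feed, econ: EconomicInputs) -> float:
    """Revenue from saleable eggs minus feed cost, per hen over the horizon."""
    return evaluate_feed(result, feed, econ).margin_per_hen


def optimize_diet(
    flock_cfg: FlockConfig,
    horizon_d: int,
    base_feed: Feed,
    search_space: Mapping[str, tuple[float, float]],
    econ: EconomicInputs,
    price_per_g: Mapping[str, float] | None = None,
    seed: int | None = None,
    n_grid: int = 7,
    n_refine: int = 3,
    deficit_mode: str = "egg_size",
    result: FlockResult | None = None,
    constants=None,
    maint=None,
    growth=None,
) -> tuple[Feed, pd.DataFrame]:
    """Search dietary densities for the best economic outcome.

    Coordinate descent over each searched nutrient on an ``n_grid``-point
    grid, repeated with the grid refined around the incumbent ``n_refine``
    times.  A single flock simulation (common random numbers: the same seed
    and hence the same hens for every candidate feed) is reused across all
    evaluations, so the search is deterministic given the seed.  The feed
    price moves with density through ``price_per_g`` (currency per extra g/kg
    of each nutrient, per kg of feed; for 'energy', per extra MJ/kg).

    Returns the best feed and the full evaluation table (one row per
    candidate) for response-curve inspection.
    """
    price_per_g = price_per_g or {}
    if result is None:
        cfg = flock_cfg if seed is None else replace(flock_cfg, seed=int(seed))
        result = simulate_flock(
            generate_flock(cfg), horizon_d, cfg, constants=constants, maint=maint, growth=growth
        )

    def priced(feed: Feed, nutrient: str, value: float) -> Feed:
        delta = value - base_feed.density(nutrient)
        base_other = feed.price_per_kg - price_per_g.get(nutrient, 0.0) * (
            feed.density(nutrient) - base_feed.density(nutrient)
        )
        return feed.with_density(
            nutrient, value, price_per_kg=base_other + price_per_g.get(nutrient, 0.0) * delta
        )

    bounds = {nut: tuple(b) for nut, b in search_space.items()}
    current = base_feed
    for nut, (lo, hi) in bounds.items():
        current = priced(current, nut, 0.5 * (lo + hi))
    rows: list[dict] = []
    best_eval = evaluate_feed(result, current, econ, deficit_mode)
    best_val = best_eval.objective_value(econ)

    for refine in range(n_refine):
        for nut in sorted(bounds):
            lo, hi = bounds[nut]
            grid = np.linspace(lo, hi, n_grid)
            for value in grid:
                cand = priced(current, nut, float(value))
                ev = evaluate_feed(result, cand, econ, deficit_mode)
                val = ev.objective_value(econ)
                rows.append(
                    {
                        "refine": refine,
                        "nutrient": nut,
                        "density": float(value),
                        "price_per_kg": cand.price_per_kg,
                        "objective": val,
                        "margin_per_hen": ev.margin_per_hen,
                        "realized_egg_mass_g_per_hen": ev.realized_egg_mass_g_per_hen,
                        "intake_g_per_hen": ev.intake_g_per_hen,
                    }
                )
                if val > best_val + 1e-12:
                    best_val = val
                    current = cand
        # shrink each nutrient's bounds around the incumbent
        new_bounds = {}
        for nut, (lo, hi) in bounds.items():
            step = (hi - lo) / (n_grid - 1)
            center = current.density(nut)
            new_bounds[nut] = (max(lo, center - step), min(hi, center + step))
        bounds = new_bounds
    return current, pd.DataFrame(rows)
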
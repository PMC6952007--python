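# Methods

This note documents the model implemented in `eggsim`: its assumptions, the
parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic flocks do and do not emulate, and known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Scope and structure

`eggsim` is an individual-based, daily-time-step simulator. One hen is a
parameter vector; a flock is a Monte Carlo sample of such vectors; flock
outputs are aggregates of independent per-hen simulations. The package is
organised as a library of small modules (`maturity`, `ovulation`,
`egg_model`, `requirements`, `flock`, `feedopt`, `fitting`, `config`/`cli`),
with the CLI a thin layer over the library. Days are whole integers; day 0
of a simulation corresponds to the configured starting age (default 120 d
from hatch); hen ages are in days from hatch.

## 2. Sexual maturity

**Layers.** Mean age at first egg (AFE) under a lighting program is a
mixture of two subpopulations:

```
AFE = (1 − f) · [B(P_final) + k_T · (max(T, T_onset) − T_ref)] + f · B(P_init)
```

where `B(P) = a0 + a1·min(P, P_sat)` is the constant-photoperiod baseline,
`T` the age at transfer to the final photoperiod, `T_onset` the age at which
photosensitivity is acquired (earlier transfers act as if made at onset),
and `f` the spontaneously maturing fraction that matures on the initial
photoperiod. A single-step (constant) program returns `B(P)` directly.

**Broiler breeders** retain photorefractoriness, so their mean age at 50 %
lay uses a three-equation form: a body-weight component
(`c1 + c_bw·BW20`, with `c_bw < 0`: heavier 20-wk pullets mature earlier), a
lighting component (`c2 + c_L·(P_final − P_init)`), and a combining
intercept.

The published coefficient values behind both forms are in cited primary
literature and are not reproducible here; the implemented forms are
structural stand-ins, config-overridable, with defaults chosen so a standard
step-up program gives layer AFE ≈ 143 d and breeder AFE ≈ 175 d. They must
be recalibrated against flock records before quantitative use for maturity
prediction specifically.

Per-hen AFE is drawn from a normal distribution truncated below at 110 d
(no pre-pubertal ages) and rounded to the nearest whole day. Rounding
rather than flooring keeps the sample mean unbiased (flooring would shift it
by −0.5 d).

## 3. Ovulatory cycle

The internal cycle length (h) at `t` days after first egg is

```
ICL(t) = b + (24 + e − b)·exp(−r·t) + s·t
```

so `ICL(0) = 24 + e` (first-egg excess `e > 0`), the curve decays at rate
`r` toward baseline `b`, and rises again with senescence slope `s ≥ 0`. The
functional form is a design choice: the biology prescribes only the shape
(high at first egg, minimum near peak, rising with age), and
exponential-decay-plus-linear is the simplest curve satisfying it. All four
parameters are per-hen and sampled in the flock module.

Daily mechanics: the day's lag is `max(ICL(t) − L_ext, floor)` with external
cycle `L_ext = 24` h and lag floor 0 by default (lags cannot reduce
accumulated lag; the config accepts other external cycle lengths but no
specialised ahemeral lighting logic). The first egg of a clutch carries no
lag — a lag is an interval *between* ovipositions. Each subsequent egg adds
its lag to the running total; when the total would exceed the threshold
(default 8.5 h, the midpoint of the reported 8–9 h range, per-hen
samplable), the hen pauses for exactly one day and the accumulator resets.
Multi-day pauses are not modelled separately; they emerge when the next
day's lag again exceeds the threshold. For a constant lag `L` and threshold
`H` this yields the closed form used as a test oracle: clutches of
`floor(H/L) + 1` eggs separated by single pause days, steady-state rate of
lay `n/(n+1)`.

**Lay times.** The first egg of a clutch is laid at
`photoperiod_end + offset + N(0, 3 h)` (offset default 0, a config
constant — the biology fixes the anchor, not the offset); later eggs at
`anchor + cumulative lag + N(0, 0.2 h)`. The ±0.2 h noise is applied
per-egg (the alternative — only on the last egg of the sequence — is
observationally near-equivalent and noted as an unresolved reading). Times
are stored modulo 24 h with the calendar day incremented when a late egg
spills past midnight; un-wrapped times strictly increase within a clutch.

**Egg quality.** Each oviposition is classified `internal` (probability
`p_internal`), `soft_shell` (`p_soft_shell`) or `normal`. Internal eggs are
ovulations that never reach the nest: they count toward ovulation rate and
incur yolk (follicular) nutrient demand, but not rate of lay, egg-mass
output, or albumen/shell demand (the ovum never traverses the oviduct).
Soft-shelled eggs are laid and counted but excluded from saleable output in
the economics.

## 4. Egg components

Egg weight is the sum of yolk, albumen and shell. Yolk mass follows a
Gompertz curve of hen age; albumen is allometric on yolk
(`a·yolk^b`); shell is a fixed fraction of contents. The underlying
strain-specific equations are unpublished; the shipped defaults are analytic
calibrations to the published period-mean egg-weight trajectories:

| strain  | anchors (age → egg weight)     | yolk Gompertz (A, k, t_i) | albumen (a, b)   | shell |
|---------|--------------------------------|---------------------------|------------------|-------|
| layer   | 175 d → 57.1 g, 385 d → 64.7 g | 18.2 g, 0.00904/d, 27 d   | 13.74, 0.387     | 0.095 |
| breeder | 185 d → 58.6 g, 388 d → 72.6 g | 23.5 g, 0.00988/d, 70.8 d | 5.835, 0.6497    | 0.09  |

The breeder allometry exponent is larger, so breeder eggs gain weight faster
with age, as the published trajectory shows. Per-hen variability enters
through a single multiplicative egg-size factor (mean 1, SD 0.06) applied
uniformly to all three components, keeping composition constant and the
parameter count manageable.

## 5. Factorial nutrient requirements

Per gram of component: yolk 2.5 kJ and 0.21 g ideal protein; albumen 2.6 kJ
and 0.13 g; shell 1.2 kJ and 0.004 g. Nitrogen: yolk 27 mg/g, albumen
17 mg/g; each amino acid is a configured profile entry (mg per mg N); the
shipped default is a whole-egg protein pattern and is explicitly
replaceable. Dietary protein and amino-acid amounts are retained amounts
divided by the feed-to-egg efficiency, 0.80. Energy is a single
"effective energy" scalar; no partitioning into heat increments.

**Timing.** Yolk is a continuous deposition: each follicle accretes 2 g/d,
so an egg of yolk mass `y` spreads over `ceil(y/2)` days ending the day
before its ovulation day (ovulation precedes lay by 1 d, configurable), with
the earliest day carrying the remainder so mass is conserved; concurrent
follicles sum (at daily lay with 18 g yolks, nine follicles overlap for a
steady 18 g/d). The 2 g/d is read as per-follicle: a flat 2 g/d per hen
could not supply an 18 g yolk at daily lay rates. Albumen and shell demand
fall on the day before lay (configurable lead).

**Maintenance** is based on body protein at first egg — body lipid needs no
maintenance — and is therefore constant through lay. The functional form is
open (only the basis is fixed); the default is linear per kg body protein
(exponent 1.0, configurable up to 1.2): 4000 kJ and 9 g ideal protein per kg
BP per day, chosen so a laying hen's total requirement sits near 1.15 MJ/d,
inside the 1.1–1.5 MJ/d band of published requirement curves. Maintenance
amino acids use the same profile, scaled through protein (6.25 × N).

**Growth** applies only before the first egg: body protein approaches its
at-lay value linearly from the simulation-start value, plus a reproductive
tract (ovary + oviduct) allowance of 40 g over the same window; retained
gain divides by a growth efficiency (default 0.80). From the day of first
egg onward no nutrients are assigned to growth — any body-protein gain in
lay is regarded as occurring in non-laying birds and is not obligatory.

The daily total is the exact sum of the parts (egg components + maintenance
+ growth), which the tests assert as a conservation identity.

## 6. Flock aggregation

Hens draw parameters independently from truncated normals (means, SDs and
bounds in `layer_flock_config` / `breeder_flock_config`); no correlation
structure is imposed (the config schema leaves a hook, defaulting to
independence). Each hen receives a child random stream spawned from the
flock seed, so results are reproducible and independent of hen order. Rates
of lay are per 100 hens housed; there is no mortality, moulting or multi-age
structure.

Default distributions were calibrated once against the published
period-mean table: layer ICL (baseline 23.9 h, excess 3.0 h, decay 0.08/d,
senescence 0.006 h/d) reproduces the layer rate trajectory
(≈88/93/90/87 vs printed 84/90/88/85); breeder (baseline 26.0 h, senescence
0.022 h/d) reproduces the breeder trajectory (≈39/73/68/64 vs printed
46/75/70/62) and the layer/breeder contrast in peak and persistency. Body
protein at first egg: layers 254 g, breeders 494 g, matching the printed
period means; the lower first-period flock means (252/461) emerge from hens
still growing toward first egg.

Period summaries report egg-count-weighted egg weight and recompute egg
output as `rate/100 × egg weight`, so every row satisfies the output
identity by construction (the printed table's own rounding tolerance,
0.5 g, is the test criterion).

## 7. Intake and economics

Desired intake is `max_i(requirement_i / density_i)` over energy, ideal
protein and every amino acid the feed declares — the amount needed to meet
the first-limiting nutrient. The scalar `actual_intake` operation is
`min(desired, bulk cap, allocation)`. At flock level, a configured daily
allocation is treated as consumed in full (restricted breeder feeding:
birds clean up their allocation; cost then rises with density, which is what
places the economic optimum at the response knee); ad-libitum flocks eat
`min(desired, bulk cap)`. Heat-loss-limited intake is out of scope; the
bulk cap is a single maximum grams/day.

Under constrained intake, maintenance and growth are met first; the realized
fraction of potential egg output is `clip(min_i((supply_i − priority_i) /
egg_i), 0, 1)` per hen-day. Two deficit-expression modes are offered —
`egg_size` (default: eggs shrink, counts unchanged) and `pause_insertion`
(expected egg counts scale) — because the mechanism of shortfall expression
is not biologically settled; mass-based economics are identical between
them.

The optimizer is coordinate descent on an `n_grid`-point grid per nutrient,
refined `n_refine` times around the incumbent, with one simulated flock
reused across all evaluations (common random numbers). A named black-box
optimizer was deliberately avoided: the objective is a stochastic simulation
output, and a deterministic monotone-improvement search is reproducible and
emits the full response table for inspection. Feed price moves linearly
with searched densities (`price_per_g` per nutrient); ingredient-level
least-cost formulation is out of scope — the search is over the density
vector directly.

## 8. ICL curve estimation (`fitting`)

The observable signature of the ICL curve is the within-clutch lag:
consecutive eggs' absolute lay times minus 24 h. Pooling (days since first
egg, lag) pairs across hens and fitting
`lag(t) = β0 + β1·exp(−r·t) + s·t` by nonlinear least squares
(`scipy.optimize.curve_fit`, bounded) recovers the population-mean curve;
`ICLCurveModel.fit()` returns a results object with estimates, standard
errors from the parameter covariance, and a `summary()` table. Caveats:
lags floored at zero are censored (curves dipping below 24 h cannot be
recovered in that region — use baselines above 24 h for identifiable
designs), and per-hen parameter heterogeneity biases the decay estimate
slightly (Jensen's inequality); at the SDs used in the tests the bias is
within a few percent.

## 9. Numerical and reproducibility choices

* All randomness flows from `numpy` `SeedSequence` trees: flock generation
  uses `[seed, 0]`, hen `i`'s simulation `[seed, 1, i]`.
* Noise draws are made unconditionally (SD 0 yields exactly 0), keeping
  random streams aligned across noise settings.
* The clutch-oracle boundary (`cumulative + lag > threshold`) is a strict
  inequality; grid tests use dyadic values so floating-point addition is
  exact at the boundary.
* Degenerate inputs: zero body protein → zero maintenance; empty record
  lists → zero demand; a horizon ending before first egg → no records;
  follicular deposition scheduled before day 0 is dropped (conservation
  holds up to one boundary follicle, as tested).
* Problem sizes in the tests (flocks of 1–200 hens, horizons of 100–300 d)
  were chosen as the smallest at which the checked properties are stable;
  the full-size acceptance recovery uses 200 hens × 300 d.

## 10. What the synthetic flocks do and do not emulate

The generator reproduces: the rise of the flock laying curve shaped by
maturity spread and prime-sequence length, peak and post-peak persistency
differences between layers and breeders, egg-weight growth with age,
within-flock egg-size variation, and incidence of internal/soft-shelled
eggs. It does not emulate: mortality and culling, moulting, seasonal or
thermal effects on intake, correlated parameter draws, double-yolked eggs,
within-clutch egg-weight position effects, or age-driven bimodality of
ovulation times beyond what clutch-position mixing produces. Passing tests
therefore demonstrate internal consistency of the model's mechanics and its
agreement with the published summary trajectories — not predictive accuracy
for any particular commercial flock, which requires strain-specific
recalibration of the maturity, egg-component and ICL parameters.

## 11. Known limitations

* Maturity coefficients and egg-component parameters are documented
  placeholders calibrated to summary trajectories, not fitted to raw data.
* Body lipid is tracked only implicitly (energy balance residual); there is
  no lipid-reserve feedback on intake or lay.
* The amino-acid profile per g N is a single whole-egg pattern; yolk and
  albumen protein differ in composition, which the model averages over.
* One pause day per threshold crossing; prolonged pauses and broodiness are
  not represented.
* The optimizer assumes the flock's potential is invariant to the feed
  (potential is simulated once); chronic deficits that would re-shape the
  ovulatory cycle itself are outside the model.
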
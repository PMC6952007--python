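# eggsim

Stochastic simulation of egg production and factorial nutrient requirements
for commercial laying hens and broiler breeders, with economic optimization
of dietary nutrient densities.

## Who this is for

Poultry nutritionists and production modellers who need to (a) predict the
daily energy, ideal-protein and amino-acid requirements of a flock from first
principles rather than requirement tables, and (b) find the dietary nutrient
densities that maximize an economic objective (margin over feed cost, feed
conversion, egg numbers). Populations of hens do not have "requirements" —
each individual has a linear-plateau response to a limiting nutrient, and the
flock response is the curvilinear integral of those individuals — so the
economically optimum density must come from simulation, not from a table.

## The model

Each hen is an individual with her own parameter vector drawn from
truncated-normal distributions (Monte Carlo over the flock):

* **Sexual maturity.** Age at first egg (AFE) comes from a lighting-response
  model (a four-component empirical form for photoresponsive layers; a
  three-equation form using 20-wk body weight for photorefractory broiler
  breeders) or directly from a configured distribution.
* **Ovulatory cycle.** The internal cycle length (h) at `t` days after first
  egg is

  `ICL(t) = b + (24 + e − b)·exp(−r·t) + s·t`

  with first-egg excess `e`, baseline `b`, decay rate `r` and senescence
  slope `s`. The daily lag is `max(ICL − 24, 0)`; lags accumulate across a
  laying sequence and when the cumulative lag would exceed a threshold
  (default 8.5 h) the hen takes a pause day and starts a new clutch. This one
  curve generates short early clutches, a long prime sequence near peak, and
  shortening clutches (more pauses) with age. Lay times are anchored to the
  end of the previous day's photoperiod (SD 3 h) and drift later through the
  sequence by the cumulative lag (SD 0.2 h).
* **Egg components.** Egg weight = yolk + albumen + shell: a Gompertz yolk
  curve of age, allometric albumen on yolk, shell proportional to contents.
* **Factorial requirements.** Per gram: yolk 2.5 kJ and 0.21 g ideal
  protein; albumen 2.6 kJ and 0.13 g; shell 1.2 kJ and 0.004 g. Amino acids
  from component nitrogen (yolk 27 mg N/g, albumen 17 mg N/g) through a
  profile per mg N; dietary amounts divide by a feed-to-egg efficiency of
  0.80. Yolk is deposited at 2 g/d per growing follicle, so concurrent
  follicles overlap. Maintenance scales on body protein at first egg (body
  lipid needs no maintenance) and is constant through lay; pre-lay growth is
  budgeted until the first egg, after which no nutrients are assigned to
  growth.
* **Intake and economics.** Desired intake is the feed needed for the
  first-limiting nutrient, `max_i(requirement_i / density_i)`; actual intake
  may be capped by bulk or a breeder-style daily allocation, in which case
  egg output scales with the limiting nutrient left after maintenance. A
  coordinate-descent optimizer with common random numbers searches densities
  for the best economic outcome.

## Worked example

```python
import eggsim as es

cfg = es.layer_flock_config(n_hens=200, seed=1)
flock = es.generate_flock(cfg)
result = es.simulate_flock(flock, horizon_d=300, cfg=cfg)
print(es.summarize_periods(result.daily_summary()).round(1).to_string(index=False))
```

```
  period  body_protein_g  rate_of_lay  egg_weight_g  egg_output_g_per_bird_d  energy_kj_per_d  ideal_protein_g_per_d
21 to 30           253.4         88.7          56.7                     50.3           1146.6                   11.4
31 to 40           253.7         93.8          60.6                     56.8           1154.9                   12.3
41 to 50           253.7         90.0          62.9                     56.7           1154.3                   12.3
51 to 60           253.7         86.8          64.2                     55.7           1147.6                   11.7
```

Reading the table: rate of lay (eggs/100 birds·d) rises to a peak in the
31–40 wk period and declines slowly (layers are persistent); egg weight
climbs from ~57 g to ~64 g as the yolk curve matures; egg output is
rate × weight; the flock-mean requirement peaks with egg mass output at about
1.15 MJ effective energy and 12.3 g ideal protein per bird-day. Every row
satisfies `egg_output ≈ rate/100 × egg_weight` by construction.

The same flow works from the shell:

```sh
eggsim fixtures --name layer_default --out layer.yaml
eggsim simulate --config layer.yaml --seed 1 --out runs/layer
eggsim optimize --config layer.yaml --nutrient lysine=5:12 --price-per-g lysine=0.02 --out runs/opt
```

Every run writes a `manifest.json` (config hash, seed, version) sufficient to
reproduce its outputs bit-for-bit.

## Documentation

See `docs/methods.md` for the full model description, parameter defaults,
calibration notes and known limitations.
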
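# transitqmp

Quantitative microbiome profiling and mass-balance analysis of colonic
transit-time variation in a two-compartment semi-continuous in vitro gut
reactor.

## The problem

Colonic transit time — how long digesta resides in the gut — is a major
driver of gut-microbiome load, composition and metabolism, but it cannot be
varied in vivo without confounding. In vitro gut simulators sidestep this:
transit time *t* is imposed by sizing each colon vessel so that its working
volume equals the influent dosage rate times the desired residence time
(V = Q·t, dilution rate D = 1/t), while the influent is concentrated per
configuration so every arm receives the same volumetric nutrient loading
(g·L⁻¹reactor·day⁻¹). Species with maximal specific growth rate μ below D
wash out; the community that remains shifts from fast simple-sugar
fermenters at short transit toward slow fibre, mucin and amino-acid
specialists at long transit.

`transitqmp` implements the full analysis chain for such an experiment, and
a mechanistic simulator that generates every input it needs, so the whole
pipeline runs and is tested without any external data:

| module | what it does |
|---|---|
| `reactor` | transit → volume/flow/dilution arithmetic, stabilisation schedules, equal-loading influent concentrations |
| `simulate` | multi-substrate Monod community dynamics with discrete transfer events, plus the observation layer (multinomial 16S reads with copy-number bias, two-channel cytometry events, noisy chemistry) |
| `fcm` | threshold gating of green/red fluorescence events into intact/damaged/noise; cell concentrations from acquisition volume and dilution |
| `qmp` | OTU QC filters, rarefaction, 16S copy-number correction, and quantitative profiles QMP = total cells × copy-corrected proportions |
| `massbalance` | net daily production P = (c_out − c_in)·Q per metabolite, carbohydrate utilisation U, biomass production B, and the efficiency ratios P/U, B/U, P/B |
| `stats` | Kruskal–Wallis, Mann–Whitney rank-sum and Wilcoxon signed-rank tests (exact at small n), Holm and Benjamini–Hochberg corrections, compact letter displays |
| `ordination` | Bray–Curtis dissimilarity, PCoA, and db-RDA variance partitioning with Ezekiel-adjusted R² (`DBRDA(...).fit()` → results with `summary()`) |
| `spls` | sparse PLS regression linking taxon abundances to net metabolite production (`SPLS(...).fit()`), CV tuning, relevance networks |
| `pipeline` / `cli` | end-to-end orchestration with seeded child streams and a run manifest |

## Worked example

Reactor geometry for the three arms (also via `transitqmp config`):

```
arm     pc_transit_h  dc_transit_h  total_transit_h  daily_flow_mL  influent_carb_g_per_L  stabilisation_days
short   8.0           13.0          21.0             600.0          14.3325                6
medium  16.0          26.0          42.0             600.0          28.665                 11
long    24.0          39.0          63.0             600.0          42.9975                16
```

A 200 mL dose every 8 h gives Q = 600 mL/day; the short arm's proximal
vessel is 25 mL/h × 8 h = 200 mL with D = 0.125 h⁻¹; the community is
stabilised after 9 distal plus 6 total transits (6/11/16 days per arm).
(The medium arm is defined by its compartment residence times, 16 + 26 h.)

Simulating the short arm at steady state and applying the mass balance:

```python
from transitqmp.reactor import ReactorConfig
from transitqmp.simulate import default_panel, simulate_experiment
from transitqmp.massbalance import net_production_rate

rc = ReactorConfig.for_arm("short")
day = rc.stabilisation_days + 6
sim = simulate_experiment(rc, default_panel(), n_days=day, sample_days=[day], seed=1)
ace = sim.samples.loc[(day, "proximal"), "acetate"]
print(f"proximal acetate on day {day}: {ace:.1f} mM")
print(f"net acetate production: {net_production_rate(ace, 0.0, rc.daily_flow_mL):.1f} mmol/day")
```

prints

```
proximal acetate on day 12: 42.4 mM
net acetate production: 25.4 mmol/day
```

i.e. 42.4 mM of accumulated acetate flushed at 0.6 L/day is a net
production of 25.4 mmol/day in the proximal vessel. The same simulated
community reaches 3.6 × 10⁹ cells/mL at short transit versus
1.2 × 10¹⁰ cells/mL at long transit — higher population density with slower
transit, at the cost of a lower biomass yield per gram of carbohydrate.

The full synthetic experiment (6 donors × 3 arms × 2 compartments × 5 days)
runs with:

```sh
transitqmp run --out results/demo --seed 1
transitqmp report --dir results/demo
```

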
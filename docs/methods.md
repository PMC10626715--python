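# Methods

This note documents the models and numerical choices behind `transitqmp`:
what the simulator does and does not emulate, how each analysis stage is
defined, and where design decisions were genuinely open.

## Reactor geometry

Transit time is imposed hydraulically. With an influent dosage rate of
25 mL/h (200 mL per 8-h feed cycle), a compartment holding residence time
*t* hours has working volume V = 25·t mL and dilution rate D = 1/t h⁻¹.
The three arms use proximal/distal residence times of 8+13 h (short, 21 h
total), 16+26 h (medium, 42 h) and 24+39 h (long, 63 h). Note the medium
arm is defined by its compartment values; a 32 h total is sometimes quoted
for this design but is inconsistent with the 16+26 h split and with the
stabilisation schedule, so the compartment values are authoritative here.

Stabilisation is declared after max(9 distal transits, 6 total transits),
rounded up to whole days — 6, 11 and 16 days for the three arms. Day
counting uses ceil(hours/24) and ignores any pre-flow stagnant period.

To keep nutrient supply from confounding transit, the influent carbohydrate
concentration is set per arm as C_in = L·V_total/Q with L = 16.38
g·L⁻¹reactor·day⁻¹, so the volumetric loading is identical across arms
(14.33 / 28.67 / 43.00 g/L influent for short/medium/long).

## Community simulator

**Dynamics.** Each arm is a serial pair of well-mixed vessels. Species *s*
grows at μ_s = μmax_s · Σ_p w_sp · S_p/(K_sp + S_p) over its preferred
substrate pools: simple carbohydrates, complex fibre, mucin+protein, and
lactate (the cross-feeding pool — lactate producers feed lactate
consumers; no other interaction terms exist). Integration uses
exponential-Euler steps (default dt = 0.05 h): cells multiply by
exp(μ·dt), substrate demand is grams = Δcells/yield, and when a pool cannot
cover total demand all uptake from that pool is rescaled proportionally, so
concentrations never go negative and cells-produced = grams-consumed ×
yield holds exactly at every step. Metabolites change by fixed per-gram
stoichiometries (mmol/g). This makes the simulator's cumulative production
ledger an exact integral that the mass-balance module can be validated
against.

**Transfer.** Feeding is event-based: a dose of volume v is removed from
the distal vessel, v of proximal content moves distally, and v of fresh
influent enters proximally, each as an instantaneous volume-weighted mix.
A non-growing population therefore decays by ln(V/(V−v)) per transfer
period — the discrete washout threshold. The 8-h cycle dose is split into
hourly sub-doses (8 per cycle) because the short arm's proximal volume
equals the full cycle dose (200 mL); a single event would replace the
entire vessel each cycle and wash out every species regardless of growth
rate, which no semi-continuous reactor with ongoing mixing actually does.
With hourly dosing the short-arm proximal threshold is
ln(200/175) ≈ 0.134 h⁻¹, close to the nominal D = 0.125 h⁻¹, and the
continuous chemostat residual S* = K·D/(μ−D) is recovered as v/V → 0
(verified in the tests).

**Species panel.** Twelve archetypes span the in-silico-predicted anaerobic
growth-rate range for gut taxa, 0.084–0.520 h⁻¹: fast simple-sugar
fermenters (0.52), a moderately fast broad fermenter producing lactate
(0.17), a lactate consumer (0.17), fast glycan degraders (0.419, 0.52),
butyrate producers (0.239), and slow fibre/mucin/amino-acid specialists
(0.084–0.088). Yields are 1.5–3.5 × 10¹¹ cells per gram of substrate
(≈0.2–0.35 g biomass/g at ~1 pg per cell); 16S copy numbers 2–7.
SCFA stoichiometries are plausible fermentation profiles (acetate +
propionate for Bacteroides-type degraders, butyrate for clostridial
fermenters, branched SCFA + ammonium for the amino-acid fermenter); they
are archetypes, not calibrated to any dataset.

**Donors.** Each simulated donor carries (i) a lognormal inoculum jitter
(σ = 0.7) and (ii) persistent per-species growth-rate factors, lognormal
with σ = 0.05 on the log scale, representing strain-level variation. The
second mechanism is what survives to steady state and generates
inter-individual variance. σ = 0.05 was chosen once so that transit remains
the dominant driver of the quantitative profiles while donors explain a
substantial minority fraction, mirroring the qualitative structure of the
in vitro system being emulated. Because competition amplifies small rate
differences, donor identity dominates the *proportional* profiles in the
simulator more than in real data — a known fidelity limit.

**Observation layer.**
- Reads: multinomial at the chosen depth with probabilities ∝ cells ×
  copy number (the forward model inverted by the QMP stage).
- Cytometry: the measured concentration is drawn lognormally around truth
  with a given CV (mean-unbiased parameterisation); events are emitted from
  a three-component Gaussian mixture in (log₁₀ green, log₁₀ red) —
  intact (2.8, 1.2), damaged (2.3, 2.6), noise (0.8, 0.8) — and the
  acquisition volume is set so gated counts divided by volume recover the
  measured concentration. Control acquisitions (filtered negative,
  heat-killed) are generated from the pure mixture components.
- Chemistry: additive Gaussian noise truncated at zero (defaults: 1 mM for
  metabolites, 0.3 g/L for carbohydrate).

**RNG.** A single root seed; every consumer derives a named child stream
(`child_rng(seed, *keys)`, CRC-keyed `SeedSequence`), so any stage can be
re-run in isolation with the stream it saw in the full pipeline, and
identical seeds give bit-identical runs.

**What the simulator does not emulate:** pH dynamics and control, gas
phase, mucosal adhesion, strain evolution, density-dependent death,
compositional read biases other than copy number, cytometer spillover or
drift. Passing tests therefore demonstrate correctness of the analysis
chain under a mechanistically sensible generative model, not fidelity to
any particular real community.

## Flow cytometry

Rectangular threshold gates replace density-based gating: the noise
threshold is the 0.999 order-statistic quantile of negative-control green
fluorescence; the damaged threshold is the 0.01 quantile of red
fluorescence among heat-killed events that pass the noise gate (so ≥99% of
gated heat-killed cells classify damaged, by construction;
order-statistic interpolation makes the guarantee exact). Events below the
noise gate are discarded; remaining events split by the red threshold into
damaged and intact. Concentration = count/(volume in mL) × dilution
factor; technical duplicates are averaged after concentration computation.
Raw-scale input is log-transformed with a floor at 1 a.u.

## Quantitative microbiome profiles

Order of operations: OTU QC → sample flagging → rarefaction → copy-number
correction → QMP. QC removes singletons, OTUs present in <5% of samples,
and OTUs whose total reads do not exceed 0.5 × the number of samples (in
that order; the composite is idempotent). Experimental samples whose depth
is at or below the maximum blank/negative total are removed and reported.
Rarefaction is a single seeded multivariate-hypergeometric draw per sample
to the minimum retained depth (kept on integers; rarefying first keeps the
copy-number correction on unbiased proportions). Copy-number correction
divides reads by per-OTU copy number and renormalises; QMP multiplies by
the cytometric total so column sums equal the cell totals exactly.
Expected rarefaction curves use the analytic hypergeometric form
E[S(d)] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)).

## Mass balance

With Q the daily flow, proximal net production of a metabolite is
P = (c_prox − c_in)·Q (fresh influent carries no cells and, by default, no
fermentation metabolites); distal production subtracts the proximal
concentration, so compartment rates telescope to the whole-system rate
identically. Carbohydrate utilisation U = (c_in − c_out)·Q and biomass
production B = (x_out − x_in)·Q follow the same convention. Efficiencies
P/U (mmol/g), B/U (cells/g) and P/B (mmol/cell) are reported only when the
denominator is positive; otherwise NaN with an explicit undefined flag —
never an infinity or a negative ratio. "Total SCFA" sums acetate,
propionate, butyrate, isobutyrate and isovalerate by default; membership
is a configuration choice. Rates are computed per sampling day; averaging
across days is left to the downstream statistics.

Sampling in the simulator happens immediately before a transfer event; at
periodic steady state every sub-dose is identical, so concentration × Q
equals the true exported mass per day and the flow-based rates match the
simulator's integrated production to within integration error (≤2% in the
acceptance checks, with only well-determined rates compared).

## Statistics

Arms are compared with Kruskal–Wallis followed by pairwise two-sided
Mann–Whitney rank-sum tests with Holm correction and a compact letter
display (insert-and-absorb); compartments with paired two-sided Wilcoxon
signed-rank tests; feature families with Benjamini–Hochberg. The phrase
"unpaired signed-rank test" is a contradiction; the unpaired member of the
Wilcoxon family is the rank-sum test, which is what is implemented (the
choice is recorded in each result's `method` string). Zero differences in
the signed-rank test are dropped (Pratt's treatment available via
`zero_method="pratt"`); ties receive average ranks everywhere. Exact
enumeration is used for the rank-sum test at n₁+n₂ ≤ 12 without ties, the
signed-rank test at n ≤ 15 without ties, and Spearman's ρ at n ≤ 9 (full
permutation enumeration); otherwise tie-corrected large-sample
approximations. For taxon-specific comparisons, donors lacking the taxon
in at least one arm are excluded by default (the strict reading); a
lenient mode (detected in ≥1 arm) is selectable.

## Ordination and variance partitioning

Bray–Curtis dissimilarities feed Gower-centred PCoA; negative eigenvalues
are reported but their axes are excluded from the coordinates (a Lingoes
correction is available by flag, off by default to match common practice of
reporting them separately). `DBRDA` regresses the positive-axis
coordinates on a dummy-coded (treatment-contrast) constraint, partialling
out covariates when given: R²raw is the semipartial constrained fraction
of total positive inertia, and the adjusted fraction is subtractive,
adjR²(X|Z) = adjR²(X+Z) − adjR²(Z), with Ezekiel's formula
1 − (1−R²)(n−1)/(n−m−1). The subtractive value is capped at the raw
fraction (a covariate set fitting worse than chance would otherwise push
the semipartial above its ceiling). Significance uses label permutations —
free for marginal models, restricted within covariate strata for partial
models — with p = (exceedances+1)/(n_perm+1). Factor pairs that are
collinear (e.g. donor and any donor-level trait) must be fitted in
separate models; the model builder raises rather than silently dropping
columns. Under the null the adjustment is mean-unbiased at 0 (verified by
simulation), and on Euclidean distances db-RDA reproduces classic RDA to
machine precision (the module's primary oracle).

## Sparse PLS integration

X (taxon abundances, log₁₀(x+1) then unit-scaled — abundances span orders
of magnitude) and Y (net production rates, unit-scaled) are linked in
regression mode. Per component, NIPALS power iterations on X'Y with
soft-thresholding retain the keepX/keepY largest-magnitude weights
(convergence at 1e-9 or 500 iterations); both matrices are deflated on the
X-scores. With nothing thresholded the model equals dense NIPALS PLS
(cross-checked against an independent implementation). Tuning
cross-validates the predicted–held-out correlation over a (components ×
keepX) grid and applies a one-standard-error rule, choosing the sparsest
model within one SE of the best — the selection rule was an open choice
and parsimony was preferred. Relevance networks score each taxon–
metabolite pair by Σ_h cor(xᵢ, t_h)·cor(y_j, t_h) over the fitted
components, clipped to [−1, 1]; the default edge threshold is 0.55. On
the simulator's own demo data the network is typically empty at that
threshold: distal net rates are small (most substrate is consumed
proximally) and pooling compartments dilutes the correlations — an honest
property of the synthetic system, not of the method, which recovers
planted associations with the correct sign in the oracle tests.

## Pipeline defaults and problem sizes

The demo experiment is 6 donors × 3 arms × 2 compartments × 5 daily
samples after stabilisation (180 samples): read depth 10,000; cytometry CV
5%, 20,000 events per acquisition, duplicate measurements; 199
permutations in the variance partition; sPLS with 2 components and
keepX = 8. The test suite uses smaller replicas of the same conditions
where full size adds nothing to the property being checked; simulation
step sizes and horizons (dt = 0.05 h, stabilisation + 5 days) are the
package's defaults throughout.

## Known limitations

- Competitive exclusion under pure Monod competition leaves few coexisting
  species per substrate pool at steady state; real communities are far more
  even. Niche overlap parameters could soften this but are not calibrated.
- The medium arm's total transit (42 h from compartment values) and the
  occasionally quoted 32 h cannot both be right; this package standardises
  on the compartment values and the discrepancy is inherited, not resolved.
- Gate geometry is a stated substitute for density-based cytometry gating,
  adequate for the synthetic mixtures but not a reconstruction of any
  instrument-specific workflow.
- Rarefaction depth and seed are free parameters of any real reanalysis;
  outputs are contract-reproducible (given seed), not bit-comparable to
  externally processed datasets.
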
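# Methods

## Exposure model

The estimated daily intake (EDI, μg/kg bw/day) follows the standard
contaminant-intake identity `EDI = Cs × IR / (1000 × Bw)`: Cs the tissue
concentration in μg/kg wet weight, IR the daily wet-weight intake of that
tissue in g/day, Bw the body weight in kg, and 1000 the unit reconciliation.
Under the default `per_tissue_sum` aggregation, each Monte Carlo iteration
sums this term over the two edible tissues — abdominal muscle and
hepatopancreas — with tissue intakes `IR_t = IR_total × ratio_t` derived
from total crayfish consumption and the tissue-to-body mass fractions.

A second aggregation, `single_tissue`, pairs one tissue's concentration
distribution with the *total* consumption rate. Both modes are first-class
because neither arithmetic is uniquely implied by published summary tables
of this kind: the per-tissue sum is the physically explicit model, while the
single-tissue product is the common spreadsheet shortcut. The adult mean EDI
is ≈0.0008 μg/kg bw/day under the first and ≈0.0015 under the second
(hepatopancreas); reports always name the mode in use, and the package
claims neither as canonical.

Risk characterisation: `HQ = mean EDI / RfD`, with HQ > 1 flagging potential
non-carcinogenic risk, and TDI compliance as the percentage of iterations
whose EDI falls below the tolerable daily intake. Populations (adults,
children) share identical concentration draws and differ only in body
weight, so their per-iteration EDIs differ by exactly the Bw ratio (3.5 for
70 vs 20 kg); this isolates the body-weight effect from sampling noise.

## Default parameters

| Parameter | Default | Units | Origin / rationale |
|---|---|---|---|
| `ir_total` | 10.54 | g/day wet weight | adult per-capita crayfish consumption |
| `ratio_muscle` | 0.2000 ± 0.0501 | — | abdominal-muscle/body mass fraction |
| `ratio_hepatopancreas` | 0.1196 ± 0.0193 | — | hepatopancreas/body mass fraction |
| `bw` | adults 70, children 20 | kg | standard assessment body weights |
| `rfd` | 0.7 | μg/kg bw/day | US NAS reference dose for perchlorate |
| `tdi` | 0.3 | μg/kg bw/day | EFSA tolerable daily intake |
| `n_iterations` | 1000 | — | Monte Carlo iteration count |
| Cs muscle | lognormal, 20.98 ± 10.49 | μg/kg | measured tissue mean ± SD |
| Cs hepatopancreas | lognormal, 10.21 ± 3.30 | μg/kg | measured tissue mean ± SD |

Intake rates and mass-fraction ratios are deterministic by default — they
are reported as constants — with a `stochastic_ratios` switch that draws the
ratios from zero-truncated normals at their stated SDs for uncertainty
exploration.

## Distribution families and moment matching

Tissue concentrations are right-skewed (sample median below mean in every
tissue), so the default concentration family is the lognormal, which also
guarantees positivity. From a printed mean m and SD s the parameters follow
the closed form `σ² = ln(1 + (s/m)²)`, `μ = ln(m) − σ²/2`, making the
analytic moments of the spec equal the inputs exactly (round-trip tested to
1e-12 relative error). `s = 0` degrades to a point mass.

A zero-truncated normal is offered as a sensitivity alternative; its
pre-truncation location and scale are solved numerically so the
*post-truncation* moments match. A truncated normal cannot attain a
coefficient of variation ≥ 1 (the exponential limit), so such targets are
rejected with a pointer to the lognormal; the synthetic generator instead
clamps the target SD to 0.95·mean under this family and warns that realized
moments deviate.

Fitting from raw samples is maximum likelihood within the family (for the
lognormal: mean and n-denominator SD of the log values); a constant sample
collapses to a point mass regardless of the requested family.

## Latin hypercube sampling

`lhs_sample` cuts [0, 1) into n equal-probability strata, draws one
uniformly jittered point in each, randomly permutes the strata and maps the
points through the spec's inverse CDF. This yields exactly one draw per
stratum at every n (a tested invariant) and reduces the variance of the
simulated mean relative to simple random sampling at equal n (tested across
200 seeds against the package's own SRS sampler). The percentile convention
throughout is linear interpolation between closest order statistics (the
"inclusive" convention); it is fixed and documented rather than matched to
any particular commercial tool, whose convention is not public.

## Seeding and reproducibility

One master seed governs everything. Every stochastic operation draws from a
named PCG64 substream obtained by hashing a label path (e.g.
`("cs", "abdominal_muscle")` or `(source, region, tissue)`) into
`SeedSequence` entropy. Consequences: identical seeds replay bit for bit;
different cells, tissues and purposes are statistically independent; and
changing one generator cell's parameters cannot perturb another cell's
draws, because stream identity depends only on the label, never on
parameters or on how much other streams consumed.

## Synthetic data generator

No raw per-sample concentrations are published for this system, so the
generator emulates the features the analysis depends on:

- **Marginals.** Each (source, region, tissue) cell draws from a lognormal
  (default) moment-matched to its target mean ± SD: the seven cultivation
  regions and five market cities carry their reported whole-crayfish
  moments, and the edible tissues their reported 20.98 ± 10.49 and
  10.21 ± 3.30 μg/kg. Exoskeleton cells have only published medians (back
  38.94, head 35.32 μg/kg); their means are reconstructed assuming a
  lognormal with CV = 0.5 — the abdominal-muscle CV — via
  `mean = median·√(1 + CV²)`, preserving the exoskeleton > muscle >
  hepatopancreas gradient.
- **Group sizes.** 35 cultivated individuals (5 per region) and 14 market
  individuals (3/3/3/3/2 per city), matching the study design; each
  individual contributes one record per applicable tissue.
- **Within-individual dependence.** Abdominal-muscle and whole-crayfish
  concentrations share a Gaussian copula on the log scale with latent
  correlation 0.4, chosen so the raw-scale Pearson correlation lands near
  the reported ≈0.38 at n = 49. Other tissues are conditionally independent
  — no within-individual covariance beyond the muscle–whole pair is
  published, so none is claimed.
- **Censoring.** Values below the configurable LOD are flagged and stored at
  the LOD; downstream statistics substitute LOD/2. Detection in this system
  is 100%, so the machinery is provided but inert at the default
  calibration.

What the generator does **not** emulate: spatial or hydrological structure
(region effects are plain mean shifts), temporal trends, analytical
measurement error, inter-tissue covariance beyond the single latent factor,
and any dependence between concentration and body size. Tests passing on
synthetic data therefore demonstrate the correctness of the statistical
machinery under the assumed data-generating process, not the field validity
of that process.

## Statistical layer

Group summaries report n, mean, SD (n−1 denominator), median (mean of
central order statistics at even n), range and detection frequency. The
two-sample comparison offers the pooled-variance Student test and the Welch
test (Satterthwaite df); Welch is the default because the compared groups
have unequal sizes (35 vs 14) and visibly unequal variances, with the pooled
variant retained for fidelity to classical reporting. No multiple-testing
correction is applied by default (per-comparison α = 0.05), matching
conventional practice for this kind of surveillance table. Skewness
direction is classified by the mean–median relation with a 1e-9 relative
tolerance.

## Sensitivity analysis

The analysis re-runs the simulation capturing per-iteration input draws and
correlates each stochastic input with the EDI: Spearman rank correlation by
default (robust to the model's monotone structure), Pearson, and a
normalised contribution-to-variance (squared rank correlations rescaled to
sum to 1). With concentration-only stochasticity the model is linear in
independent inputs, so the Pearson coefficient has the closed form
`a·σ₁/√(a²σ₁² + b²σ₂²)` ≈ 0.983 for the muscle against 0.18 for the
hepatopancreas — far from the ≈0.39/0.16 magnitudes a fuller stochastic
input set would produce. The package therefore treats only the *ranking*
(muscle > hepatopancreas, for both populations and any method) as the
reproducible finding, not the coefficient magnitudes.

## Numerical choices and degenerate inputs

- Percentiles: linear interpolation, fixed convention.
- A fully degenerate scenario (all point masses) reports SD exactly 0,
  bypassing floating-point summation noise, and collapses to the
  deterministic intake identity.
- Moment matching round-trips are exact to closed form; the truncated-normal
  solve uses a log-scale parameterisation with (mean, log sd) start.
- Scenario validation (positivity, ratio bounds, iteration minimum of 2,
  closed enums for source and tissue) happens at construction via pydantic;
  CSV rows fail with the offending 1-based row number.

## Problem sizes

The default simulation runs 1000 Latin-hypercube iterations — the package's
standard reporting size. Test-suite simulations use 100–200 seeds for
distributional properties (variance reduction, power, ranking robustness)
and n = 10 000 for moment-recovery checks; the full suite completes in a few
seconds.

## Known limitations

- The printed probabilistic EDI summaries of the original assessment
  (adult mean 0.0014, SD 0.0009, P95 0.0029) are not recoverable from any
  single documented combination of the published constants: the per-tissue
  sum gives ≈0.0008 and the hepatopancreas-only single-tissue product
  ≈0.0015. The package reports both modes side by side rather than tuning
  toward either number.
- Only crayfish is modelled; aggregate perchlorate exposure across food
  groups and drinking water is out of scope.
- Variability and uncertainty are not separated (no two-dimensional Monte
  Carlo); the LHS run propagates variability only.
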
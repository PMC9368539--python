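# crayrisk

Probabilistic dietary-exposure and health-risk assessment of perchlorate
(ClO₄⁻) in crayfish, for food-safety scientists and exposure modellers.

Perchlorate is a persistent, highly water-soluble anion that competitively
inhibits thyroidal iodide uptake. Crayfish from the middle and lower Yangtze
basin accumulate it at tens of μg/kg wet weight, more in the exoskeleton than
in the edible tissues. `crayrisk` implements the full assessment chain for
such data: per-sample tissue concentration tables (read from CSV or generated
synthetically with the calibrated generator), descriptive group statistics,
parametric distribution construction, Latin-hypercube Monte Carlo simulation
of intake, and hazard-quotient risk characterisation with a sensitivity
analysis.

## The model

The estimated daily intake for a population with body weight Bw (kg) is

```
EDI = Σ_t  Cs_t · IR_t / (1000 · Bw)        [μg/kg bw/day]
```

summed over the edible tissues t ∈ {abdominal muscle, hepatopancreas}, where
Cs_t is the tissue concentration (μg/kg wet weight, a lognormal random
variable moment-matched to the measured mean ± SD) and IR_t (g/day) is the
tissue intake derived from total crayfish consumption (10.54 g/day) and the
tissue-to-body mass fractions (muscle 20.00%, hepatopancreas 11.96%).
Concentrations are sampled by Latin hypercube: one uniformly jittered draw
per equal-probability stratum, permuted, through the inverse CDF.

Risk is characterised by the hazard quotient `HQ = mean EDI / RfD` with
RfD = 0.7 μg/kg bw/day (HQ > 1 flags potential non-carcinogenic risk) and by
the percentage of iterations whose EDI falls below the EFSA tolerable daily
intake of 0.3 μg/kg bw/day. Adults (70 kg) and children (20 kg) share
identical concentration draws and differ only in body weight.

## Worked example

```python
from crayrisk import ExposureScenario, run_simulation

results = run_simulation(ExposureScenario(seed=1, n_iterations=1000))
for pop, r in results.items():
    print(f"{pop}: mean={r.edi_mean:.6f} sd={r.edi_sd:.6f} "
          f"P95={r.edi_p95:.6f} HQ={r.hq:.5f} TDI-compliance={r.tdi_compliance}%")
```

prints

```
adults: mean=0.000815 sd=0.000322 P95=0.001423 HQ=0.00116 TDI-compliance=100.0%
children: mean=0.002853 sd=0.001126 P95=0.004980 HQ=0.00408 TDI-compliance=100.0%
```

Adults ingest ≈0.0008 μg perchlorate per kg body weight per day through
crayfish on average; children, at the same draws but 3.5× lower body weight,
≈0.0029. Both hazard quotients sit three orders of magnitude below 1, and
every simulated intake falls below the 0.3 μg/kg bw/day tolerable daily
intake — crayfish consumption alone poses no appreciable perchlorate risk
under these conditions.

The same pipeline is scriptable from the shell:

```sh
crayrisk simulate --seed 3 --out concentrations.csv
crayrisk summarize --input concentrations.csv --by source,region
crayrisk assess --seed 1 --out risk.csv --samples-out edi.csv
crayrisk sensitivity --seed 1
```

`assess` accepts `--aggregation {per_tissue_sum,single_tissue}`: the default
sums tissue-specific intakes; the alternative pairs one tissue's
concentration distribution with the total consumption rate. `sensitivity`
ranks the stochastic inputs by rank correlation with the EDI (the abdominal
muscle dominates the hepatopancreas in every run).

Scenario parameters (intake rate, mass fractions, body weights, RfD, TDI,
iteration count, concentration distributions) live in a YAML config passed
via `--config`; absent keys take the defaults above. See
`crayrisk.io.load_scenario` for the key reference.

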
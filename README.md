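# picovir

Infection-kinetics analysis for lytic viruses of marine picophytoplankton.

Quantifying how a dsDNA virus (e.g. a prasinovirus infecting
*Ostreococcus*) interacts with its host in batch culture requires a
chain of estimators that are usually scattered across spreadsheets:
most-probable-number (MPN) titration of infectious virions, DNA-content
cell-cycle gating of flow-cytometry histograms, infected-fraction
inference, latent-period and burst-size estimation from host/virion time
series, and the energetic cost of replicating the viral genome.
`picovir` implements this pipeline as a tested Python package, together
with a stochastic synthetic-experiment generator with known ground truth
so that every stage can be validated end to end without any external
data.

## Core quantities

* **MPN / infectivity / MOI** — infectious titer ĉ maximises the
  Poisson single-hit likelihood over serial-dilution well outcomes,
  `ℓ(c) = Σ p·ln(1 − e^{−c·v·d}) − (n−p)·c·v·d`, with a Wald 95% CI on
  log c; infectivity = ĉ / total virions; MOI = virus:host ratio ×
  infectivity.
* **Cell cycle / infected fraction** — G1 gate at the modal KDE peak of
  log fluorescence (G2/M sits at exactly 2× G1);
  `F_I = max(F^>G1 − F^D_C · s, 0)` with `s = clamp(n_I/n_C, 0, 1)` the
  relative generations since dawn.
* **Kinetics** — `n_t = (ln N_t − ln N_i)/ln 2`, `μ = ln(N_t/N_i)/Δt`,
  `VP = N_t/N_i`; latent period as the first sampling interval with
  virion log2FC significantly > 0; burst size `ΔV/(−ΔH)` over the
  18.5–24.5 h window; LL:SL production ratios with Welch tests; one-way
  ANOVA (Type II SS) + Tukey per timepoint.
* **Energetics** — `E_rep = 2·L_g·(e_d + e_p)` ATP-equivalents per dsDNA
  genome (defaults e_d = 11, e_p = 2 per nucleotide).

Fit-shaped estimators (`MPNEstimator`, `G1Gater`,
`LatentPeriodEstimator`, `BurstSizeEstimator`) follow scikit-learn
conventions (`fit`, `get_params`, fitted attributes with trailing
underscores) and compose with sklearn tooling; module-level functions
wrap them.

## Worked example

Run a full synthetic experiment (standard-light conditions, MOI ≈ 3,
latent period 7 h, burst 500, 3 replicates, 8% count noise) and analyse
it:

```python
from picovir import pipeline, simulate

cfg = pipeline.RunConfig(out_dir="demo", seed=1,
                         sim=simulate.SimConfig(seed=1),
                         genome_length=200_000, genome_length_b=188_000)
summary = pipeline.run(cfg)
```

`demo/metrics_summary.json` from this exact run (abridged):

```json
{
  "infectivity": {"fraction": 0.3997, "ci95": [0.236, 0.677]},
  "moi": {"value": 3.7, "ci95": [2.2, 6.3]},
  "growth_rate_per_day": {"control_SL": {"mean": 0.836, "sd": 0.100},
                          "virus_SL":   {"mean": -1.120, "sd": 0.073}},
  "latent_interval_h": {"virus_SL": {"t_low": 6.5, "t_high": 8.5}},
  "burst_size": {"virus_SL": {"mean": 491.9, "sd": 406.9}},
  "energetics": {"cost_difference_atp": 312000}
}
```

Reading the numbers: the MPN assay estimated 40% of virions infectious
(truth 32%; the CI covers it), giving MOI 3.7 (truth 3.0).  The control
culture grew at 0.84 d⁻¹ (truth 0.76) while the infected culture lost
cells at −1.1 d⁻¹.  The free-virion log2 fold change first became
significantly positive in the (6.5, 8.5] h sampling interval,
bracketing the true 7 h latent period, and the burst estimate of 492
virions per lysed cell recovers the true 500 (the large SD across
3 replicates mirrors the noise sensitivity of this ratio estimator).
Replicating a 12 kb larger genome costs 312,000 additional
ATP-equivalents.  `demo/recovery_report.json` tabulates these
estimate-vs-truth comparisons.

The same stages are exposed on the command line:

```bash
picovir simulate --out demo_sim --seed 1
picovir mpn --wells demo_sim/mpn_wells.csv --total-virions 3e7 --host-density 3.2e6
picovir cellcycle --events-dir demo_sim/flow_events --abundance demo_sim/abundance.csv --out cellcycle.csv
picovir kinetics --abundance demo_sim/abundance.csv --out kinetics.csv --summary summary.json
picovir energetics --length 200000 --length-b 188000
picovir run --config run.yaml
```

## Layout

```
src/picovir/
  simulate.py    stochastic batch-culture experiment generator
  mpn.py         MPN MLE, infectivity, MOI
  cellcycle.py   G1 gating, infected-fraction correction
  kinetics.py    fold changes, growth, latent period, burst, statistics
  energetics.py  dsDNA replication cost
  pipeline.py    orchestration and report bundle
  cli.py         `picovir` command group
docs/methods.md  model and estimator documentation
```
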
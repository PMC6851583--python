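# Methods

`picovir` analyses batch-culture infection experiments in which a lytic
dsDNA virus (a prasinovirus-like phycodnavirus) is added to a
diel-synchronised picophytoplankton host (*Ostreococcus*-like) at a
target multiplicity of infection, and host cells, free virions and
per-cell DNA content are followed by flow cytometry over ~28 h.  This
note documents the models, estimators, defaults and their limitations.

## MPN titration (`picovir.mpn`)

A serial-dilution endpoint assay scores `n` wells per dilution `d` as
lysed/not lysed after inoculating volume `v` (mL) of diluted virus
concentrate into growing host culture.  Under the Poisson single-hit
model the positive probability is `1 − exp(−c·v·d)`, and the infectious
titer `c` is estimated by maximising

    ℓ(c) = Σ_levels [ p·ln(1 − e^{−c·v·d}) − (n − p)·c·v·d ].

All levels, including all-positive and all-negative ones, are retained
in the likelihood (they are informative).  The 95% CI is a Wald interval
on `log c` using the observed Fisher information (numerical second
derivative), exponentiated.  With all wells negative the estimate is
censored at 0 with a one-sided upper bound from
`P(all negative | c) = 0.05`; with all wells positive it is censored at
+∞ with the analogous lower bound.  An optional second-order correction
(`bias_correction=True`) divides the MLE by `exp(SE_log²/2)`,
counteracting the upward bias of the endpoint-dilution MLE on the
concentration scale; it is off by default so that the default estimator
is the standard one.  A brute-force likelihood grid search serves as the
independent oracle in the tests; simulated-assay studies in the test
suite check that the 95% CI covers the generating titer at close to
nominal rate for 24-well, 8-dilution assays across titers 10⁶–10¹⁰ mL⁻¹.

Infectivity is the MPN titer divided by the total (stain-counted) virion
concentration; MOI is the total virus:host ratio times infectivity, with
CI bounds scaled identically and reported at two significant figures.

## Cell-cycle gating and infected fraction (`picovir.cellcycle`)

DNA-stain histograms of intact host cells show a G1 peak and a G2/M peak
at exactly twice its fluorescence.  The G1 mode is located as the modal
peak of a Gaussian KDE of log fluorescence (Silverman bandwidth — a
standard, scale-free choice).  The G1 gate spans
`[g1_mode/√2, g1_mode·√2)`: the upper edge lies halfway (in log space)
to the 2× peak.  The published procedure specifies only the peak rule,
so the √2 edge is an explicit, configurable stand-in.  Events below
`g1_mode/2` are treated as sub-cellular debris and excluded — an
approximation to the upstream chlorophyll/scatter gating that this
package does not reimplement (tabular event lists carry no scatter
channels).  Gates are learned on non-infected control samples and
applied to infected samples of the same timepoint, which may have no
recognisable G1 peak of their own.  A warning (not an error) is raised
when ≥5% of events sit above the gate but no secondary mode is found at
1.8–2.2× the G1 mode; early in the light phase this is expected, because
S-phase cells accumulate hours before any cell reaches G2.

The fraction of infected cells corrects the above-G1 fraction for
dividing cells:

    F_I = max(F^>G1 − F^D, 0),   F^D = F^D_C · s,   s = clamp(n_I/n_C, 0, 1)

with `F^D_C` the mean above-G1 fraction of the control replicates and
`n_I`, `n_C` generations since dawn of the infected and control
cultures.  When `n_C = 0` exactly, `s` is defined as 1 if `n_I ≥ 0` else
0, and the result is flagged.

The ratio `n_I/n_C` is statistically fragile early in the experiment:
the control has completed only ~0.1 generations while its dividing
fraction is already near its maximum, so count noise in the denominator
makes the raw pointwise ratio essentially unidentifiable there.  The
pipeline therefore estimates `s` adaptively: generations come from the
replicate-mean host series smoothed with a Gaussian kernel (default
bandwidth 2 h), and the ratio is applied only when the treated culture's
growth deficit is resolvable (one-sided Welch test on the per-replicate
generations, default p < 0.01); otherwise equal growth (s = 1) is
assumed — the exact identity for non-infected cultures.  A stabiliser of
0.5 generations is added to numerator and denominator when the ratio is
used.  All three knobs are parameters of `analyze_cellcycle`; setting
bandwidth and stabiliser to 0 and the threshold to 1 recovers the raw
pointwise rule, which `cellcycle.infected_fraction` itself implements
unchanged.  With the adaptive default, simulated no-infection
experiments show a mean spurious infected fraction below 2% at every
timepoint, while the peak infected fraction of a simulated high-MOI
infection is recovered within a few percentage points.

## Population kinetics (`picovir.kinetics`)

* log2 fold change `n_t = (ln N_t − ln N_i)/ln 2`, with reference dawn
  (−3.5 h) for hosts and the first post-inoculation sample (0.5 h) for
  virions; viral production `VP = N_t/N_i = 2^{n_t}` exactly.
* Growth rate `μ = ln(N_t/N_i)/Δt` in d⁻¹; negative values are net
  mortality.
* Latent period: the earliest sampling interval `(t_prev, t_sig]` at
  which the replicate virion log2 fold changes are significantly greater
  than zero (one-sample t-test, default two-sided α = 0.05 with a
  required positive mean, since release is directional; a one-sided
  option exists).  Identical all-positive replicates (zero variance) are
  treated as attested increases; all-zero replicates as no evidence.
* Burst size per replicate `b = (V(t₂) − V(t₁))/(H(t₁) − H(t₂))` over a
  late window (default 18.5–24.5 h) in which lysis dominates host loss;
  replicates with net host gain are excluded with a warning (the
  estimator is undefined for them), a documented choice where the
  original analysis is silent.  The estimator is unit-invariant and, on
  noise-free one-step simulations with fixed burst, exact.  Under
  reinfection it is only approximately unbiased (progeny adsorbed within
  the window are lost from the numerator).
* Light-sensitivity of production: `mean(VP_LL)/mean(VP_SL)` per
  timepoint after first release (default 8.5 h), SE by first-order error
  propagation of the two independent replicate means (flasks are not
  paired across light conditions), Welch's t-test for the contrast.  A
  ratio of 1 means production is insensitive to the growth condition.
* Statistical protocol: per-timepoint one-way ANOVA with Type II sums of
  squares (statsmodels) followed by Tukey-adjusted pairwise comparisons,
  plus Welch's two-sample t-tests for two-group contrasts; α = 0.05.
  P-values are reported per timepoint without multiplicity correction
  (a Holm option exists in spirit via the returned tidy table).  Zero
  within-group variance everywhere yields flagged NaN p-values.

## Replication energetics (`picovir.energetics`)

The direct cost of synthesising one dsDNA genome is
`E = 2·L_g·(e_d + e_p)` ATP-equivalents, with `L_g` the single-strand
length in bases (the factor 2 carries double-strandedness — kept
explicit to prevent a silent 2× error), `e_d = 11` ATP-equivalents per
nucleotide for precursor synthesis and `e_p = 2` for chain elongation.
Cost differences depend only on the length difference; arithmetic is
exact for integer inputs.  Transcription, translation and opportunity
costs are out of scope.

## Synthetic experiment generator (`picovir.simulate`)

A hybrid deterministic–stochastic, discrete-time (tau-leap, dt = 0.05 h)
model.  Concentrations are continuous densities — at ~10⁶ cells mL⁻¹
demographic noise is negligible and agent-based simulation unnecessary —
while burst sizes (per lysing cohort, Gamma with CV 0.3) and MPN well
outcomes (binomial) are stochastic, and measurement noise is
multiplicative lognormal (CV 8%, chosen to reproduce the replicate
scatter of the emulated experiment's growth curves) drawn independently
per replicate observation.  Everything is deterministic given the
configuration, including its seed.

State: susceptible cells S (plus a refractory pool), infected cells
binned by infection age at dt resolution, and free virions split into
infectious and non-infectious pools (equal adsorption kinetics for both,
since infectivity assays cannot distinguish them).  Update order per
step: adsorption/infection, aging, lysis with burst release, diel
division.

* **Infection.**  Per-cell hazard `λ = min(k_ads·V_inf, λ_max)` with
  `k_ads = 1.8×10⁻⁸ mL h⁻¹` and `λ_max = 0.35 h⁻¹`.  The cap is a
  receptor/handling saturation: without it, once progeny dominate the
  virion pool the whole culture is infected within a fraction of one
  latent period, which contradicts the progressive multi-wave host
  decline the emulated experiment shows.  Each infection consumes one
  infectious virion; non-infectious virions adsorb to susceptible cells
  at per-virion rate `k_ads·S`.
* **Refractory pool.**  10% of host cells never acquire infection
  (`susceptible_fraction = 0.9`), a standard representation of
  heterogeneous permissiveness.  It is what makes the infected fraction
  peak mid-infection and then decline, and leaves a surviving host
  population at the end, both features of the emulated data.
* **Latency and burst.**  Fixed latent period (default 7 h); the cohort
  reaching it lyses, releasing `burst_mean = 500` progeny per cell on
  average, which re-enter the free pool (reinfection on by default —
  the emulated design performs no post-adsorption dilution).  With
  `reinfection=False` progeny are inert and the remaining free inoculum
  is removed at `adsorption_stop_h` (default 0.5 h), emulating a
  classical one-step design.
* **Diel division.**  Cells commit to division during a window 6–14 h
  after lights-on (dawn at −3.5 h, 14:10 photoperiod), transit S for 2 h
  and G2+M for 1.5 h, then double.  The in-window hazard is calibrated
  so that the growth rate *measured the way batch experiments measure
  it* — `ln(N_end/N_start)` over the full −3.5 → 24.5 h window — equals
  `mu_max` (0.76 d⁻¹ standard light; 0.091 d⁻¹ limited light).  With a
  window spanning all 24 h this reduces to exact continuous exponential
  growth.  Phase occupancies of uninfected cells are computed
  kinematically from the commit hazard and transit times; infected cells
  arrest immediately (or after a configurable delay, for the
  late-arrest phenotype) and their DNA content is
  `1 + genome_ratio·burst_mean·min(age/latent, 1)` host-genome units
  (viral genomes ~1.5% of the host genome, ramping to the burst size).
* **Defaults as study conditions.**  Host at 3.2×10⁶ cells mL⁻¹,
  inoculum sized for MOI 3 at 32% infectivity, sampling at
  {−3.5, 0.5, 2.5, …, 14.5, 18.5, 24.5} h, 3 replicates, 5000 flow
  events per sample, 24-well MPN assays with 8 ten-fold dilutions from
  10⁻³ at 0.05 mL per well.  `k_ads`, `λ_max` and the refractory
  fraction were set jointly so that the noiseless trajectory reproduces
  the emulated experiment's qualitative anchors: free-virion dip of
  ~−0.4 log2 before first release, first significant virion increase in
  the (6.5, 8.5] h interval, infected fraction peaking at ~0.6 within
  6.5–10.5 h, ~50-fold virion production and ~75% host loss by 24.5 h
  with lysis continuing through the 18.5–24.5 h burst window.

Mass balance holds to machine precision at every step: hosts satisfy
`S + I = N₀ + divisions − lysed`, virions satisfy
`V = added + bursts − infections − adsorbed − diluted`.

What the generator does *not* emulate: virion decay (negligible on this
timescale), nutrient limitation, intracellular gene expression, spatial
structure, light-dependent adsorption, instrument-specific flow
artefacts (doublets, carryover) and scatter-channel gating.  Passing
tests therefore show that the estimators recover known parameters under
realistic noise and reinfection — not that they are robust to every
failure mode of real cytometry data.

## Numerical choices and degenerate inputs

Sampling times must lie on the dt grid (enforced).  Tau-leap
preconditions (`k_ads·N₀·dt < 0.5`, per-step division probability small)
are validated at configuration time; state updates use
exponential-fraction removals so negative state is impossible without
clamping.  The MPN optimiser brackets the MLE with a coarse grid before
bounded Brent refinement; KDE gating requires ≥100 events and fails
loudly otherwise.  Ties and degenerate statistics (zero-variance groups,
all-censored assays, zero reference counts) are flagged rather than
silently propagated.

## Problem sizes

Default analyses run in seconds: one simulated experiment is ~600 steps;
Monte-Carlo calibration studies in the tests use 50–200 seeds for scalar
recoveries, 500 assays for CI coverage, and 5–6 seeded experiments for
flow-cytometry-based recoveries — sizes at which the binomial/seed noise
of each check is comfortably below its acceptance margin.
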
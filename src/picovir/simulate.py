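"""Stochastic batch-culture simulator of a lytic infection experiment.

The generator emulates the standard design for characterising infection
of a diel-synchronised picophytoplankton host in batch culture: host
cells grow exponentially with division confined to a window of the light
phase; a virus inoculum is added at t = 0 at a target multiplicity of
infection; virions adsorb to susceptible cells, replicate intracellularly
for a fixed latent period and lyse the host, releasing a burst of progeny
that can reinfect (no post-adsorption dilution).  The simulator produces
every input of the analysis pipeline — host/virion abundance time series
with replicate measurement noise, per-cell DNA-stain fluorescence event
tables, and serial-dilution MPN well outcomes — together with the ground
truth used to generate them.

Modelling choices (hybrid deterministic–stochastic tau-leaping):

* concentrations are continuous densities (populations of ~10^6 mL^-1
  make agent-based simulation unnecessary); updates use discrete-time
  tau-leap steps of ``dt`` hours (default 0.05 h);
* only burst sizes (per lysing cohort) and MPN well outcomes are drawn
  stochastically inside the dynamics; measurement noise is multiplicative
  lognormal applied per replicate observation;
* infected cells are tracked by infection age in bins of ``dt``; a cohort
  lyses when its age reaches the latent period;
* the per-cell infection hazard is ``k_ads * V_infectious`` capped at
  ``infection_rate_cap`` — a receptor/handling saturation that keeps the
  epidemic progressive (host lysis continuing into the final sampling
  window) instead of collapsing within one latent period once progeny
  dominate;
* a fraction ``1 - susceptible_fraction`` of host cells is refractory
  (never infected, keeps dividing) — heterogeneous permissiveness is what
  makes the infected fraction peak mid-infection and then decline as
  infected cells lyse out while the refractory pool persists;
* division is a diel pulse: cells commit to division during a fixed
  window after lights-on and complete it a fixed S+G2/M transit later;
  the in-window hazard is calibrated so that the specific growth rate
  measured over the experiment interval equals ``mu_max``.

Everything is deterministic given the configuration (including its seed).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellcycle import FlowSample
from .mpn import DilutionAssay

__all__ = [
    "SimConfig",
    "SimState",
    "SimResult",
    "GroundTruth",
    "SimConfigError",
    "step",
    "initial_state",
    "run_experiment",
    "emit_flow_sample",
    "simulate_mpn_assay",
    "susceptible_phase_fractions",
    "SAMPLE_TIMES_DEFAULT",
]

#: Default sampling grid (h relative to virus addition): every 2 h for the
#: first 14 h, then 18 and 24 h, plus the dawn baseline at -3.5 h.
SAMPLE_TIMES_DEFAULT = (-3.5, 0.5, 2.5, 4.5, 6.5, 8.5, 10.5, 12.5, 14.5, 18.5, 24.5)


class SimConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass
class SimConfig:
    """Full parameterisation of one simulated infection experiment.

    Times are hours relative to virus addition (t = 0); dawn (lights-on)
    is at -3.5 h and the photoperiod is 14:10 light:dark.  Defaults are
    the standard-light (SL) conditions of the experiment the simulator
    emulates: host at 3.2e6 cells mL^-1 growing at 0.76 d^-1, inoculum
    sized for a multiplicity of infection of ~3 infectious virions per
    cell at 32% infectivity, a ~7 h latent period and a burst of ~500
    progeny per cell.  The limited-light (LL) condition differs in
    ``mu_max`` (0.091 d^-1).
    """

    seed: int = 0
    dt: float = 0.05                       # h
    t_start: float = -3.5                  # h (dawn baseline sample)
    t_end: float = 24.5                    # h
    lights_on: float = -3.5                # dawn, h
    photoperiod: tuple = (14.0, 10.0)      # light, dark (h)
    mu_max: float = 0.76                   # host growth rate, d^-1
    division_window: tuple = (6.0, 14.0)   # h after lights-on
    tau_s: float = 2.0                     # S-phase transit (h)
    tau_g2m: float = 1.5                   # G2+M transit (h)
    n0_host: float = 3.2e6                 # cells mL^-1
    v0: float = 3.0e7                      # total virions mL^-1 added at t=0
    infectivity_true: float = 0.32         # infectious fraction of virions
    susceptible_fraction: float = 0.9      # permissive fraction of host cells
    k_ads: float = 1.8e-8                  # adsorption rate, mL virion^-1 h^-1
    infection_rate_cap: float = 0.35       # max per-cell infection hazard, h^-1
    latent_period_true: float = 7.0        # h
    burst_mean: float = 500.0              # progeny per lysed cell
    burst_cv: float = 0.3
    arrest_mode: str = "immediate"         # "immediate" | "delayed"
    arrest_delay: float = 6.0              # h, used when arrest_mode="delayed"
    genome_ratio: float = 0.015            # viral / host genome length
    reinfection: bool = True
    adsorption_stop_h: float = 0.5         # one-step mode: inoculum removed here
    noise_cv_counts: float = 0.08          # lognormal CV of count measurements
    n_replicates: int = 3
    events_per_sample: int = 5000
    fluor_cv: float = 0.10                 # per-cell fluorescence CV
    light_label: str = "SL"
    sample_times: tuple = SAMPLE_TIMES_DEFAULT

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dt <= 0:
            raise SimConfigError("dt must be positive")
        if not (0.0 <= self.infectivity_true <= 1.0):
            raise SimConfigError("infectivity_true must be in [0, 1]")
        if not (0.0 < self.susceptible_fraction <= 1.0):
            raise SimConfigError("susceptible_fraction must be in (0, 1]")
        if self.burst_mean <= 0:
            raise SimConfigError("burst_mean must be positive")
        if self.burst_cv < 0:
            raise SimConfigError("burst_cv must be non-negative")
        if self.latent_period_true <= 0:
            raise SimConfigError("latent_period_true must be positive")
        if not (self.t_start < 0.0 < self.t_end):
            raise SimConfigError("need t_start < 0 < t_end (virus added at t = 0)")
        if self.n0_host <= 0:
            raise SimConfigError("n0_host must be positive")
        if self.v0 < 0:
            raise SimConfigError("v0 must be non-negative")
        if self.k_ads < 0 or self.mu_max < 0 or self.noise_cv_counts < 0:
            raise SimConfigError("rates and noise CV must be non-negative")
        w0, w1 = self.division_window
        if not (0.0 <= w0 < w1 <= 24.0):
            raise SimConfigError("division_window must satisfy 0 <= start < end <= 24")
        if self.arrest_mode not in ("immediate", "delayed"):
            raise SimConfigError("arrest_mode must be 'immediate' or 'delayed'")
        # tau-leap preconditions: per-step adsorption and division
        # probabilities must be small
        if self.k_ads * self.n0_host * self.dt >= 0.5:
            raise SimConfigError("dt too large: k_ads * N0 * dt must be < 0.5")
        if self.mu_max / 24.0 * self.dt >= 0.5:
            raise SimConfigError("dt too large for the configured growth rate")

    # -- diel machinery ----------------------------------------------------

    def _window_measure(self, t0: float, t1: float, shift: float = 0.0) -> float:
        """Hours of (t0, t1] inside the daily division windows shifted by ``shift``."""
        if t1 <= t0:
            return 0.0
        w0, w1 = self.division_window
        a0 = self.lights_on + w0 + shift
        a1 = self.lights_on + w1 + shift
        total = 0.0
        k_lo = math.floor((t0 - a1) / 24.0)
        k_hi = math.ceil((t1 - a0) / 24.0)
        for k in range(k_lo, k_hi + 1):
            total += max(0.0, min(t1, a1 + 24 * k) - max(t0, a0 + 24 * k))
        return total

    @property
    def _transit(self) -> float:
        return self.tau_s + self.tau_g2m

    def commit_hours(self, t0: float, t1: float) -> float:
        """Hours of (t0, t1] in which cells commit to division (enter S)."""
        return self._window_measure(t0, t1)

    def completion_hours(self, t0: float, t1: float) -> float:
        """Hours of (t0, t1] in which committed cells complete division."""
        return self._window_measure(t0, t1, shift=self._transit)

    @property
    def division_hazard(self) -> float:
        """In-window division hazard (h^-1).

        Calibrated so that the specific growth rate measured over the
        experiment interval (t_start to t_end, the way batch-culture
        growth rates are measured) equals ``mu_max``.  With a division
        window spanning all 24 h this reduces to continuous exponential
        growth at ``mu_max / 24`` per hour.
        """
        target = self.mu_max * (self.t_end - self.t_start) / 24.0
        hours = self.completion_hours(self.t_start, self.t_end)
        if hours == 0.0:
            if self.mu_max > 0:
                warnings.warn("no division-completion hours fall inside the "
                              "experiment; growth is disabled", stacklevel=2)
            return 0.0
        return target / hours

    @property
    def n_age_bins(self) -> int:
        return max(1, math.ceil(self.latent_period_true / self.dt))


def susceptible_phase_fractions(t: float, config: SimConfig) -> tuple:
    """(f_G1, f_S, f_G2M) of uninfected cells at clock time ``t``.

    Cells commit to division at the in-window hazard and transit S for
    ``tau_s`` h then G2+M for ``tau_g2m`` h, so the S (G2M) occupancy is
    the commit hazard integrated over the trailing transit window.  A
    first-order kinematic approximation, adequate for the small per-day
    committed fractions of a once-daily divider.
    """
    r = config.division_hazard
    f_s = r * config.commit_hours(t - config.tau_s, t)
    f_g2m = r * config.commit_hours(t - config.tau_s - config.tau_g2m, t - config.tau_s)
    total = f_s + f_g2m
    if total > 0.95:  # keep fractions valid for extreme configurations
        f_s, f_g2m = 0.95 * f_s / total, 0.95 * f_g2m / total
    return (1.0 - f_s - f_g2m, f_s, f_g2m)


@dataclass
class SimState:
    """Evolving state of the culture (concentrations per mL).

    ``i_ages[k]`` holds infected cells whose infection age is ``(k+1)*dt``
    at the end of the current step; the oldest bin lyses on aging past
    the latent period.  Cumulative tallies make mass balance checkable:
    hosts: S + sum(I) = N0 + divisions - lysed;
    virions: V pools = added + bursts - infections - adsorbed_noninf - diluted.
    """

    t: float
    s: float
    i_ages: np.ndarray
    s_r: float = 0.0           # refractory (uninfectable) host cells
    v_inf: float = 0.0
    v_non: float = 0.0
    v_prog: float = 0.0        # progeny pool when reinfection is disabled
    cum_divisions: float = 0.0
    cum_lysed: float = 0.0
    cum_bursts: float = 0.0    # virions released
    cum_infections: float = 0.0
    cum_adsorbed_non: float = 0.0
    cum_diluted: float = 0.0
    v_added: float = 0.0

    @property
    def i_total(self) -> float:
        return float(self.i_ages.sum())

    @property
    def host_total(self) -> float:
        return self.s + self.s_r + self.i_total

    @property
    def v_total(self) -> float:
        return self.v_inf + self.v_non + self.v_prog

    def copy(self) -> "SimState":
        return dataclasses.replace(self, i_ages=self.i_ages.copy())


def initial_state(config: SimConfig) -> SimState:
    return SimState(t=config.t_start,
                    s=config.n0_host * config.susceptible_fraction,
                    s_r=config.n0_host * (1.0 - config.susceptible_fraction),
                    i_ages=np.zeros(config.n_age_bins))


def add_inoculum(state: SimState, config: SimConfig, v0: float) -> None:
    """Add the virus inoculum (in place) at the current time."""
    state.v_inf += v0 * config.infectivity_true
    state.v_non += v0 * (1.0 - config.infectivity_true)
    state.v_added += v0


def step(state: SimState, config: SimConfig, rng: np.random.Generator) -> SimState:
    """Advance the culture by one tau-leap step of ``dt`` hours.

    Update order: adsorption/infection, infected aging, lysis with burst
    release, diel division.  Negative state is impossible by construction
    (all removals are exponential-fraction or donor-limited).
    """
    st = state.copy()
    dt = config.dt
    t0, t1 = st.t, st.t + dt

    # (1) adsorption: per-cell infection hazard capped by receptor handling
    if st.v_inf > 0 and st.s > 0:
        lam = min(config.k_ads * st.v_inf, config.infection_rate_cap)
        new_i = st.s * -math.expm1(-lam * dt)
        new_i = min(new_i, st.v_inf)  # one virion consumed per infection
        st.s -= new_i
        st.v_inf -= new_i
        st.cum_infections += new_i
    else:
        new_i = 0.0
    if st.v_non > 0 and st.s > 0:
        dv = st.v_non * -math.expm1(-config.k_ads * st.s * dt)
        st.v_non -= dv
        st.cum_adsorbed_non += dv
    # one-step mode: remaining free inoculum is diluted away after the
    # adsorption phase
    if not config.reinfection and t0 < config.adsorption_stop_h <= t1:
        st.cum_diluted += st.v_inf + st.v_non
        st.v_inf = 0.0
        st.v_non = 0.0

    # (2) aging and (3) lysis of the cohort reaching the latent period
    lysing = float(st.i_ages[-1])
    st.i_ages[1:] = st.i_ages[:-1]
    st.i_ages[0] = new_i
    if lysing > 0:
        if config.burst_cv > 0:
            shape = 1.0 / config.burst_cv**2
            burst = rng.gamma(shape, config.burst_mean / shape)
        else:
            burst = config.burst_mean
        released = lysing * burst
        st.cum_lysed += lysing
        st.cum_bursts += released
        if config.reinfection:
            st.v_inf += released * config.infectivity_true
            st.v_non += released * (1.0 - config.infectivity_true)
        else:
            st.v_prog += released

    # (4) diel division: uninfected cells (and pre-arrest infected cells
    # under delayed arrest) complete division inside the completion window
    hours = config.completion_hours(t0, t1)
    if hours > 0:
        g = math.exp(config.division_hazard * hours)
        st.cum_divisions += (st.s + st.s_r) * (g - 1.0)
        st.s *= g
        st.s_r *= g
        if config.arrest_mode == "delayed":
            ages = (np.arange(config.n_age_bins) + 1) * dt
            pre = ages < config.arrest_delay
            st.cum_divisions += float(st.i_ages[pre].sum()) * (g - 1.0)
            st.i_ages[pre] *= g

    st.t = t1
    return st


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters and noiseless targets for recovery checks."""

    infectivity_true: float
    latent_period_true: float
    burst_mean: float
    burst_cv: float
    mu_max: float
    moi: float
    n0_host: float
    v0: float
    light: str
    infected_fraction: pd.DataFrame  # columns: time_h, f_infected


@dataclass
class SimResult:
    """Everything one simulated experiment produces."""

    config: SimConfig
    abundance: pd.DataFrame   # treatment, light, replicate, time_h, target, value_per_ml
    latent: pd.DataFrame      # noiseless: treatment, light, time_h, target, value_per_ml
    flow_samples: list
    ground_truth: GroundTruth


def emit_flow_sample(state: SimState, config: SimConfig,
                     rng: np.random.Generator, sample_id: str = "sample",
                     treatment: str = "virus", replicate: int = 1) -> FlowSample:
    """Draw a per-cell DNA-fluorescence event table from the current state.

    Events are drawn multinomially in proportion to class abundance.
    Fluorescence is in host-genome units: G1 = 1, S uniform in (1, 2),
    G2/M = 2; an infected cell of age ``a`` carries
    ``1 + genome_ratio * burst_mean * min(a / latent_period, 1)``
    (viral genome copies ramping linearly to the burst size over the
    latent period).  Each event is multiplied by mean-1 lognormal noise
    with CV ``fluor_cv``, so the G1 mode sits at half the G2/M mode in
    expectation.
    """
    if state.host_total <= 0:
        raise ValueError("no cells to sample")
    n_events = config.events_per_sample
    if n_events < 100:
        warnings.warn("fewer than 100 events per sample: histogram gating "
                      "will be unreliable", stacklevel=2)
    f_g1, f_s, f_g2m = susceptible_phase_fractions(state.t, config)
    uninf = state.s + state.s_r
    weights = np.concatenate(
        [[uninf * f_g1, uninf * f_s, uninf * f_g2m], state.i_ages]
    )
    probs = weights / weights.sum()
    counts = rng.multinomial(n_events, probs)
    n_g1, n_s, n_g2m = counts[:3]
    parts = [np.ones(n_g1), rng.uniform(1.0, 2.0, n_s), np.full(n_g2m, 2.0)]
    ages = (np.arange(config.n_age_bins) + 1) * config.dt
    dna_infected = 1.0 + config.genome_ratio * config.burst_mean * np.minimum(
        ages / config.latent_period_true, 1.0
    )
    for k, c in enumerate(counts[3:]):
        if c:
            parts.append(np.full(c, dna_infected[k]))
    fluor = np.concatenate(parts)
    if config.fluor_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.fluor_cv**2))
        fluor = fluor * rng.lognormal(-sigma**2 / 2.0, sigma, fluor.size)
    return FlowSample(
        sample_id=sample_id,
        treatment=treatment,
        light=config.light_label,
        replicate=replicate,
        time_h=state.t,
        fluorescence=fluor,
    )


def _run_arm(config: SimConfig, v0: float, rng: np.random.Generator) -> dict:
    """Simulate one arm (a treatment) and snapshot at the sampling times."""
    n_steps = round((config.t_end - config.t_start) / config.dt)
    grid = config.t_start + config.dt * np.arange(n_steps + 1)
    sample_times = np.asarray(config.sample_times, dtype=float)
    tol = config.dt / 2.0

    state = initial_state(config)
    if abs(config.t_start) <= tol and v0 > 0:  # pragma: no cover
        add_inoculum(state, config, v0)
    snapshots = {}

    def maybe_snapshot(s: SimState) -> None:
        hit = sample_times[np.abs(sample_times - s.t) <= tol]
        if hit.size:
            snap = s.copy()
            snap.t = float(hit[0])  # pin to the exact sampling time
            snapshots[snap.t] = snap

    maybe_snapshot(state)
    added = False
    for k in range(n_steps):
        if not added and v0 > 0 and abs(grid[k]) <= tol:
            add_inoculum(state, config, v0)
            added = True
        state = step(state, config, rng)
        maybe_snapshot(state)
    missing = [t for t in sample_times if t not in snapshots]
    if missing:
        raise SimConfigError(f"sampling times {missing} do not lie on the dt grid "
                             f"inside (t_start, t_end]")
    return {"snapshots": snapshots, "final": state}


def run_experiment(config: SimConfig, include_control: bool = True,
                   emit_flow: bool = True) -> SimResult:
    """Simulate a virus treatment (plus a non-infected control) end to end.

    Returns noiseless latent trajectories, noisy observed series
    (``n_replicates`` independent lognormal measurement-noise draws per
    treatment), per-sample flow-event tables and the ground truth.
    Deterministic given ``config`` (including its seed).
    """
    ss = np.random.SeedSequence(config.seed)
    keys = ["virus_traj", "control_traj", "virus_noise", "control_noise",
            "virus_flow", "control_flow"]
    rngs = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))

    arms = {"virus": _run_arm(config, config.v0, rngs["virus_traj"])}
    if include_control:
        arms["control"] = _run_arm(config, 0.0, rngs["control_traj"])

    sample_times = [float(t) for t in config.sample_times]
    sigma = (math.sqrt(math.log(1.0 + config.noise_cv_counts**2))
             if config.noise_cv_counts > 0 else 0.0)

    latent_rows, obs_rows, flow_samples = [], [], []
    for treatment, arm in arms.items():
        snaps = arm["snapshots"]
        for t in sample_times:
            snap = snaps[t]
            targets = {"host": snap.host_total}
            if treatment == "virus" and t >= 0:
                targets["virus"] = snap.v_total
            for target, value in targets.items():
                latent_rows.append((treatment, config.light_label, t, target, value))
        noise_rng = rngs[f"{treatment}_noise"]
        for rep in range(1, config.n_replicates + 1):
            for treatment_, light_, t, target, value in latent_rows:
                if treatment_ != treatment:
                    continue
                factor = (noise_rng.lognormal(-sigma**2 / 2.0, sigma)
                          if sigma > 0 else 1.0)
                obs_rows.append((treatment, config.light_label, rep, t, target,
                                 value * factor))
        if emit_flow:
            flow_rng = rngs[f"{treatment}_flow"]
            for rep in range(1, config.n_replicates + 1):
                for t in sample_times:
                    snap = snaps[t]
                    if snap.host_total <= 0:
                        continue
                    flow_samples.append(emit_flow_sample(
                        snap, config, flow_rng,
                        sample_id=f"{treatment}_{config.light_label}_r{rep}_t{t:+05.1f}",
                        treatment=treatment, replicate=rep,
                    ))

    latent = pd.DataFrame(
        latent_rows, columns=["treatment", "light", "time_h", "target", "value_per_ml"]
    )
    abundance = pd.DataFrame(
        obs_rows,
        columns=["treatment", "light", "replicate", "time_h", "target", "value_per_ml"],
    )
    virus_snaps = arms["virus"]["snapshots"]
    truth_frac = pd.DataFrame({
        "time_h": sample_times,
        "f_infected": [
            (virus_snaps[t].i_total / virus_snaps[t].host_total
             if virus_snaps[t].host_total > 0 else 0.0)
            for t in sample_times
        ],
    })
    truth = GroundTruth(
        infectivity_true=config.infectivity_true,
        latent_period_true=config.latent_period_true,
        burst_mean=config.burst_mean,
        burst_cv=config.burst_cv,
        mu_max=config.mu_max,
        moi=config.v0 * config.infectivity_true / config.n0_host,
        n0_host=config.n0_host,
        v0=config.v0,
        light=config.light_label,
        infected_fraction=truth_frac,
    )
    return SimResult(config=config, abundance=abundance, latent=latent,
                     flow_samples=flow_samples, ground_truth=truth)


def simulate_mpn_assay(titer_infectious: float, dilutions, wells: int,
                       inoculum_volume_ml: float,
                       rng: np.random.Generator | int | None = None) -> DilutionAssay:
    """Simulate well outcomes of a serial-dilution endpoint assay.

    Each well receives ``inoculum_volume_ml`` of concentrate diluted by
    the level's factor and is positive with probability
    ``1 - exp(-titer * dilution * volume)`` (Poisson single-hit).
    """
    dilutions = np.asarray(dilutions, dtype=float)
    if titer_infectious < 0:
        raise ValueError("titer must be non-negative")
    if np.any(np.diff(dilutions) >= 0):
        raise ValueError("dilutions must be strictly decreasing")
    if wells < 1:
        raise ValueError("need at least one well per dilution")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_pos = -np.expm1(-titer_infectious * dilutions * inoculum_volume_ml)
    positives = rng.binomial(wells, p_pos)
    return DilutionAssay(
        dilution=dilutions,
        positive=positives,
        total=np.full(dilutions.shape, wells, dtype=int),
        volume_ml=inoculum_volume_ml,
    )


def ll_config(**overrides) -> SimConfig:
    """Limited-light (LL) variant of the default configuration."""
    params = dict(mu_max=0.091, light_label="LL")
    params.update(overrides)
    return SimConfig(**params)
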
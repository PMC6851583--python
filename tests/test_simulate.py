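"""Simulator contracts: conservation, determinism, limits, null controls."""

import numpy as np
import pandas as pd
import pytest

from picovir import kinetics as kin
from picovir import simulate as sim


def run_states(config, v0=None):
    """Step a single arm over the full window; return the final state."""
    rng = np.random.default_rng(config.seed)
    v0 = config.v0 if v0 is None else v0
    n = round((config.t_end - config.t_start) / config.dt)
    grid = config.t_start + config.dt * np.arange(n + 1)
    state = sim.initial_state(config)
    added = False
    for k in range(n):
        if not added and v0 > 0 and abs(grid[k]) <= config.dt / 2:
            sim.add_inoculum(state, config, v0)
            added = True
        state = sim.step(state, config, rng)
    return state


def latent_series(result, treatment, target):
    lat = result.latent
    sub = lat[(lat.treatment == treatment) & (lat.target == target)]
    return sub.set_index("time_h")["value_per_ml"].sort_index()


# -- configuration validation -----------------------------------------------

@pytest.mark.parametrize("kwargs", [
    dict(dt=0.0),
    dict(infectivity_true=1.5),
    dict(burst_mean=0.0),
    dict(latent_period_true=-1.0),
    dict(t_start=1.0),          # virus must be added inside the window
    dict(n0_host=0.0),
    dict(v0=-1.0),
    dict(division_window=(14.0, 6.0)),
    dict(arrest_mode="sometimes"),
    dict(dt=5.0, k_ads=1e-6),   # tau-leap precondition violated
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(sim.SimConfigError):
        sim.SimConfig(**kwargs)


# -- determinism and control equivalence ------------------------------------

def test_bit_identical_outputs_for_identical_config():
    a = sim.run_experiment(sim.SimConfig(seed=42))
    b = sim.run_experiment(sim.SimConfig(seed=42))
    pd.testing.assert_frame_equal(a.abundance, b.abundance)
    pd.testing.assert_frame_equal(a.latent, b.latent)
    for fa, fb in zip(a.flow_samples, b.flow_samples):
        np.testing.assert_array_equal(fa.fluorescence, fb.fluorescence)


def test_zero_inoculum_reproduces_the_control():
    res = sim.run_experiment(sim.SimConfig(seed=7, v0=0.0), emit_flow=False)
    virus = latent_series(res, "virus", "host")
    control = latent_series(res, "control", "host")
    np.testing.assert_array_equal(virus.to_numpy(), control.to_numpy())


# -- growth -----------------------------------------------------------------

def test_continuous_division_matches_closed_form_exponential():
    """With the division window spanning all hours, growth is exactly e^(mu t)."""
    cfg = sim.SimConfig(seed=0, v0=0.0, division_window=(0.0, 24.0),
                        burst_cv=0.0, noise_cv_counts=0.0)
    state = run_states(cfg, v0=0.0)
    t_days = (cfg.t_end - cfg.t_start) / 24.0
    expected = cfg.n0_host * np.exp(cfg.mu_max * t_days)
    assert state.host_total == pytest.approx(expected, rel=1e-2)
    assert state.host_total == pytest.approx(expected, rel=1e-9)  # exact here


def test_diel_pulse_recovers_configured_growth_rate(noiseless_result):
    """Table-style mu over the experiment equals mu_max for the control."""
    control = latent_series(noiseless_result, "control", "host")
    mu = kin.growth_rate(control.index.to_numpy(), control.to_numpy(),
                         -3.5, 24.5)
    assert mu == pytest.approx(0.76, abs=0.01)


def test_division_confined_to_diel_window(noiseless_result):
    control = latent_series(noiseless_result, "control", "host")
    # no division before the window opens (dawn -3.5 h + 6 h + S/G2M transit)
    assert control.loc[4.5] == pytest.approx(control.loc[-3.5], rel=1e-12)
    assert control.loc[14.5] > control.loc[4.5] * 1.5


# -- infection machinery ----------------------------------------------------

def test_zero_infectivity_never_infects():
    cfg = sim.SimConfig(seed=3, infectivity_true=0.0, noise_cv_counts=0.0)
    state = run_states(cfg)
    assert state.i_total == 0.0
    assert state.cum_infections == 0.0
    res = sim.run_experiment(cfg, emit_flow=False)
    virus = latent_series(res, "virus", "host")
    control = latent_series(res, "control", "host")
    np.testing.assert_allclose(virus.to_numpy(), control.to_numpy(), rtol=1e-12)


def test_zero_adsorption_keeps_virions_constant():
    cfg = sim.SimConfig(seed=3, k_ads=0.0, noise_cv_counts=0.0)
    res = sim.run_experiment(cfg, emit_flow=False)
    virus = latent_series(res, "virus", "virus")
    np.testing.assert_allclose(virus.to_numpy(), cfg.v0, rtol=1e-12)
    assert run_states(cfg).i_total == 0.0


def test_deterministic_burst_of_single_cohort():
    """10^3 cells lysing with burst 100 and no CV release exactly 10^5 virions."""
    cfg = sim.SimConfig(seed=0, burst_mean=100.0, burst_cv=0.0, v0=0.0)
    state = sim.initial_state(cfg)
    state.s = 0.0
    state.s_r = 0.0
    state.i_ages[-1] = 1e3  # one cohort at the lysis boundary
    rng = np.random.default_rng(0)
    new = sim.step(state, cfg, rng)
    assert new.v_total == pytest.approx(1e5, rel=1e-12)
    assert new.cum_lysed == pytest.approx(1e3)


def test_no_susceptibles_means_virions_change_only_by_bursts():
    cfg = sim.SimConfig(seed=0, burst_cv=0.0, v0=0.0)
    state = sim.initial_state(cfg)
    state.s = 0.0
    state.s_r = 0.0
    state.v_inf = 1e6
    state.i_ages[10] = 1e3
    rng = np.random.default_rng(0)
    new = sim.step(state, cfg, rng)
    assert new.v_inf == 1e6  # nothing to adsorb to, nothing lysed yet
    assert new.cum_infections == 0.0


def test_mass_balance_to_machine_precision():
    """Hosts: N0 + divisions - lysed; virions: added + bursts - sinks."""
    cfg = sim.SimConfig(seed=11)
    state = run_states(cfg)
    hosts = state.host_total
    np.testing.assert_allclose(
        hosts, cfg.n0_host + state.cum_divisions - state.cum_lysed, rtol=1e-9)
    np.testing.assert_allclose(
        state.v_total,
        state.v_added + state.cum_bursts - state.cum_infections
        - state.cum_adsorbed_non - state.cum_diluted,
        rtol=1e-9)


def test_first_virion_increase_in_expected_sampling_interval(noiseless_result):
    """Latent period 7 h: log2FC first exceeds zero in the (6.5, 8.5] interval."""
    virus = latent_series(noiseless_result, "virus", "virus")
    n = np.log2(virus / virus.loc[0.5])
    assert (n.loc[2.5:6.5] <= 0).all()
    assert n.loc[8.5] > 1.0


def test_delayed_arrest_lets_infected_cells_divide():
    base = dict(seed=5, noise_cv_counts=0.0, burst_cv=0.0)
    immediate = run_states(sim.SimConfig(arrest_mode="immediate", **base))
    delayed = run_states(sim.SimConfig(arrest_mode="delayed", arrest_delay=6.0,
                                       **base))
    assert delayed.cum_divisions > immediate.cum_divisions


# -- flow emission ----------------------------------------------------------

def test_flow_sample_g1_mode_at_half_g2m(default_result):
    from picovir.cellcycle import G1Gater

    samples = [f for f in default_result.flow_samples
               if f.treatment == "control" and f.time_h == 12.5]
    gater = G1Gater().fit(samples[0])
    assert gater.g2_mode_ is not None
    assert gater.g2_mode_ / gater.g1_mode_ == pytest.approx(2.0, abs=0.25)


def test_flow_sample_warns_below_event_floor(rng):
    cfg = sim.SimConfig(seed=0, events_per_sample=50)
    state = sim.initial_state(cfg)
    with pytest.warns(UserWarning):
        sim.emit_flow_sample(state, cfg, rng)


def test_flow_sampling_proportional_to_abundance(rng):
    cfg = sim.SimConfig(seed=0, events_per_sample=20000, fluor_cv=0.0)
    state = sim.initial_state(cfg)
    state.t = 0.0  # outside the division window: all uninfected cells in G1
    state.s = 1e6
    state.s_r = 0.0
    state.i_ages[-1] = 1e6  # equal infected pool at high DNA
    fs = sim.emit_flow_sample(state, cfg, rng)
    frac_high = np.mean(fs.fluorescence > 4.0)
    assert frac_high == pytest.approx(0.5, abs=0.02)


# -- MPN well simulation ----------------------------------------------------

def test_mpn_assay_zero_titer_all_negative(rng):
    assay = sim.simulate_mpn_assay(0.0, [1e-3, 1e-4], 24, 0.05, rng)
    assert (assay.positive == 0).all()


def test_mpn_assay_half_positive_at_ln2_exposure(rng):
    """Exposure ln2 per well makes each well a fair coin."""
    titer = np.log(2.0) / (0.05 * 1e-3)
    assay = sim.simulate_mpn_assay(titer, [1e-3], 10000, 0.05, rng)
    assert assay.positive[0] / assay.total[0] == pytest.approx(0.5, abs=0.02)


def test_mpn_assay_requires_decreasing_dilutions(rng):
    with pytest.raises(ValueError):
        sim.simulate_mpn_assay(1e9, [1e-4, 1e-3], 24, 0.05, rng)
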
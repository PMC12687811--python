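"""Compartmental infusion simulator: kinetics, balance, forward measurement."""

import numpy as np
import pandas as pd
import pytest

from nadflux.atlas import TracerSpec
from nadflux.simulate import (
    SCENARIOS,
    build_default_model,
    infusion_rate,
    measure,
    simulate,
)


@pytest.mark.parametrize(
    ("conc_mM", "pump", "mass", "rate"),
    [
        (50.0, 0.5, 20.0, 1.25),   # the U-13C11-Trp arm
        (4.0, 0.5, 20.0, 0.1),     # the 2H4-NAM arm
        (1.0, 1.0, 1.0, 1.0),      # unit identity
    ],
)
def test_infusion_rate_arithmetic(conc_mM, pump, mass, rate):
    assert infusion_rate(conc_mM, pump, mass) == pytest.approx(rate, rel=1e-12)


@pytest.mark.parametrize("bad", [(-1, 1, 1), (1, 0, 1), (1, 1, -2)])
def test_infusion_rate_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        infusion_rate(*bad)


@pytest.mark.parametrize("scenario", SCENARIOS)
@pytest.mark.parametrize("tracer_name", ["13C11-Trp", "2H4-NAM"])
def test_presets_are_balanced(pmap, tracers, scenario, tracer_name):
    config = build_default_model(scenario, tracers[tracer_name])
    assert config.validate(pmap) == []


def test_unknown_scenario_rejected(nam_tracer):
    with pytest.raises(ValueError, match="unknown scenario"):
        build_default_model("remission", nam_tracer)


def test_active_flare_directions(tracers):
    """Inflammation presets move pools and fluxes the documented way."""
    for name in ("13C11-Trp", "2H4-NAM"):
        ctrl = build_default_model("control", tracers[name])
        dss = build_default_model("active_flare", tracers[name])
        assert dss.pools[("colon", "NAD+")] < ctrl.pools[("colon", "NAD+")]

        def flux(cfg, met_from, met_to, comp, route):
            return sum(f.rate for f in cfg.fluxes
                       if (f.met_from, f.met_to, f.comp_to, f.route)
                       == (met_from, met_to, comp, route))

        assert flux(dss, "NAM", "NAD+", "colon", "salvage") > \
            flux(ctrl, "NAM", "NAD+", "colon", "salvage")
        assert flux(dss, "NAD+", "NAM", "colon", "consumption") > \
            flux(ctrl, "NAD+", "NAM", "colon", "consumption")
        assert flux(dss, "Kyn", "NAD+", "liver", "de_novo") > \
            flux(ctrl, "Kyn", "NAD+", "liver", "de_novo")


def test_unbalanced_config_refused(pmap, nam_tracer, make_one_pool):
    cfg = make_one_pool(nam_tracer)
    cfg.fluxes = cfg.fluxes[:-1]  # drop the sink
    with pytest.raises(ValueError, match="unbalanced"):
        simulate(cfg, pmap)


def test_zero_infusion_stays_unlabeled(pmap, nam_tracer, make_one_pool):
    cfg = make_one_pool(nam_tracer, labeled_frac=0.0)
    sim = simulate(cfg, pmap)
    for (comp, met, shift), series in sim.trajectories.items():
        if shift > 0:
            assert np.allclose(series, 0.0, atol=1e-12)
        else:
            assert np.allclose(series, 1.0, atol=1e-9)


def test_one_pool_matches_closed_form(pmap, nam_tracer, make_one_pool):
    """Labeled fraction follows f(1 - exp(-kt)) in a single well-mixed pool."""
    f, k = 0.4, 0.05
    cfg = make_one_pool(nam_tracer, pool=10.0, turnover=k, labeled_frac=f)
    sim = simulate(cfg, pmap)
    expected = f * (1.0 - np.exp(-k * sim.times))
    got = sim.trajectories[("pool", "NAM", 4)]
    assert np.abs(got - expected).max() < 1e-6


def test_two_pool_chain_equilibrates(pmap, nam_tracer):
    """Downstream steady-state enrichment equals the upstream enrichment."""
    from nadflux.simulate import InfusionSpec, SimConfig, sink, source, transfer

    f, F = 0.3, 1.0
    cfg = SimConfig(
        compartments=["up", "down"],
        pools={("up", "NAM"): 5.0, ("down", "NAM"): 8.0},
        fluxes=[
            source("NAM", "up", (1 - f) * F),
            transfer("NAM", "up", "down", F),
            sink("NAM", "down", F),
        ],
        infusion=InfusionSpec(tracer=nam_tracer, rate=f * F, duration=2000.0),
        sample_times=[0.0, 2000.0],
        infusion_compartment="up",
    )
    sim = simulate(cfg, pmap)
    up = sim.at("up", "NAM", 4, 2000.0)
    down = sim.at("down", "NAM", 4, 2000.0)
    assert up == pytest.approx(f, abs=1e-6)
    assert down == pytest.approx(up, abs=1e-6)


def test_mass_balance_and_fraction_sums(control_sim_nam):
    cfg = control_sim_nam.config
    for (comp, met) in cfg.pools:
        total = sum(series for (c, m, _), series
                    in control_sim_nam.trajectories.items()
                    if (c, m) == (comp, met))
        assert np.abs(total - 1.0).max() < 1e-7


def test_labeled_fractions_rise_monotonically(control_sim_nam):
    for (comp, met, shift), series in control_sim_nam.trajectories.items():
        if shift > 0:
            assert np.all(np.diff(series) > -1e-9), (comp, met, shift)


def test_ground_truth_contribution_split(control_sim_nam):
    truth = control_sim_nam.ground_truth_contributions
    assert truth[("colon", "NAM")] == pytest.approx(70.0)
    assert truth[("colon", "Trp")] == pytest.approx(30.0)
    assert truth[("liver", "Trp")] > 0


def test_precursor_dilution_bound(control_sim_nam):
    """Tissue NAD+ labeling cannot exceed the serum precursor enrichment."""
    serum = (control_sim_nam.at("serum", "NAM", 3, 1200.0)
             + control_sim_nam.at("serum", "NAM", 4, 1200.0))
    for comp in ("liver", "colon"):
        assert control_sim_nam.at(comp, "NAD+", 3, 1200.0) <= serum + 1e-9


def test_measure_deterministic_for_fixed_seed(control_sim_nam, pmap):
    a, ma = measure(control_sim_nam, pmap, n_animals=2, noise_cv=0.1, seed=42)
    b, mb = measure(control_sim_nam, pmap, n_animals=2, noise_cv=0.1, seed=42)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(ma, mb)
    c, _ = measure(control_sim_nam, pmap, n_animals=2, noise_cv=0.1, seed=43)
    assert not np.allclose(a["intensity"], c["intensity"])


def test_measure_degenerate_forward_model_is_exact(pmap, make_one_pool):
    """No noise, perfect purity, zero abundances: raw equals true fractions."""
    pure = TracerSpec(name="pure-NAM", element="H", n_heavy=4,
                      entry_metabolite="NAM", redox_site_loss=1, purity=1.0)
    cfg = make_one_pool(pure, pool=10.0)
    sim = simulate(cfg, pmap)
    peaks, _ = measure(sim, pmap, noise_cv=0.0,
                       abundances={"C": 0.0, "H": 0.0}, intensity_scale=1.0)
    nam = peaks[peaks["metabolite"] == "NAM"]
    terminal = nam[nam["sample_id"].str.endswith("t1200")]
    m4 = terminal.loc[terminal["isotopologue"] == "M+4", "intensity"].iloc[0]
    assert m4 / 10.0 == pytest.approx(sim.at("pool", "NAM", 4, 1200.0),
                                      abs=1e-9)


def test_measure_noise_cv_calibrated(pmap, nam_tracer, make_one_pool):
    """Log-normal noise at cv=0.1 yields a sample CV near 0.1 over replicates."""
    cfg = make_one_pool(nam_tracer)
    sim = simulate(cfg, pmap)
    peaks, _ = measure(sim, pmap, n_animals=50, noise_cv=0.1, seed=9)
    m0 = peaks[(peaks["metabolite"] == "NAM")
               & (peaks["isotopologue"] == "M+0")]["intensity"]
    cv = m0.std(ddof=1) / m0.mean()
    assert 0.07 < cv < 0.13


def test_measure_times_must_be_on_grid(control_sim_nam, pmap):
    with pytest.raises(KeyError):
        measure(control_sim_nam, pmap, times=[0.0, 777.0])
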
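import numpy as np
import pytest

from nadflux.atlas import default_map, default_tracers
from nadflux.simulate import (
    Flux,
    InfusionSpec,
    SimConfig,
    balance,
    build_default_model,
    simulate,
    sink,
    source,
    transfer,
)


@pytest.fixture(scope="session")
def pmap():
    return default_map()


@pytest.fixture(scope="session")
def tracers():
    return default_tracers()


@pytest.fixture(scope="session")
def trp_tracer(tracers):
    return tracers["13C11-Trp"]


@pytest.fixture(scope="session")
def nam_tracer(tracers):
    return tracers["2H4-NAM"]


@pytest.fixture(scope="session")
def control_sim_nam(pmap, nam_tracer):
    """Control-scenario d4-NAM infusion, solved once per session."""
    config = build_default_model("control", nam_tracer, seed=11)
    return simulate(config, pmap)


@pytest.fixture(scope="session")
def control_sim_trp(pmap, trp_tracer):
    config = build_default_model("control", trp_tracer, seed=11)
    return simulate(config, pmap)


def one_pool_config(tracer, *, pool=10.0, turnover=0.05, labeled_frac=0.4,
                    duration=1200.0, times=None, seed=3, noise_cv=0.0):
    """Single well-mixed pool with constant fractional labeled inflow.

    Total inflow F = turnover * pool, of which ``labeled_frac`` is the
    infused tracer; the labeled fraction follows f * (1 - exp(-F/P * t)).
    """
    met = tracer.entry_metabolite
    F = turnover * pool
    cfg = SimConfig(
        compartments=["pool"],
        pools={("pool", met): pool},
        fluxes=[source(met, "pool", (1 - labeled_frac) * F),
                sink(met, "pool", F)],
        infusion=InfusionSpec(tracer=tracer, rate=labeled_frac * F,
                              duration=duration),
        sample_times=list(times) if times is not None
        else [0.0, 15.0, 30.0, 60.0, 120.0, 360.0, 900.0, 1200.0],
        noise_cv=noise_cv,
        seed=seed,
        infusion_compartment="pool",
    )
    return cfg


@pytest.fixture()
def make_one_pool():
    return one_pool_config
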
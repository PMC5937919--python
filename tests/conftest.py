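import numpy as np
import pytest

import fluxmu as fm

MEASURED_POOLS = ["G6P", "F6P", "GAP", "DHAP", "E4P", "RUL5P", "RIB5P", "SED7P"]

# Aldolase recombination returns the marginal triose labeling unchanged, so
# the FBA exchange is structurally unidentifiable from metabolite-level MIDs;
# fits that need a regular model pin it at the generating value.
FIXED_EXCHANGES = {"FBA": 0.1}


@pytest.fixture(scope="session")
def abundances():
    return fm.IsotopeAbundances()


@pytest.fixture(scope="session")
def rl5p_composition():
    comps = fm.load_compositions()
    return comps["RUL5P"]


@pytest.fixture(scope="session")
def rl5p_distribution(rl5p_composition):
    return fm.build_shift_distribution(rl5p_composition)


@pytest.fixture(scope="session")
def network():
    return fm.load_network()


@pytest.fixture(scope="session")
def compositions():
    return fm.load_compositions()


@pytest.fixture(scope="session")
def tracer():
    return fm.glucose_1_6_13c2()


@pytest.fixture(scope="session")
def reference_experiment():
    return fm.reference_scenario(seed=3)


@pytest.fixture(scope="session")
def noise_free_measurements(reference_experiment, network):
    meas, nets, exch = fm.measurement_set_from_scenario(
        reference_experiment, network, MEASURED_POOLS, noise=False
    )
    return meas, nets, exch


@pytest.fixture(scope="session")
def noise_free_fit(network, noise_free_measurements, reference_experiment):
    meas, _, _ = noise_free_measurements
    return fm.fit_fluxes(network, meas, reference_experiment.tracer, restarts=5, seed=0)


@pytest.fixture(scope="session")
def noisy_fit(network, reference_experiment):
    meas, nets, exch = fm.measurement_set_from_scenario(
        reference_experiment, network, MEASURED_POOLS, noise=True, seed=11
    )
    fit = fm.fit_fluxes(
        network,
        meas,
        reference_experiment.tracer,
        restarts=1,
        seed=0,
        fixed_exchanges=FIXED_EXCHANGES,
    )
    return meas, fit
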
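import pytest

import clhomeo as c


@pytest.fixture(scope="session")
def gcl_protocol():
    return c.make_protocol("gcl_estimation")


@pytest.fixture(scope="session")
def noiseless_cell():
    return c.GroundTruthCell(noise_sd_pA=0.0)


@pytest.fixture(scope="session")
def noiseless_gcl_sweep(noiseless_cell, gcl_protocol):
    """Noiseless, Rs-distorted, chloride-coupled g_Cl-protocol sweep."""
    return c.simulate_sweep(noiseless_cell, gcl_protocol,
                            couple_cl_dynamics=True, seed=1)


@pytest.fixture(scope="session")
def linear_leak_config():
    return c.GclAnalysisConfig(leak_form="linear")
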
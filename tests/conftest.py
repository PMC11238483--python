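import numpy as np
import pytest

from cvdadapt.simulate import GeneratorConfig, generate_institution, site_profiles


@pytest.fixture(scope="session")
def small_site():
    """One small generated institution (all dimensions present)."""
    cfg = GeneratorConfig(n_patients=80, seed=7)
    return generate_institution(cfg, "site_A", site_index=0)


@pytest.fixture(scope="session")
def small_site_b():
    """Small institution lacking hemoglobin and smoking data."""
    cfg = site_profiles(n_a=50, n_b=60, seed=11)["site_B"]
    return generate_institution(cfg, "site_B", site_index=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
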
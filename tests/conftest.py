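import numpy as np
import pytest

import micelkin as mk


@pytest.fixture(scope="session")
def reference_formulations():
    return mk.generate_formulations()


@pytest.fixture(scope="session")
def noiseless_panel():
    return mk.generate_panel(mk.PanelConfig(seed=101, noise_rel=0.0))


@pytest.fixture(scope="session")
def noisy_panel():
    return mk.generate_panel(mk.PanelConfig(seed=101, noise_rel=0.02))


@pytest.fixture
def ou_params():
    return mk.OUParameters(D=1.0, eta=0.5, x0=1.0)


@pytest.fixture
def sample_curve():
    t = np.linspace(1.0, 100.0, 20)
    return mk.ReleaseCurve("A", 7.4, t, 10.0 * np.sqrt(t / 100.0) * 9.5)
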
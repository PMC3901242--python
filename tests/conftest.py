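"""Shared fixtures: canonical parameter sets and cached recovery studies."""

import numpy as np
import pytest

from nmrkin.pipeline import pgi_recovery_study, pfk_recovery_study

# published parameter sets used as ground truth throughout
PGI_TRUTH = {"vf": 3.551, "ks": 0.550, "kp": 0.152, "keq": 0.286}
PFK_TRUTH = {"vf": 0.4435, "ks1": 0.4174, "ks2": 0.5444, "km": 0.0863,
             "alpha": 0.3797, "h": 1.883}


@pytest.fixture(scope="session")
def pgi_study():
    """Noiseless 5-assay PGI round trip (simulate -> spline -> GA+LM fit)."""
    return pgi_recovery_study(seed=42)


@pytest.fixture(scope="session")
def pfk_study():
    """Noiseless 6-assay PFK round trip."""
    return pfk_recovery_study(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
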
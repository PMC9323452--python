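import numpy as np
import pytest

from vitalcorr.model_core import ModelConfig, logit
from vitalcorr.synthetic_data import CovarianceStructure, VitalRateModel


@pytest.fixture
def simple_vr():
    """Two-age-class survival, success and detection; no productivity layer."""
    return VitalRateModel(
        mu={"phi": logit(0.5), "pi": logit(0.5), "p": logit(0.9)},
        age_effects={"phi": {1: logit(0.8) - logit(0.5)}},
        productivity_family=None,
        active_params=("phi_j", "phi_ad", "pi"),
    )


@pytest.fixture
def simple_config():
    return ModelConfig(active_params=("phi_j", "phi_ad", "pi"),
                       productivity_family=None)


@pytest.fixture
def simple_cov():
    corr = np.array([[1.0, 0.6, 0.24], [0.6, 1.0, 0.4], [0.24, 0.4, 1.0]])
    return CovarianceStructure(param_order=("phi_j", "phi_ad", "pi"),
                               sigma=np.full(3, 0.4), corr=corr, sigma_p=0.3)
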
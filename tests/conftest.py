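import numpy as np
import pytest

from bispkpd.covariate_pk import Patient, pk_params_from_covariates
from bispkpd.pkpd import EffectLinkConfig, InfusionProtocol, PDParams


@pytest.fixture
def ref_patient() -> Patient:
    """Reference covariates at which every covariate correction vanishes
    (age 53, weight 77 kg, height 177 cm)."""
    return Patient(id="ref", age=53.0, weight=77.0, height=177.0, sex="male")


@pytest.fixture
def ref_pk(ref_patient):
    """Reference PK parameter set with lean body mass pinned to 59 kg."""
    return pk_params_from_covariates(ref_patient, lbm=59.0)


@pytest.fixture
def hill() -> PDParams:
    return PDParams(e0=90.0, emax=70.0, ec50=2.5, gamma=2.0)


@pytest.fixture
def link() -> EffectLinkConfig:
    return EffectLinkConfig()


@pytest.fixture
def induction_protocol() -> InfusionProtocol:
    """85 mg induction bolus plus 7 mg/min maintenance for 40 min."""
    return InfusionProtocol(boluses=((0.0, 85.0),), segments=((0.0, 40.0, 7.0),))
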
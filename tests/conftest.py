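import pytest

from biliforecast import Covariates, default_population_model


@pytest.fixture(scope="session")
def pop():
    return default_population_model()


@pytest.fixture(scope="session")
def ref_cov():
    """Reference covariates: all covariate multipliers equal one."""
    return Covariates(gestational_age=38.7, birth_weight=3500.0,
                      sex="female", delivery_mode="vaginal", hemolytic=False)
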
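import pytest

import tkidist


@pytest.fixture(scope="session")
def params():
    return tkidist.load_default_parameters()


@pytest.fixture(scope="session")
def blood(params):
    return params.blood


@pytest.fixture(scope="session")
def final():
    return tkidist.final_model_scenario()


@pytest.fixture(scope="session")
def observed():
    return tkidist.load_observed_tbr()


@pytest.fixture(scope="session")
def model_predictions(params, final):
    """Final-model TBR predictions over the full compound x tissue grid."""
    return {
        (r.compound, r.tissue): r.tbr
        for r in tkidist.predict_all(params, final)
    }
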
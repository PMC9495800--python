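import numpy as np
import pytest

from parafuzz.calibration import default_calibration_table, fit
from parafuzz.fuzzy import InferenceConfig, save_rule_base


@pytest.fixture(scope="session")
def calib():
    """One calibration of the default template against the laboratory table.

    Session-scoped: the fitted system is reused by engine, pipeline and
    acceptance tests.
    """
    return fit(default_calibration_table(), seed=1)


@pytest.fixture(scope="session")
def fitted_rb(calib):
    return calib.rule_base


@pytest.fixture(scope="session")
def rules_file(calib, tmp_path_factory):
    path = tmp_path_factory.mktemp("rules") / "rules_fitted.yaml"
    save_rule_base(calib.rule_base, path)
    return path


@pytest.fixture
def cfg():
    return InferenceConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20220828)
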
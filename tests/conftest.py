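import numpy as np
import pytest
from hypothesis import settings

from sarcoscore import study
from sarcoscore.cohort_io import write_panel
from sarcoscore.synthetic_cohort import simulate, study_default_spec

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return list(study.STUDY_PANEL)


@pytest.fixture
def panel_file(tmp_path, panel):
    path = tmp_path / "panel.ini"
    write_panel(panel, path)
    return path


@pytest.fixture(scope="session")
def sim_spec():
    # joint calibration is cached inside study_default_spec
    return study_default_spec(seed=11)


@pytest.fixture(scope="session")
def sim_cohort(sim_spec):
    """One study-sized simulated cohort (190 samples) plus generator truth."""
    return simulate(sim_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
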
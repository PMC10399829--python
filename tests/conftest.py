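import numpy as np
import pytest

from commodular.gllvm import GLLVMConfig, fit_gllvm
from commodular.synthetic import StudyDesign, generate_study


@pytest.fixture(scope="session")
def study():
    """One default study-shaped community (120 x 36) with its truth."""
    return generate_study(StudyDesign(seed=3))


@pytest.fixture(scope="session")
def study_fit(study):
    cm, meta, truth = study
    return fit_gllvm(cm, GLLVMConfig(seed=3))


@pytest.fixture()
def small_study():
    """A reduced community for fast fitting tests (60 x 12)."""
    return generate_study(StudyDesign(n_farms=3, n_years=2, n_times=10, n_taxa=12, seed=7))
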
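import numpy as np
import pytest

from morphodisp import gower_matrix, pcoa, retain_axes, synthetic_reference


@pytest.fixture(scope="session")
def reference():
    """The fixed synthetic reference matrix and its two grouping schemes."""
    matrix, body_plan, truth = synthetic_reference()
    return matrix, body_plan, truth


@pytest.fixture(scope="session")
def reference_ordination(reference):
    matrix, _, _ = reference
    return retain_axes(pcoa(gower_matrix(matrix)), n_axes=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150424)
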
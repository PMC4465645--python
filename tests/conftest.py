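import numpy as np
import pytest

#: eigenvalues of a published PCA of eight pain-threshold measurements
#: (intercorrelation matrix; they sum to 8.000)
PCA_EIGENVALUES = [3.834, 1.142, 1.061, 0.740, 0.491, 0.432, 0.208, 0.092]


@pytest.fixture
def pca_eigenvalues():
    return np.array(PCA_EIGENVALUES)


@pytest.fixture
def rng():
    return np.random.default_rng(20150610)
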
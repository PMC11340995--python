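import numpy as np
import pytest

from scharm.core_io import AcquisitionSetting, Connectome, Parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def setting():
    return AcquisitionSetting(res=1.25, bval=3000.0)


def make_connectome(matrix, subject_id="sub1", session="1",
                    setting=None, labels=None):
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    parc = Parcellation(tuple(labels) if labels else
                        tuple(f"R{i + 1:03d}" for i in range(n)))
    return Connectome(
        matrix=matrix,
        subject_id=subject_id,
        session=session,
        setting=setting or AcquisitionSetting(res=1.25, bval=3000.0),
        parcellation=parc,
    )


def random_symmetric_counts(rng, n, density=0.6, max_count=20):
    """Random valid connectivity matrix: symmetric, zero diagonal, ints >= 0."""
    upper = rng.integers(1, max_count + 1, size=(n, n))
    present = rng.random((n, n)) < density
    m = np.triu(upper * present, k=1)
    return m + m.T


@pytest.fixture
def connectome_factory():
    return make_connectome
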
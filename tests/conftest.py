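import numpy as np
import pytest

from ncphmda import AssociationNetwork, SymptomProfile


@pytest.fixture
def toy_net():
    """2x2 network: d1-{m1,m2}, d2-{m1}."""
    return AssociationNetwork(["d1", "d2"], ["m1", "m2"],
                              np.array([[1.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def dense_net():
    """6x8 network dense enough that every entity keeps associations in CV."""
    rng = np.random.default_rng(123)
    A = (rng.random((6, 8)) < 0.5).astype(float)
    A[A.sum(axis=1) == 0, 0] = 1.0
    A[0, A.sum(axis=0) == 0] = 1.0
    return AssociationNetwork([f"d{i}" for i in range(6)],
                              [f"m{j}" for j in range(8)], A)


@pytest.fixture
def toy_symptoms():
    return SymptomProfile(["d1", "d2"], ["s1", "s2"],
                          np.array([[2.0, 1.0], [0.0, 1.0]]))


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
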
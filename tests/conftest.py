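import numpy as np
import pytest

import spatemp_rsa as sr


@pytest.fixture(scope="session")
def movements26():
    return sr.synth.default_movement_set()


@pytest.fixture(scope="session")
def target26(movements26):
    """Euclidean-embeddable 26-condition target geometry."""
    return sr.synth.random_geometry_rdm(26, seed=1, labels=movements26.labels)


@pytest.fixture(scope="session")
def small_movements():
    return sr.synth.default_movement_set(8)


@pytest.fixture(scope="session")
def small_target(small_movements):
    return sr.synth.random_geometry_rdm(8, seed=3, labels=small_movements.labels)


def reorder_to(rdm, labels):
    """Reorder an RDM's conditions to a reference label order."""
    order = np.array([rdm.labels.index(lab) for lab in labels])
    return sr.RDM(rdm.values[np.ix_(order, order)], labels, rdm.kind)


@pytest.fixture(scope="session")
def reorder():
    return reorder_to
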
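import pytest

from subclonetk.clustering import ClusterSet
from subclonetk.enumeration import enumerate_structures


@pytest.fixture
def two_cluster_set():
    """CPs 0.6 > 0.3: both the chain and the branch are viable."""
    return ClusterSet("s", ("A", "B"), (0.6, 0.3))


@pytest.fixture
def chain_only_set():
    """CPs 0.8 > 0.5: the branch would need a negative normal fraction."""
    return ClusterSet("s", ("A", "B"), (0.8, 0.5))


@pytest.fixture
def three_cluster_set():
    return ClusterSet("s", ("A", "B", "C"), (0.9, 0.5, 0.3))


@pytest.fixture
def two_cluster_solutions(two_cluster_set):
    return enumerate_structures(two_cluster_set)
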
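import numpy as np
import pytest

from delimpy import Alignment, make_scenario, parse_newick_ultrametric
from delimpy.seqdata import DistanceMatrix

BALANCED_NEWICK = "((a:1,b:1):2,(c:2,d:2):1);"


@pytest.fixture
def balanced_tree():
    """4 tips, internal heights 1 (ab), 2 (cd), 3 (root)."""
    return parse_newick_ultrametric(BALANCED_NEWICK)


@pytest.fixture
def two_tip_tree():
    return parse_newick_ultrametric("(a:0.5,b:0.5);")


@pytest.fixture
def toy_alignment():
    """6 records: two tight clusters separated by many substitutions."""
    return Alignment(
        ["x1", "x2", "x3", "y1", "y2", "y3"],
        [
            "ACGTACGTACGTACGTACGT",
            "ACGTACGTACGTACGTACGA",
            "ACGTACGTACGTACGTACGT",
            "GTGTATGTACGAACGTACGT",
            "GTGTATGTACGAACGTACGA",
            "GTGTATGTACGAACGTACGT",
        ],
    )


def random_distance_matrix(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """A random symmetric matrix with distinct positive off-diagonals."""
    vals = rng.permutation(np.linspace(0.01, 1.0, n * (n - 1) // 2))
    D = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    D[iu] = vals
    D = D + D.T
    return DistanceMatrix([f"l{i}" for i in range(n)], D, "p")


@pytest.fixture(scope="session")
def scenario42():
    """The default synthetic scenario, shared across tests."""
    return make_scenario(42)
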
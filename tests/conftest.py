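import hypothesis.strategies as st
import pytest
from hypothesis import HealthCheck, settings

from locmotif import DirectedLabeledNetwork, NetworkSample, VertexLabelSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ALPHABET = ("A", "B", "C", "D", "E", "F")


def make_network(labels, edges):
    return DirectedLabeledNetwork(VertexLabelSet(tuple(labels)), frozenset(edges))


@st.composite
def networks(draw, min_n=2, max_n=6, min_m=0):
    """Random simple digraph on a prefix of the test alphabet."""
    n = draw(st.integers(min_value=min_n, max_value=max_n))
    labels = ALPHABET[:n]
    pairs = [(a, b) for a in labels for b in labels if a != b]
    mask = draw(st.lists(st.booleans(), min_size=len(pairs), max_size=len(pairs)))
    edges = {p for p, keep in zip(pairs, mask) if keep}
    if len(edges) < min_m:
        extra = draw(
            st.lists(
                st.sampled_from(pairs),
                min_size=min_m - len(edges),
                max_size=min_m,
                unique=True,
            )
        )
        edges.update(extra)
    return make_network(labels, edges)


@st.composite
def edge_sets(draw, max_n=6, min_size=1):
    labels = ALPHABET[:max_n]
    pairs = [(a, b) for a in labels for b in labels if a != b]
    return frozenset(
        draw(st.lists(st.sampled_from(pairs), min_size=min_size, max_size=8, unique=True))
    )


@pytest.fixture
def labels_abc():
    return VertexLabelSet(("A", "B", "C"))


@pytest.fixture
def path_network():
    """F3 -> Fz -> F4 on a 3-electrode label set."""
    return make_network(("F3", "Fz", "F4"), {("F3", "Fz"), ("Fz", "F4")})


@pytest.fixture
def three_cycle(labels_abc):
    return DirectedLabeledNetwork(
        labels_abc, frozenset({("A", "B"), ("B", "C"), ("C", "A")})
    )


@pytest.fixture
def two_disjoint_edges():
    return make_network(("A", "B", "C", "D"), {("A", "B"), ("C", "D")})


@pytest.fixture
def four_cycle():
    """In/out degree all 1 on 4 vertices; its degree-sequence space is the
    9 fixed-point-free permutation digraphs, small enough to brute-force."""
    return make_network(("A", "B", "C", "D"), {("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")})
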
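"""Degree-sequence-preserving null model and its calibration.

Randomization is by edge switching: repeatedly pick two distinct directed
edges (vi, vj), (vi', vj') uniformly at random and exchange their heads to
(vi, vj'), (vi', vj), rejecting any switch that would create a loop or a
multi-edge.  Rejected attempts count as transitions of the underlying Markov
chain from a network to itself.  The move preserves every vertex's in- and
out-degree exactly, and the total number of attempts per randomization run
is round(Q * m), where m is the edge count and Q the mixing parameter.

Two calibration procedures accompany the chain:

* ``estimate_mixing_parameter`` — pick Q so that, as far as a chi-square
  style performance index over pooled realizations can tell, the chain
  samples networks with the prescribed degree sequence uniformly.  Because
  only a lower bound on the number of such networks is available (the pooled
  distinct count), the index is conservative in an unknown direction; its
  critical value is taken from Monte-Carlo simulation rather than the
  chi-squared distribution, which cannot be assumed a priori.
* ``estimate_ensemble_size`` — pick the smallest number of bootstrap
  randomizations of the whole sample whose relative subnetwork-frequency
  distribution is within a sup-norm epsilon of a larger reference.

The chain is not irreducible for every degree sequence: the directed
3-cycle, for example, is a fixed point (every proposal creates a loop).
Degenerate cases like this are detected and reported, not patched with extra
move types.
"""

from __future__ import annotations

import random
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    DirectedLabeledNetwork,
    Edge,
    NetworkSample,
    VertexLabelSet,
    degree_sequence,
)
from .enumeration import enumerate_subnetworks


def derive_seed(*parts: int | str) -> int:
    """Deterministically derive a child seed from a run seed and context parts.

    Strings are folded to stable integers first; the result fits in 32 bits.
    """
    ints = []
    for p in parts:
        if isinstance(p, str):
            acc = 0
            for ch in p:
                acc = (acc * 31 + ord(ch)) % (2**32)
            ints.append(acc)
        else:
            ints.append(int(p) % (2**32))
    return int(np.random.SeedSequence(ints).generate_state(1, np.uint32)[0])


@dataclass
class SwitchChainState:
    """Mutable state of one edge-switching Markov chain.

    The degree sequence of ``network`` is invariant over the chain's
    lifetime and the network stays simple at every step.
    """

    label_set: VertexLabelSet
    _edge_list: list[Edge]
    _edge_set: set[Edge]
    rng: random.Random
    attempts_made: int = 0
    switches_accepted: int = 0

    @classmethod
    def from_network(cls, network: DirectedLabeledNetwork, seed: int) -> "SwitchChainState":
        if network.m < 2:
            raise ValueError("chain undefined: fewer than 2 edges")
        edge_list = sorted(network.edges)  # sorted for seed-reproducible indexing
        return cls(
            label_set=network.label_set,
            _edge_list=edge_list,
            _edge_set=set(edge_list),
            rng=random.Random(seed),
        )

    @property
    def network(self) -> DirectedLabeledNetwork:
        return DirectedLabeledNetwork(self.label_set, frozenset(self._edge_set))


def attempt_edge_switch(state: SwitchChainState) -> SwitchChainState:
    """One attempt of the edge-switching move; mutates and returns ``state``.

    Two distinct edges are selected uniformly; their heads are exchanged if
    this creates neither a loop nor a multi-edge, otherwise the attempt is
    rejected and the network unchanged.  A proposal identical to the current
    edge pair (shared tail or shared head) conflicts with nothing and counts
    as an accepted switch that happens to leave the network fixed.
    """
    lst = state._edge_list
    m = len(lst)
    if m < 2:
        raise ValueError("chain undefined: fewer than 2 edges")
    rng = state.rng
    i = rng.randrange(m)
    j = rng.randrange(m - 1)
    if j >= i:
        j += 1
    a, b = lst[i]
    c, d = lst[j]
    state.attempts_made += 1
    if a == d or c == b:
        return state  # rejected: would create a loop
    if a == c or b == d:
        state.switches_accepted += 1  # proposal equals the current pair
        return state
    new1, new2 = (a, d), (c, b)
    eset = state._edge_set
    if new1 in eset or new2 in eset:
        return state  # rejected: would create a multi-edge
    eset.remove(lst[i])
    eset.remove(lst[j])
    eset.add(new1)
    eset.add(new2)
    lst[i] = new1
    lst[j] = new2
    state.switches_accepted += 1
    return state


def randomize_network(
    network: DirectedLabeledNetwork, Q: float, seed: int
) -> DirectedLabeledNetwork:
    """One randomization run: round(Q * m) switch attempts from a fresh copy.

    Rejected attempts count toward the total.  Networks with fewer than two
    edges cannot be switched and are returned unchanged with a warning.
    """
    if Q < 0:
        raise ValueError("mixing parameter Q must be nonnegative")
    m = network.m
    if m < 2:
        warnings.warn(
            f"network with m={m} edges cannot be randomized; returning it unchanged",
            stacklevel=2,
        )
        return network
    attempts = int(round(Q * m))
    if attempts == 0:
        return network
    state = SwitchChainState.from_network(network, seed)
    for _ in range(attempts):
        attempt_edge_switch(state)
    return state.network


@dataclass(frozen=True)
class NullEnsemble:
    """M independent randomizations of one sample element network.

    Every realization restarts the chain from the original network, so the
    realizations are independent draws (given enough mixing) rather than a
    thinned single chain.
    """

    source_index: int
    Q: float
    realizations: tuple[DirectedLabeledNetwork, ...]
    seed: int

    @property
    def size(self) -> int:
        return len(self.realizations)


def generate_ensemble(
    network: DirectedLabeledNetwork,
    M: int,
    Q: float,
    seed: int,
    source_index: int = 0,
) -> NullEnsemble:
    """Generate M independent randomizations, seeded per realization."""
    if M < 1:
        raise ValueError("ensemble size M must be >= 1")
    realizations = tuple(
        randomize_network(network, Q, derive_seed(seed, r)) for r in range(M)
    )
    return NullEnsemble(source_index=source_index, Q=Q, realizations=realizations, seed=seed)


def select_representative(sample: NetworkSample) -> int:
    """Index of the sample element closest to the mean degree sequence.

    Distance is the maximum norm over the concatenated (in, out) degree
    vector; ties break to the lowest index.  The representative stands in
    for the whole sample when calibrating the mixing parameter.
    """
    vectors = [np.asarray(degree_sequence(net).as_vector(), dtype=float) for net in sample.networks]
    mean_vec = np.mean(vectors, axis=0)
    distances = [float(np.max(np.abs(v - mean_vec))) for v in vectors]
    return int(np.argmin(distances))


def performance_index(
    category_counts: dict[str, int] | Counter,
    N: int,
    p0: float,
    num_categories: Optional[int] = None,
) -> float:
    """Chi-square-style goodness-of-fit index against the uniform hypothesis.

    X^2 = sum over all categories (observed - N*p0)^2 / (N*p0), where a
    category is one distinct network with the prescribed degree sequence and
    p0 the common probability under uniformity.  Categories without observed
    realizations contribute their full expected count.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if p0 <= 0:
        raise ValueError("p0 must be positive")
    if num_categories is None:
        num_categories = int(round(1.0 / p0))
    if len(category_counts) > num_categories:
        raise ValueError("more observed categories than the assumed total")
    expected = N * p0
    x2 = sum((obs - expected) ** 2 / expected for obs in category_counts.values())
    x2 += (num_categories - len(category_counts)) * expected
    return float(x2)


def mc_quantile(
    num_categories: int,
    N: int,
    p0: float,
    alpha: float,
    reps: int = 10000,
    seed: int = 0,
) -> float:
    """Monte-Carlo (1 - alpha) quantile of the performance index under uniformity.

    Simulates ``reps`` multinomial draws of N networks over equiprobable
    categories and returns the empirical quantile of X^2.  Used instead of a
    chi-squared quantile because the asymptotic distribution cannot be
    assumed when expected counts per category are small.
    """
    if num_categories < 1 or N < 1 or reps < 1:
        raise ValueError("num_categories, N and reps must be positive")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pvals = np.full(num_categories, 1.0 / num_categories)
    expected = N * p0
    stats = np.empty(reps)
    # chunk to bound memory at ~1e7 cells
    chunk = max(1, int(1e7 // max(num_categories, 1)))
    done = 0
    while done < reps:
        take = min(chunk, reps - done)
        counts = rng.multinomial(N, pvals, size=take)
        stats[done : done + take] = (((counts - expected) ** 2) / expected).sum(axis=1)
        done += take
    return float(np.quantile(stats, 1.0 - alpha))


@dataclass(frozen=True)
class PooledSpaceSummary:
    """Pooled distinct-network count across mixing parameters.

    ``distinct_count`` is a lower bound on the number of simple digraphs
    with the input's degree sequence: the union of all realizations over the
    whole Q grid plus the input network itself.  ``per_q_counts`` holds the
    per-Q category counts (input network excluded as a pseudo-realization).
    """

    distinct_count: int
    per_q_counts: dict[float, Counter]
    n_per_q: int


def estimate_distinct_lower_bound(
    network: DirectedLabeledNetwork,
    Q_grid: Sequence[float],
    N_per_Q: int,
    seed: int = 0,
) -> PooledSpaceSummary:
    """Pool realizations over a Q grid and count pairwise-different networks.

    Chains started with different mixing parameters may explore different
    regions of the space, so the per-Q sets are pooled; the input network is
    a member of the space and is included in the pooled set.
    """
    pooled: set[str] = {network.key}
    per_q: dict[float, Counter] = {}
    for qi, Q in enumerate(Q_grid):
        counter: Counter = Counter()
        for r in range(N_per_Q):
            real = randomize_network(network, Q, derive_seed(seed, qi, r))
            counter[real.key] += 1
        per_q[Q] = counter
        pooled.update(counter)
    return PooledSpaceSummary(
        distinct_count=len(pooled), per_q_counts=per_q, n_per_q=N_per_Q
    )


@dataclass(frozen=True)
class UniformityReport:
    """Outcome of mixing-parameter calibration."""

    Q_grid: tuple[float, ...]
    X2_per_Q: tuple[float, ...]
    quantile: float
    chosen_Q: float
    uniform: bool
    num_categories: int
    n_per_q: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "Q_grid": list(self.Q_grid),
            "X2_per_Q": list(self.X2_per_Q),
            "quantile": self.quantile,
            "chosen_Q": self.chosen_Q,
            "uniform": self.uniform,
            "num_categories": self.num_categories,
            "n_per_q": self.n_per_q,
            "alpha": self.alpha,
        }


def _has_accessible_move(network: DirectedLabeledNetwork) -> bool:
    """True iff some edge-switch proposal is accepted AND changes the network."""
    edges = sorted(network.edges)
    eset = network.edges
    for i, (a, b) in enumerate(edges):
        for c, d in edges[i + 1 :]:
            if a == d or c == b:
                continue
            if a == c or b == d:
                continue  # accepted but identical
            if (a, d) in eset or (c, b) in eset:
                continue
            return True
    return False


def estimate_mixing_parameter(
    network: DirectedLabeledNetwork,
    Q_grid: Sequence[float],
    N_per_Q: int,
    alpha: float = 0.05,
    reps: int = 10000,
    seed: int = 0,
    num_categories: Optional[int] = None,
) -> UniformityReport:
    """Choose the smallest Q for which the chain looks uniform on its space.

    The pooled distinct-network count sets the category count (unless a
    better bound is supplied) and p0 = 1/categories.  The smallest Q whose
    X^2 falls below the Monte-Carlo (1 - alpha) quantile is selected; if no
    Q passes, the Q minimizing X^2 is returned with ``uniform=False``.

    A single pooled category means the chain never moved.  That is genuine
    uniformity only when no accepted state-changing move exists (e.g. the
    directed 3-cycle); if moves exist but were never taken (e.g. Q = 0), the
    report is non-uniform.
    """
    Q_grid = tuple(Q_grid)
    if not Q_grid:
        raise ValueError("Q_grid must be nonempty")
    if sorted(Q_grid) != list(Q_grid):
        raise ValueError("Q_grid must be sorted ascending")
    summary = estimate_distinct_lower_bound(network, Q_grid, N_per_Q, seed=seed)
    C = num_categories if num_categories is not None else summary.distinct_count
    p0 = 1.0 / C
    x2s = tuple(
        performance_index(summary.per_q_counts[Q], N_per_Q, p0, num_categories=C)
        for Q in Q_grid
    )
    if C == 1:
        stuck_is_whole_space = not _has_accessible_move(network)
        return UniformityReport(
            Q_grid=Q_grid,
            X2_per_Q=x2s,
            quantile=0.0,
            chosen_Q=Q_grid[0],
            uniform=stuck_is_whole_space,
            num_categories=C,
            n_per_q=N_per_Q,
            alpha=alpha,
        )
    quantile = mc_quantile(C, N_per_Q, p0, alpha, reps=reps, seed=derive_seed(seed, "mc"))
    for Q, x2 in zip(Q_grid, x2s):
        if x2 <= quantile:
            return UniformityReport(
                Q_grid=Q_grid,
                X2_per_Q=x2s,
                quantile=quantile,
                chosen_Q=Q,
                uniform=True,
                num_categories=C,
                n_per_q=N_per_Q,
                alpha=alpha,
            )
    best = int(np.argmin(x2s))
    return UniformityReport(
        Q_grid=Q_grid,
        X2_per_Q=x2s,
        quantile=quantile,
        chosen_Q=Q_grid[best],
        uniform=False,
        num_categories=C,
        n_per_q=N_per_Q,
        alpha=alpha,
    )


def estimate_ensemble_size(
    sample: NetworkSample,
    k: int,
    Q: float,
    B_grid: Sequence[int],
    B_max: int,
    epsilon: float,
    seed: int = 0,
) -> int:
    """Smallest bootstrap ensemble size whose frequency distribution has converged.

    One bootstrap ensemble is one randomization of every sample element.  A
    reference distribution of relative k-subnetwork frequencies is built
    from ``B_max`` bootstrap ensembles; D_B, built the same way from the
    first B of them, is accepted when the sup-norm distance
    max_key |D_B(key) - D_ref(key)| is at most ``epsilon``.  Returns the
    smallest accepted B from ``B_grid``, else ``B_max``.
    """
    B_grid = sorted(set(int(b) for b in B_grid))
    if not B_grid or B_grid[0] < 1:
        raise ValueError("B_grid must contain positive sizes")
    if B_grid[-1] >= B_max:
        raise ValueError("max(B_grid) must be < B_max")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    S = len(sample)
    per_bootstrap: list[Counter] = []
    for b in range(B_max):
        counter: Counter = Counter()
        for i, net in enumerate(sample.networks):
            real = randomize_network(net, Q, derive_seed(seed, b, i))
            counter.update(enumerate_subnetworks(real, k))
        per_bootstrap.append(counter)

    def rel_freq(n_boot: int) -> dict[str, float]:
        total: Counter = Counter()
        for counter in per_bootstrap[:n_boot]:
            total.update(counter)
        denom = n_boot * S
        return {key: c / denom for key, c in total.items()}

    d_ref = rel_freq(B_max)
    for B in B_grid:
        d_b = rel_freq(B)
        keys = set(d_ref) | set(d_b)
        dist = max((abs(d_b.get(key, 0.0) - d_ref.get(key, 0.0)) for key in keys), default=0.0)
        if dist <= epsilon:
            return B
    return B_max


def gnp_null(
    network: DirectedLabeledNetwork, variant: str = "gnp", seed: int = 0
) -> DirectedLabeledNetwork:
    """Poisson-random-graph alternatives that do NOT preserve degree sequences.

    ``gnp`` includes each of the n(n-1) possible directed edges independently
    with p = m / (n(n-1)); ``gnm`` draws a uniform simple digraph with
    exactly m edges.  Useful as a deliberately weaker reference system.
    """
    labels = network.label_set.labels
    pairs = [(a, b) for a in labels for b in labels if a != b]
    m = network.m
    rng = np.random.default_rng(seed)
    if variant == "gnp":
        p = m / len(pairs)
        mask = rng.random(len(pairs)) < p
        edges = frozenset(pair for pair, keep in zip(pairs, mask) if keep)
    elif variant == "gnm":
        idx = rng.choice(len(pairs), size=m, replace=False)
        edges = frozenset(pairs[i] for i in idx)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'gnp' or 'gnm'")
    return DirectedLabeledNetwork(network.label_set, edges)
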
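"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive (exhaustive subset scans, full outcome
enumeration, closed-form recurrences) and shares no code with the package's
own algorithms.
"""

from itertools import combinations, product
from math import comb

import networkx as nx

from locmotif import canonical_key


def enumerate_oracle(network, k):
    """All induced weakly connected k-subnetwork keys, via networkx."""
    keys = set()
    for combo in combinations(network.label_set.labels, k):
        sub = [(t, h) for t, h in network.edges if t in combo and h in combo]
        g = nx.DiGraph()
        g.add_nodes_from(combo)
        g.add_edges_from(sub)
        if sub and nx.is_weakly_connected(g):
            keys.add(canonical_key(sub))
    return keys


def connected_digraph_count_recurrence(n):
    """Weakly connected labeled digraphs on n vertices, by the standard
    complement recurrence over the component containing vertex 1."""

    def total(j):
        return 2 ** (j * (j - 1))

    memo = {1: 1}

    def connected(j):
        if j not in memo:
            memo[j] = total(j) - sum(
                connected(i) * comb(j - 1, i - 1) * total(j - i) for i in range(1, j)
            )
        return memo[j]

    return connected(n)


def poisson_binomial_tail_oracle(q, c_obs):
    """P(sum of Bernoulli(q_i) >= c_obs) by enumerating all 2^n outcomes."""
    total = 0.0
    n = len(q)
    for outcome in product((0, 1), repeat=n):
        if sum(outcome) >= c_obs:
            prob = 1.0
            for x, qi in zip(outcome, q):
                prob *= qi if x else 1.0 - qi
            total += prob
    return total


def digraphs_with_degree_sequence(labels, in_deg, out_deg):
    """All simple digraphs on ``labels`` with the prescribed degree sequence,
    by scanning every edge subset of the right size."""
    pairs = [(a, b) for a in labels for b in labels if a != b]
    m = sum(in_deg)
    idx = {lab: i for i, lab in enumerate(labels)}
    result = []
    for subset in combinations(pairs, m):
        ins = [0] * len(labels)
        outs = [0] * len(labels)
        for t, h in subset:
            outs[idx[t]] += 1
            ins[idx[h]] += 1
        if tuple(ins) == tuple(in_deg) and tuple(outs) == tuple(out_deg):
            result.append(frozenset(subset))
    return result
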
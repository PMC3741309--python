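"""Exhaustive enumeration of induced connected labeled k-subnetworks.

Enumeration scans all C(n, k) vertex combinations of a network and keeps
those that induce a weakly connected subnetwork.  For the dense, small
networks this tool targets (EEG electrode geometries, n around 9, k in
{2, 3}) the combination scan beats recursive extension schemes such as ESU,
which are a non-goal here.

Because vertex labels are fixed, each labeled subnetwork occurs at most once
per network, so its count over a sample is simply the number of sample
element networks containing it (an integer between 0 and the sample size).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    DirectedLabeledNetwork,
    NetworkSample,
    canonical_key,
)


@dataclass(frozen=True)
class SubnetworkCountTable:
    """Counts of every observed k-subnetwork over one sample.

    Keys with zero count are never materialized; the candidate universe for
    significance testing is built from observed keys only.
    """

    sample_name: str
    k: int
    counts: dict[str, int]
    sample_size: int

    def __post_init__(self) -> None:
        for key, count in self.counts.items():
            if not 0 <= count <= self.sample_size:
                raise ValueError(f"count {count} for {key!r} outside [0, {self.sample_size}]")

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "key": [k for k, _ in rows],
                "count": [c for _, c in rows],
                "sample_size": self.sample_size,
                "k": self.k,
            }
        )

    def write_tsv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _connected(vertices: Sequence[str], edges: Iterable[tuple[str, str]]) -> bool:
    # inline union-find; hot path of the combination scan
    parent = {v: v for v in vertices}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_comp = len(parent)
    for t, h in edges:
        rt, rh = find(t), find(h)
        if rt != rh:
            parent[rt] = rh
            n_comp -= 1
    return n_comp == 1


def enumerate_subnetworks(network: DirectedLabeledNetwork, k: int) -> set[str]:
    """Keys of all induced weakly connected k-subnetworks of ``network``.

    Scans all C(n, k) combinations of the network's labels.
    """
    n = len(network.label_set)
    if k < 2 or k > n:
        raise ValueError(f"subnetwork size k={k} must satisfy 2 <= k <= n={n}")
    eset = network.edges
    keys: set[str] = set()
    for combo in combinations(network.label_set.labels, k):
        induced = [
            (a, b)
            for a in combo
            for b in combo
            if a != b and (a, b) in eset
        ]
        if induced and _connected(combo, induced):
            keys.add(canonical_key(induced))
    return keys


def count_over_sample(sample: NetworkSample, k: int) -> SubnetworkCountTable:
    """Count, for every observed key, the number of sample elements containing it."""
    counts: dict[str, int] = {}
    for net in sample.networks:
        for key in enumerate_subnetworks(net, k):
            counts[key] = counts.get(key, 0) + 1
    return SubnetworkCountTable(
        sample_name=sample.name, k=k, counts=counts, sample_size=len(sample)
    )


def filter_candidates(tables: Sequence[SubnetworkCountTable], min_count: int) -> set[str]:
    """Keys reaching ``min_count`` in at least one of the given count tables.

    This is the candidate prefilter: only subnetworks recurring within at
    least one sample are promising motif candidates and enter the test
    family.  ``min_count=1`` returns every observed key.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not tables:
        return set()
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"inconsistent subnetwork sizes across tables: {sorted(ks)}")
    selected: set[str] = set()
    for table in tables:
        selected.update(key for key, c in table.counts.items() if c >= min_count)
    return selected


def count_connected_topologies(k: int) -> int:
    """Number of weakly connected simple digraphs on k distinctly labeled vertices.

    Computed by exhaustive generation over all 2^(k(k-1)) labeled digraphs;
    capped at k=5 to bound run time and memory.  For k=3 there are 54 such
    topologies — on a fixed triple of electrodes, each connected pattern is
    one of these.
    """
    if k < 2 or k > 5:
        raise ValueError("k must be between 2 and 5 for exhaustive generation")
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    vertices = list(range(k))
    count = 0
    for mask in range(1 << len(pairs)):
        edges = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
        if len(edges) >= k - 1 and _connected(vertices, edges):
            count += 1
    return count
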
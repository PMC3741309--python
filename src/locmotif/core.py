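"""Domain types and I/O for samples of vertex-labeled directed networks.

The unit of analysis is a *sample* of simple directed networks that all live
on one fixed, ordered set of pairwise-different vertex labels — for example
EEG effective-connectivity networks over the nine electrodes F3, Fz, F4, C3,
Cz, C4, P3, Pz, P4, one network per subject.  Because the labels are fixed,
two induced subnetworks are considered the same pattern if and only if they
have exactly the same edge set; no isomorphism test is involved.

Networks are stored on disk as 2-column TSV edge lists (tail TAB head) and
grouped by a YAML/JSON manifest that carries the shared label set, so that
isolated vertices survive round trips.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

Edge = tuple[str, str]

#: The nine-electrode geometry used in EEG pain-processing studies.
EEG_9_LABELS: tuple[str, ...] = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")


@dataclass(frozen=True)
class VertexLabelSet:
    """Ordered set of pairwise-different vertex labels shared by a whole sample.

    The order is significant: it defines row/column order for any adjacency
    serialization and the alignment of degree vectors.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("a label set needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("vertex labels must be pairwise different")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    @property
    def n_possible_edges(self) -> int:
        """Number of possible directed edges n(n-1); 72 for the 9-electrode set."""
        n = len(self.labels)
        return n * (n - 1)


@dataclass(frozen=True)
class DirectedLabeledNetwork:
    """A simple digraph (no loops, no multi-edges) on a fixed label set."""

    label_set: VertexLabelSet
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def n(self) -> int:
        return len(self.label_set)

    @property
    def key(self) -> str:
        """Canonical key of the full edge set (used for distinct-network counting)."""
        return canonical_key(self.edges)


@dataclass(frozen=True)
class NetworkSample:
    """Ordered collection of networks sharing one label set (e.g. one per subject)."""

    label_set: VertexLabelSet
    networks: tuple[DirectedLabeledNetwork, ...]
    name: str = "sample"

    def __post_init__(self) -> None:
        object.__setattr__(self, "networks", tuple(self.networks))
        if len(self.networks) < 1:
            raise ValueError(f"empty sample {self.name!r}")
        for i, net in enumerate(self.networks):
            if net.label_set != self.label_set:
                raise ValueError(
                    f"network {i} of sample {self.name!r} has a different label set"
                )

    def __len__(self) -> int:
        return len(self.networks)


@dataclass(frozen=True)
class DegreeSequence:
    """Per-label in/out degree vectors, aligned with the label-set order."""

    labels: tuple[str, ...]
    in_deg: tuple[int, ...]
    out_deg: tuple[int, ...]

    @property
    def m(self) -> int:
        return sum(self.in_deg)

    def as_vector(self) -> tuple[int, ...]:
        """Concatenated (in, out) vector, for distance computations."""
        return self.in_deg + self.out_deg


@dataclass(frozen=True)
class LabeledSubnetwork:
    """An induced, weakly connected subnetwork identified by its exact edge set."""

    vertex_labels: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertex_labels", frozenset(self.vertex_labels))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if len(self.vertex_labels) < 2:
            raise ValueError("a subnetwork has at least 2 vertices")
        if not self.edges:
            raise ValueError("a subnetwork has at least one edge")
        for t, h in self.edges:
            if t not in self.vertex_labels or h not in self.vertex_labels:
                raise ValueError(f"edge ({t},{h}) leaves the vertex set")
        if not is_weakly_connected(self.vertex_labels, self.edges):
            raise ValueError("subnetwork is not weakly connected")

    @property
    def key(self) -> str:
        return canonical_key(self.edges)

    @property
    def k(self) -> int:
        return len(self.vertex_labels)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...]


def canonical_key(edges: Iterable[Edge]) -> str:
    """Deterministic, order-independent serialization of an edge set.

    Edges are written ``tail>head``, sorted lexicographically and joined with
    ``|``.  Two edge sets are equal iff their keys are equal; direction
    matters, so ``A>B`` and ``B>A`` differ.
    """
    tokens = sorted(f"{t}>{h}" for t, h in edges)
    if not tokens:
        raise ValueError("cannot key an empty edge set")
    return "|".join(tokens)


def subnetwork_from_key(key: str) -> LabeledSubnetwork:
    """Inverse of :func:`canonical_key` for subnetwork keys."""
    edges = set()
    for token in key.split("|"):
        tail, sep, head = token.partition(">")
        if not sep or not tail or not head:
            raise ValueError(f"malformed key token {token!r}")
        edges.add((tail, head))
    vertices = {v for e in edges for v in e}
    return LabeledSubnetwork(frozenset(vertices), frozenset(edges))


def is_weakly_connected(vertex_labels: Iterable[str], edges: Iterable[Edge]) -> bool:
    """True iff every vertex is reachable from every other, ignoring direction."""
    vertices = list(vertex_labels)
    if not vertices:
        return False
    adj: dict[str, list[str]] = {v: [] for v in vertices}
    for t, h in edges:
        adj[t].append(h)
        adj[h].append(t)
    seen = {vertices[0]}
    stack = [vertices[0]]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(vertices)


def validate_network(network: DirectedLabeledNetwork) -> ValidationReport:
    """Check the simple-digraph invariants: no loops, all endpoints labeled.

    Multi-edges cannot be represented (edge sets), so duplicates present in an
    input file are already collapsed by the reader before validation.
    """
    violations = []
    for t, h in sorted(network.edges):
        if t == h:
            violations.append(f"loop at {t!r}")
        if t not in network.label_set:
            violations.append(f"unknown label {t!r}")
        if h not in network.label_set and h != t:
            violations.append(f"unknown label {h!r}")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def degree_sequence(network: DirectedLabeledNetwork) -> DegreeSequence:
    """Per-label in-degree and out-degree; both sum to the edge count."""
    labels = network.label_set.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    in_deg = [0] * len(labels)
    out_deg = [0] * len(labels)
    for t, h in network.edges:
        out_deg[idx[t]] += 1
        in_deg[idx[h]] += 1
    return DegreeSequence(labels=labels, in_deg=tuple(in_deg), out_deg=tuple(out_deg))


def bidirectional_edge_count(network: DirectedLabeledNetwork) -> int:
    """Number of reciprocal pairs {(a,b),(b,a)} both present.

    Edge switching does not preserve this quantity; it is reported as a run
    diagnostic, not corrected.
    """
    return sum(1 for t, h in network.edges if t < h and (h, t) in network.edges)


def induced_subnetwork(
    network: DirectedLabeledNetwork, vertex_labels: Iterable[str]
) -> Optional[LabeledSubnetwork]:
    """The subnetwork induced on ``vertex_labels``, or None if not weakly connected.

    The induced subnetwork contains exactly the edges of ``network`` with both
    endpoints in ``vertex_labels``.  A subnetwork with no edges (or a
    disconnected one) is not a pattern and yields None.
    """
    labels = list(vertex_labels)
    vset = frozenset(labels)
    if len(vset) != len(labels):
        raise ValueError("duplicate labels in vertex subset")
    if len(vset) < 2:
        raise ValueError("need at least 2 vertices")
    unknown = [v for v in vset if v not in network.label_set]
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    edges = frozenset(
        (t, h) for t, h in network.edges if t in vset and h in vset
    )
    if not edges or not is_weakly_connected(vset, edges):
        return None
    return LabeledSubnetwork(vertex_labels=vset, edges=edges)


def contains_subnetwork(network: DirectedLabeledNetwork, sub: LabeledSubnetwork) -> bool:
    """True iff ``sub`` is the exact induced subnetwork of ``network`` on its vertices.

    Equivalent to ``sub.key`` being a member of the k-enumeration of the
    network: the edges of ``network`` among the subnetwork's vertices must
    coincide with the subnetwork's edges.
    """
    vs = sorted(sub.vertex_labels)
    edges = network.edges
    sub_edges = sub.edges
    for a in vs:
        for b in vs:
            if a != b and ((a, b) in edges) != ((a, b) in sub_edges):
                return False
    return True


# ---------------------------------------------------------------------------
# File I/O


def read_network_edgelist(path: Path | str, label_set: VertexLabelSet) -> DirectedLabeledNetwork:
    """Read a 2-column TSV edge list (tail TAB head).

    An optional ``tail<TAB>head`` header and ``#`` comment lines are ignored.
    Duplicate edges are deduplicated with a warning (the method works on
    simple graphs; a duplicate in a file is a representation artifact, not a
    multi-edge).  Loops and unknown labels are hard errors.
    """
    path = Path(path)
    edges: set[Edge] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            tail, head = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (tail.lower(), head.lower()) == ("tail", "head"):
                continue
            if tail == head:
                raise ValueError(f"{path.name}:{lineno}: loop edge {tail!r} -> {head!r}")
            for lab in (tail, head):
                if lab not in label_set:
                    raise ValueError(f"{path.name}:{lineno}: unknown label {lab!r}")
            if (tail, head) in edges:
                warnings.warn(
                    f"{path.name}:{lineno}: duplicate edge {tail}>{head} ignored",
                    stacklevel=2,
                )
            edges.add((tail, head))
    return DirectedLabeledNetwork(label_set=label_set, edges=frozenset(edges))


def write_network_edgelist(network: DirectedLabeledNetwork, path: Path | str) -> None:
    """Write a TSV edge list, edges sorted for byte-stable output."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("tail\thead\n")
        for t, h in sorted(network.edges):
            fh.write(f"{t}\t{h}\n")


def read_sample(manifest_path: Path | str) -> NetworkSample:
    """Load a network sample from a YAML/JSON manifest.

    The manifest carries ``name``, the ordered ``labels`` and the per-network
    edge-list ``networks`` paths (relative to the manifest's directory).
    Every network is validated; any violation aborts the load.
    """
    manifest_path = Path(manifest_path)
    with manifest_path.open() as fh:
        if manifest_path.suffix == ".json":
            manifest = json.load(fh)
        else:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ValueError(f"{manifest_path}: manifest must be a mapping")
    for field in ("labels", "networks"):
        if field not in manifest:
            raise ValueError(f"{manifest_path}: missing manifest field {field!r}")
    label_set = VertexLabelSet(tuple(str(lab) for lab in manifest["labels"]))
    paths = manifest["networks"]
    if not paths:
        raise ValueError(f"{manifest_path}: empty sample (no network files listed)")
    networks = []
    for rel in paths:
        net = read_network_edgelist(manifest_path.parent / rel, label_set)
        report = validate_network(net)
        if not report.ok:
            raise ValueError(f"{rel}: invalid network: {'; '.join(report.violations)}")
        networks.append(net)
    return NetworkSample(
        label_set=label_set,
        networks=tuple(networks),
        name=str(manifest.get("name", manifest_path.stem)),
    )
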
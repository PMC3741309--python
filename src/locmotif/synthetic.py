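"""Synthetic samples of effective-connectivity-like networks.

Each sample element is drawn as a directed G(n, p_base) over a fixed label
set (by default the nine EEG electrodes F3..P4), after which each planted
pattern is, with its planting probability, added in full to the element
(set union, so elements remain simple digraphs).  Degree sequences therefore
vary across elements, as they do across subjects in real connectivity
samples.  Defaults mirror the application geometry: 9 vertices and sample
size 16 (one of the study's eight samples had 15 subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import (
    EEG_9_LABELS,
    DirectedLabeledNetwork,
    Edge,
    NetworkSample,
    VertexLabelSet,
    write_network_edgelist,
)


@dataclass(frozen=True)
class SynthesisConfig:
    labels: VertexLabelSet = field(default_factory=lambda: VertexLabelSet(EEG_9_LABELS))
    sample_size: int = 16
    p_base: float = 0.1
    planted: tuple[tuple[frozenset[Edge], float], ...] = ()
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if not 0 <= self.p_base <= 1:
            raise ValueError("p_base must be in [0, 1]")
        norm = []
        for edges, prob in self.planted:
            edges = frozenset(tuple(e) for e in edges)
            if not 0 <= prob <= 1:
                raise ValueError("planting probability must be in [0, 1]")
            for t, h in edges:
                if t == h:
                    raise ValueError(f"planted loop ({t},{h})")
                if t not in self.labels or h not in self.labels:
                    raise ValueError(f"planted edge ({t},{h}) uses unknown labels")
            norm.append((edges, float(prob)))
        object.__setattr__(self, "planted", tuple(norm))


def generate_sample(config: SynthesisConfig) -> NetworkSample:
    """Draw a sample: G(n, p_base) background plus planted patterns.

    Deterministic under ``config.seed``; for each element, each planted
    pattern is either added completely (all its edges) or not at all.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.labels.labels
    pairs = [(a, b) for a in labels for b in labels if a != b]
    networks = []
    for _ in range(config.sample_size):
        mask = rng.random(len(pairs)) < config.p_base
        edges = {pair for pair, keep in zip(pairs, mask) if keep}
        for pattern, prob in config.planted:
            if rng.random() < prob:
                edges |= pattern
        networks.append(DirectedLabeledNetwork(config.labels, frozenset(edges)))
    return NetworkSample(
        label_set=config.labels, networks=tuple(networks), name=config.name
    )


def write_fixture(config: SynthesisConfig, directory: Path | str) -> Path:
    """Generate a sample and write it as edge lists plus a manifest.

    Returns the manifest path; ``read_sample`` on it reproduces the sample
    exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sample = generate_sample(config)
    filenames = []
    width = max(3, len(str(config.sample_size)))
    for i, net in enumerate(sample.networks):
        fname = f"network_{i:0{width}d}.tsv"
        write_network_edgelist(net, directory / fname)
        filenames.append(fname)
    manifest = {
        "name": config.name,
        "labels": list(config.labels.labels),
        "networks": filenames,
    }
    manifest_path = directory / "manifest.yaml"
    with manifest_path.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
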
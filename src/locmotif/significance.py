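"""Significance assignment for subnetwork counts and motif extraction.

A candidate subnetwork's observed count over the sample is tested for
overrepresentation against the degree-sequence-preserving null model.  The
count is modeled as a Poisson-binomial variable: each sample element i
(subject) contributes an independent Bernoulli occurrence with probability
q_i, estimated as the relative frequency of the subnetwork in element i's
own null ensemble.  This respects the per-network degree sequences and
reduces to a binomial when all q_i coincide.  The one-sided tail
P(X >= observed) is computed exactly by dynamic programming.

Testing is one-sided (overrepresentation only) and the familywise error
rate over all candidates is controlled with the Bonferroni-Holm step-down
procedure; false-discovery-rate control is deliberately not offered.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import RunConfig
from .core import (
    NetworkSample,
    bidirectional_edge_count,
    contains_subnetwork,
    subnetwork_from_key,
)
from .enumeration import SubnetworkCountTable, count_over_sample, filter_candidates
from .null_model import (
    NullEnsemble,
    derive_seed,
    estimate_ensemble_size,
    estimate_mixing_parameter,
    generate_ensemble,
    select_representative,
)


@dataclass(frozen=True)
class MotifResult:
    """One candidate subnetwork with its full significance diagnostics."""

    key: str
    observed_count: int
    occurrence_probs: tuple[float, ...]
    p_raw: float
    p_rank: int
    significant: bool
    alpha: float

    @property
    def mean_q(self) -> float:
        return float(np.mean(self.occurrence_probs))


@dataclass(frozen=True)
class DetectionResult:
    """All candidate results of one sample plus resolved run metadata."""

    sample_name: str
    results: tuple[MotifResult, ...]
    metadata: dict

    @property
    def motifs(self) -> tuple[MotifResult, ...]:
        return tuple(r for r in self.results if r.significant)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "key": [r.key for r in self.results],
                "k": self.metadata["k"],
                "observed_count": [r.observed_count for r in self.results],
                "sample_size": self.metadata["sample_size"],
                "mean_q": [r.mean_q for r in self.results],
                "p_raw": [r.p_raw for r in self.results],
                "holm_rank": [r.p_rank for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )


def occurrence_probabilities(
    key: str, ensembles: Sequence[NullEnsemble], k: Optional[int] = None
) -> tuple[float, ...]:
    """Per-sample-element null occurrence probabilities of one subnetwork.

    q_i is the fraction of element i's M realizations whose k-enumeration
    contains the subnetwork, clamped to [1/(M+1), M/(M+1)] so that finite
    ensembles never produce degenerate probabilities of exactly 0 or 1.
    """
    if not ensembles:
        raise ValueError("no ensembles supplied")
    sub = subnetwork_from_key(key)
    if k is not None and sub.k != k:
        raise ValueError(f"key has {sub.k} vertices, expected k={k}")
    sizes = {ens.size for ens in ensembles}
    if 0 in sizes:
        raise ValueError("empty ensemble")
    if len(sizes) != 1:
        raise ValueError(f"ensembles have unequal sizes {sorted(sizes)}")
    qs = []
    for ens in ensembles:
        M = ens.size
        hits = sum(1 for real in ens.realizations if contains_subnetwork(real, sub))
        q = hits / M
        qs.append(min(max(q, 1.0 / (M + 1)), M / (M + 1.0)))
    return tuple(qs)


def poisson_binomial_tail(q: Sequence[float], c_obs: int) -> float:
    """Exact upper tail P(X >= c_obs) for X = sum of independent Bernoulli(q_i).

    Computed by dynamic programming over the count distribution (convolving
    one Bernoulli at a time), so no normal approximation is involved.
    """
    q = np.asarray(q, dtype=float)
    n = len(q)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 <= c_obs <= n:
        raise ValueError(f"c_obs={c_obs} outside [0, {n}]")
    if c_obs == 0:
        return 1.0
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for qi in q:
        nxt = pmf * (1.0 - qi)
        nxt[1:] += pmf[:-1] * qi
        pmf = nxt
    return float(min(1.0, max(0.0, pmf[c_obs:].sum())))


def holm_adjust(
    p_values: Mapping[str, float], alpha: float
) -> dict[str, tuple[int, bool]]:
    """Bonferroni-Holm step-down over a family of raw p-values.

    Sorted ascending, hypothesis j (1-based) is rejected while
    p_(j) <= alpha / (m - j + 1); the first failure stops all further
    rejections.  Returns per key its rank and significance flag.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    items = sorted(p_values.items(), key=lambda kv: (kv[1], kv[0]))
    m = len(items)
    out: dict[str, tuple[int, bool]] = {}
    rejecting = True
    for j, (key, p) in enumerate(items, start=1):
        if rejecting and p <= alpha / (m - j + 1):
            out[key] = (j, True)
        else:
            rejecting = False
            out[key] = (j, False)
    return out


def detect_motifs(
    sample: NetworkSample,
    k: Optional[int] = None,
    config: Optional[RunConfig] = None,
    candidate_keys: Optional[Iterable[str]] = None,
) -> DetectionResult:
    """Full single-sample pipeline: count, filter, randomize, test, adjust.

    When ``candidate_keys`` is given (e.g. a family pooled over several
    samples), it replaces the sample's own min-count filter as the Holm test
    family; keys never observed in this sample are tested with observed
    count 0.  ``Q`` and ``M`` set to ``"estimate"`` trigger the calibration
    procedures on this sample before the ensembles are generated.
    """
    config = config or RunConfig()
    if k is not None and k != config.k:
        config = _with_k(config, k)
    k = config.k
    table = count_over_sample(sample, k)
    if candidate_keys is None:
        candidates = filter_candidates([table], config.resolved_min_count)
    else:
        candidates = set(candidate_keys)
    metadata = {
        "sample_name": sample.name,
        "sample_size": len(sample),
        "k": k,
        "min_count": config.resolved_min_count,
        "alpha": config.alpha,
        "seed": config.seed,
        "n_candidates": len(candidates),
        "bidirectional_edges_input": [bidirectional_edge_count(n) for n in sample.networks],
        "package_version": _pkg_version,
        "python_version": platform.python_version(),
    }
    if not candidates:
        metadata.update({"Q": config.Q if config.Q != "estimate" else None, "M": None})
        return DetectionResult(sample_name=sample.name, results=(), metadata=metadata)

    if config.Q == "estimate":
        rep = select_representative(sample)
        report = estimate_mixing_parameter(
            sample.networks[rep],
            config.Q_grid,
            config.n_per_q,
            alpha=config.alpha,
            reps=config.mc_reps,
            seed=derive_seed(config.seed, "Q"),
        )
        Q = report.chosen_Q
        metadata["representative_index"] = rep
        metadata["uniformity_report"] = report.to_dict()
    else:
        Q = float(config.Q)
    metadata["Q"] = Q

    if config.M == "estimate":
        M = estimate_ensemble_size(
            sample,
            k,
            Q,
            config.B_grid,
            config.B_max,
            config.epsilon,
            seed=derive_seed(config.seed, "M"),
        )
    else:
        M = int(config.M)
    metadata["M"] = M

    ensembles = [
        generate_ensemble(net, M, Q, derive_seed(config.seed, "ens", i), source_index=i)
        for i, net in enumerate(sample.networks)
    ]
    metadata["mean_bidirectional_edges_null"] = float(
        np.mean(
            [bidirectional_edge_count(r) for ens in ensembles for r in ens.realizations]
        )
    )

    p_raw: dict[str, float] = {}
    qvecs: dict[str, tuple[float, ...]] = {}
    observed: dict[str, int] = {}
    for key in sorted(candidates):
        qs = occurrence_probabilities(key, ensembles, k=k)
        c_obs = table.counts.get(key, 0)
        qvecs[key] = qs
        observed[key] = c_obs
        p_raw[key] = poisson_binomial_tail(qs, c_obs)
    adjusted = holm_adjust(p_raw, config.alpha)
    results = tuple(
        sorted(
            (
                MotifResult(
                    key=key,
                    observed_count=observed[key],
                    occurrence_probs=qvecs[key],
                    p_raw=p_raw[key],
                    p_rank=adjusted[key][0],
                    significant=adjusted[key][1],
                    alpha=config.alpha,
                )
                for key in candidates
            ),
            key=lambda r: (r.p_rank, r.key),
        )
    )
    return DetectionResult(sample_name=sample.name, results=results, metadata=metadata)


def _with_k(config: RunConfig, k: int) -> RunConfig:
    from dataclasses import replace

    return replace(config, k=k)
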
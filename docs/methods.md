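# Methods

## Problem and model

The input is a sample of simple directed networks G₁, …, G_S that share one
ordered set of pairwise-different vertex labels (the nine EEG electrodes by
default). A *locatable* pattern is an induced, weakly connected k-vertex
subnetwork identified by its exact edge set — fixed labels make position
part of the pattern's identity, so no isomorphism classes are formed and
patterns of size 2 are already informative. Each pattern occurs at most
once per network; its sample count is the number of networks containing it
as an exact induced subnetwork.

A pattern is a motif when its sample count is significantly larger than
expected under a null model that preserves each network's in- and
out-degree sequence but is otherwise neutral about edge placement.

"Connected" is interpreted as **weak** connectivity (directions ignored),
the standard convention in motif detection; it is a code constant
(`core.is_weakly_connected`), not a run-time option.

## Enumeration

Enumeration scans all C(n, k) vertex combinations per network and keeps
those inducing at least one edge and a weakly connected subgraph. For
dense, small networks (n ≈ 9, k ∈ {2, 3}) this is faster than recursive
extension schemes (ESU), which are deliberately out of scope. Keys are the
lexicographically sorted `tail>head` tokens joined by `|`; keys with zero
count are never materialized. `count_connected_topologies` brute-forces all
2^(k(k−1)) labeled digraphs and is capped at k = 5 to bound run time; the
test suite cross-checks it against the component-counting recurrence.

The candidate filter (count ≥ 4 within at least one analyzed sample for
k = 3, ≥ 1 for k = 2) keeps the test family small and focused on recurring
patterns. The filter threshold is data-analytic, not inferential: it is
applied before any null-model computation.

## Null model

Edge switching exchanges the heads of two uniformly chosen distinct
directed edges and rejects any proposal creating a loop or multi-edge;
rejections count as chain transitions from a network to itself. One
randomization run performs round(Q·m) attempts restarting from the
original network, so ensemble realizations are independent runs rather
than a thinned single chain — this independence is what the
Poisson-binomial significance model assumes. A proposal whose edge pair
shares a tail or a head reproduces the current pair and is counted as an
accepted switch that leaves the network fixed.

Known degenerate behavior is reported, not patched:

* the directed 3-cycle is a fixed point (all three proposals make loops);
* a network of two disjoint edges has a 2-state space in which every
  attempt is accepted, so the state after t attempts depends only on the
  parity of t — pooling runs with odd and even attempt totals (e.g. a Q
  grid containing 0.5 and 1) reveals both states;
* networks with fewer than two edges are returned unchanged with a warning;
* the number of bidirectional edges is not preserved; run metadata reports
  the input and null-ensemble bidirectional-edge counts as a diagnostic.

### Mixing-parameter calibration

For the sample element closest (maximum norm over the concatenated in/out
degree vector, ties to the lowest index) to the mean degree sequence,
realizations are generated for every Q in a grid and pooled — together
with the input network — into a set of pairwise-different networks. Its
size C is a lower bound for the true space size and sets p₀ = 1/C. Per Q,
the performance index X² = Σ over all C categories of
(observed − N·p₀)²/(N·p₀) is compared with the Monte-Carlo (1 − α)
quantile of X² under uniform multinomial sampling (expected counts are
typically too small to trust the asymptotic chi-squared distribution, and
binning has no natural order to exploit). The smallest passing Q wins;
if none passes, the Q minimizing X² is returned with `uniform=False`.
Because C is only a lower bound, the index is conservative in an unknown
direction; the report carries C so this can be judged.

A pooled count of C = 1 is ambiguous: it is genuine (trivial) uniformity
only when no accepted, state-changing move exists at all, which is checked
exhaustively over all edge pairs; otherwise (e.g. a grid of Q = 0 on a
switchable network) the chain simply never moved and the report is
non-uniform. Default grid {1, 3, 10, 30, 100, 300}: empirical practice
puts adequate mixing around 100 attempts per edge, and the smaller values
document the approach to stationarity.

### Ensemble-size calibration

One bootstrap ensemble = one randomization of every sample element. From
B_max bootstrap ensembles a reference distribution D_ref of relative
k-subnetwork frequencies (occurrences over element × bootstrap
realizations) is computed; D_B uses the first B of the same realizations
(nested reuse keeps cost linear). The smallest B in the grid with
sup-norm distance max_key |D_B − D_ref| ≤ ε is returned, else B_max.
Defaults: B grid {100, 250, 500}, B_max 1000, ε 0.02 — chosen so that
frequency errors are an order of magnitude below the candidate filter's
resolution (1/16 per subject); all are configurable and serialized into
output metadata.

## Significance

The null distribution of a candidate's sample count is Poisson-binomial:
element i contributes an independent Bernoulli with probability qᵢ
estimated from *its own* ensemble (fraction of the M realizations whose
k-enumeration contains the key). This respects per-subject degree
sequences and reduces to a binomial when all qᵢ coincide; a
pooled-frequency binomial variant could be swapped in behind
`occurrence_probabilities` if per-element ensembles were ever pooled.
Frequencies are clamped to [1/(M+1), M/(M+1)] so finite ensembles never
yield p = 0 artifacts. The upper tail P(X ≥ c) is computed exactly by
dynamic programming over the count distribution — no normality assumption.

Testing is one-sided (overrepresentation only). The familywise error rate
over the candidate family — pooled across all analyzed samples when
several are supplied — is controlled by the Bonferroni–Holm step-down at
multiple level α (default 0.05); false-discovery-rate control is a
non-goal.

## Synthetic data

`synthetic.generate_sample` draws each element as a directed G(n, p_base)
and then, per planted pattern, adds all of the pattern's edges with the
planting probability (set union, so elements stay simple and degree
sequences vary across elements as across real subjects). Defaults copy the
application geometry: 9 electrode labels, sample size 16 (one study group
had 15). The generator emulates network-level structure only — no
signal-level simulation (VAR models, gPDC estimation), no spatial edge
correlation, no subject-level density differences — so passing tests show
correctness of enumeration, randomization and inference, not robustness to
realistic connectivity estimation noise.

## Numerical and scale choices

* Seeding: a single run seed deterministically derives per-purpose,
  per-element, per-realization child seeds through `numpy.SeedSequence`;
  identical config + seed ⇒ byte-identical outputs.
* Representative-selection ties and Holm ties break deterministically
  (lowest index; lexicographic key).
* The stochastic suite runs at desk scale: type-I control is measured over
  200 unplanted 16-element samples and recovery over 50 planted runs, both
  with M = 500 and a fixed Q = 3 (ample for the sparse m ≈ 7 networks
  involved, where ~20 attempts give ~10 accepted switches on 7 edges);
  the uniformity check uses a degree sequence whose full space (9
  networks) is enumerable by brute force.

## Limitations

* The edge-switching chain is not irreducible for every degree sequence;
  no corrective moves (e.g. triangle reversals) are implemented, matching
  the method being implemented. The calibration reports make
  non-uniformity visible rather than hiding it.
* The distinct-network count is a lower bound; true space sizes are
  generally unknown (upper-bound estimation via adjacency-matrix
  decomposition is out of scope).
* Per-element occurrence probabilities are themselves Monte-Carlo
  estimates; with small M the clamping floor 1/(M+1) limits how small a
  p-value can get, which is conservative.
* Only unweighted, simple, directed networks are supported; GraphML or
  adjacency-matrix input, weighted generalizations, and z-score or FDR
  based significance are non-goals.
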
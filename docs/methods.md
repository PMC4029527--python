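# Methods

## Model and state space

The sampler treats complex prediction as inference over the space of set
partitions of the protein set V of a weighted PPI network G = (V, E, w),
w(e) > 0 encoding interaction reliability (absent pairs have weight 0, self
pairs are excluded). A partition C is scored by f(C) = −(g₁ + g₂ + g₃) and
sampled from P(C) ∝ exp(−f(C)/T) by Metropolis–Hastings; the prediction is
the minimum-f state visited, minus its singleton clusters.

**g₁ — generalized density.** For a cluster c: 0 if |c| = 1; −∞ if |c| > N
or some member has weight 0 to every other member; otherwise
(Σ_{{u,v}⊆c} w(u,v)) / √|c|, each unordered pair counted once. The
unordered-once convention is a deliberate global factor-of-2 choice: an
ordered double sum would scale every finite g₁ uniformly, which only
rescales the effective temperature and the relative strength of g₂/g₃; one
convention had to be fixed and documented, and this is it. The √|c|
denominator grows slowly enough that clusters can absorb additional members
whose edges are weaker than the existing average, which is what lets the
size distribution spread beyond dimers.

**g₂ — size-law regularizer.** ψ_C(i) is the relative frequency of clusters
of size i among clusters of size ≥ 2 (singletons carry no density signal and
are excluded from the denominator; if no cluster of size ≥ 2 exists, ψ_C ≡ 0).
The penalty is −Σ_{i=2..N} (ψ_C(i) − ψ(i))²/(2σ²₂,ᵢ) with target
ψ(i) = i^−γ / Σ_{j=2..N} j^−γ and σ²₂,ᵢ = 1000·1.1⁻ⁱ, so larger sizes are
constrained more tightly. γ = 2 approximates the empirical power-law
exponent of curated complex-size distributions. The regularizer can be
disabled (`g2_enabled = false`), exposing the observation that g₁ and g₃
alone already produce heavy-tailed size distributions.

**g₃ — coverage regularizer.** −(s(C) − λ)²/(2σ₃²) with s(C) the number of
proteins in clusters of size ≥ 2. λ (default 2000) expresses how many
proteins one expects to participate in complexes; σ₃² = 10⁶.

## Proposal distribution and acceptance

Per iteration, u ~ Uniform(V) is (conceptually) removed from its cluster.
With probability β = 0.01 it forms a new singleton (q = β/|V|); otherwise a
destination cluster is drawn with probability proportional to
S(c) = Σ_{i : v_i ∈ c} 1/i², ranks i taken over u's neighbors sorted by
decreasing w(u, v) (ties broken by identifier so ranks are deterministic).
The residue of u's own cluster is a legal destination, so the chain has
self-loops; those count as accepted iterations. A protein with no neighbors
(Z = 0) deterministically becomes a singleton with q = 1/|V|.

Acceptance is computed wholly in log space:
log U < min(0, −Δf/T + log q_rev − log q_fwd). The reverse probability is
evaluated by the same formulas on the proposed state; because removing u
again yields the identical partition-after-removal, S and its normalizer are
shared between directions, making the correction cheap. The full
Hastings ratio is the default because it is required for the chain to
have exp(−f/T)/Z as its stationary distribution (verified by enumeration),
and a `hastings_correction = false` switch provides the plain-Metropolis
variant. Moves creating clusters of size N+1 are proposed normally and
rejected through the +∞ score rather than masked, keeping q computable.
Proposals that would isolate a member (g₁ = −∞) likewise reject via +∞, so
every committed state has finite f.

The initial state clusters the maximum-weight pair (lexicographic
tie-break) and leaves everything else as singletons. Best-state tracking is
first-found-wins on strict improvement; at T = 10⁻⁹ the chain is
near-greedy, so the best state is effectively the hill-climbing endpoint.
"States sampled" means the post-decision state of every iteration.

## Incremental evaluation

A naive f(C) recomputation is O(|V|²); the chain instead maintains per
cluster the member-wise intra-weight sums (floats) and intra-partner counts
(integers). A relocation touches only the two affected clusters for g₁, at
most four histogram bins for g₂, and a constant-time shift for g₃.
Isolation tests use the integer counts — a float-cancellation test
(`sum == 0.0`) is not trustworthy after thousands of incremental updates,
and an early implementation of exactly that kind was caught by the
delta-vs-recompute oracle. When a member's partner count reaches zero its
cached weight sum is reset to exactly 0.0 to stop drift. Cached and
from-scratch scores agree within 1e−9 over 10⁴ random moves (tested);
deltas involving infinite states fall back to full recomputation rather
than subtracting infinities.

## Randomness and reproducibility

One seeded PCG64 generator drives the whole chain, consumed in a fixed
order (protein index, branch uniform, cluster uniform, acceptance uniform,
pre-drawn in blocks of 8192). Identical seeds give byte-identical cluster
files end to end. Derived seeds for sweeps and repeated runs come from
`SeedSequence([base, tag])`, so runs are independent but reproducible.

## Matching statistics

ov(s,t) = |s∩t|/√(|s||t|) if |s∩t| ≥ 2 else 0. The floor exists because two
dimers sharing one protein would otherwise match at 1/√4 = 0.5 > √0.2.
η defaults to √0.2 computed in code, not the rounded 0.4472. Matching is
many-to-many (a cluster may match several complexes and vice versa);
Npc/|C| is precision, Nkc/|K| recall, F the harmonic mean (0 when both
vanish). Size-stratified scores restrict the cluster side for precision
(C|ᵢ vs all of K) and the catalog side for recall (all of C vs K|ᵢ) for
i = 2, 3 and ≥ 4 — taken literally, so a size-5 cluster may serve the
recall of K|₂. Empty strata yield NaN precision with a warning rather than
a silent 0. Clusters of size 1 are dropped before any statistic.

## Enrichment

The p-value of observing ≥ b annotated members in a cluster of size |c|
drawn from a universe of |V| proteins with |M| annotated is the
hypergeometric upper tail, delegated to `scipy.stats.hypergeom.sf` (exact
against full enumeration to 1e−12 for all universes ≤ 12, tested).
Bonferroni correction uses, per cluster, the number of terms with non-zero
overlap — the family an ordinary term-finder tests; per-run correction
would be stricter and is easy to apply downstream by multiplying instead by
the total term count. Annotations are supplied as flat, pre-propagated
term → protein sets; ontology parsing and true-path propagation are out of
scope. Extended precision adds significant-but-unmatched clusters to the
precision numerator, acknowledging catalog incompleteness.

## Synthetic benchmark generator

The generator emulates the statistics the scoring model assumes: complex
sizes i.i.d. from a truncated power law (γ = 2 over sizes 2–10 by default),
disjoint planted complexes, all intra-complex pairs connected with
truncated-normal "high" weights (mean 5, sd 1), sparse background edges
(probability 0.005 per pair) with "low" weights (mean 1, sd 0.3) — a
five-fold separation. Defaults give ≈ 200 proteins: 40 complexes averaging
≈ 3.5 members plus 62 background proteins. It does **not** model degree
heterogeneity, weight mixtures of real reliability scores, bait–prey
sampling artifacts, or overlapping complexes (the predictor outputs a
partition, so overlapping truth would cap recall by construction). Passing
recovery tests therefore demonstrates correctness of the machinery under
the model's own assumptions, not performance on real interactomes.
Truncated normals were chosen as the simplest positive distribution with
controllable separation. Weights are truncated by redraw, preserving
strict positivity without a point mass.

## Study sizes for validation runs

Chain-correctness uses a 5-protein complete graph (52 partitions,
enumerable exactly) at T = 1 with g₂ off and λ, σ₃² chosen so every
partition has finite f; 10⁶ iterations give total-variation distance ≈ 0.01–
0.04 against exp(−f/T)/Z. Recovery experiments run L = 2×10⁵ iterations on
the ≈ 200-protein default benchmark with λ set to the true planted
clustered-protein count — mirroring how λ is tuned on real data — reaching
F ≥ 0.85 across seeds; L scales with network size and 2×10⁵ is comfortably
past saturation at this size. Iteration sweeps on real-scale networks use
the full default L = 2×10⁶.

## Numerical and edge-case choices

* Duplicate edge lines keep the maximum weight (strongest evidence wins);
  re-reading with swapped columns gives the identical network.
* Neighbor-rank ties break by protein identifier ascending — rank enters
  the proposal as 1/i², so determinism here is load-bearing.
* Identifiers are opaque case-sensitive strings; no gene-name mapping.
* Column-shuffle randomization feeds the permuted table back through the
  normal reader, so self-pairs drop and duplicates resolve exactly as on
  input.
* `score_delta` returns +∞ (never NaN) for forbidden finite→forbidden
  moves; −(−∞) propagates as f = +∞ for externally constructed invalid
  partitions.
* Weight parsing rejects non-positive and non-finite values with the
  offending line number.

## Known limitations

* The sampler is single-chain, single-temperature; no tempering or restart
  schedule. At T = 10⁻⁹, different seeds can land in different local
  optima — the mean ± sd reporting of `repeat` quantifies that spread.
* Pure-Python chain: ≈ 10⁵ iterations/s on toy networks, which is ample
  for the validation sizes here but a real ~6000-protein interactome at
  L = 2×10⁶ takes tens of minutes on one core.
* The g₂ delta recomputes the penalty over all N−1 bins per move
  (vectorized); an O(4-bin) update would be faster but was not needed.
* Enrichment treats terms independently; no term-hierarchy awareness.
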
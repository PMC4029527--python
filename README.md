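# complexsampler

Prediction of heteromeric protein complexes from a weighted protein–protein
interaction (PPI) network by Metropolis–Hastings sampling over set
partitions, together with the standard evaluation statistics of the field
(overlap-ratio matching, precision/recall/F-measure, hypergeometric term
enrichment) and a planted-complex benchmark generator.

It is aimed at computational/systems biologists who have a reliability-
weighted interactome (e.g. a WI-PHI-style 3-column table for yeast) and want
partition-based complex predictions plus a self-contained way to validate the
machinery on synthetic data with known ground truth.

## The model

A state is a partition *C* of the protein set *V* into disjoint clusters.
The sampler draws partitions from

&nbsp;&nbsp;&nbsp;&nbsp;P(C) ∝ exp(−f(C)/T),&nbsp;&nbsp;&nbsp;&nbsp;f(C) = −(g₁(C) + g₂(C) + g₃(C)),

where

* **g₁ (generalized density).** Each cluster *c* contributes the sum of its
  intra-cluster edge weights divided by √|c|; singletons contribute 0, and a
  cluster is forbidden (g₁ = −∞) if it exceeds the maximum size *N* or
  contains a protein with no positive-weight partner inside the cluster.
* **g₂ (size-law regularizer).** A Gaussian penalty pulls the relative
  frequency ψ_C(i) of cluster sizes i = 2..N toward a truncated power law
  ψ(i) ∝ i^−γ (γ = 2, matching the empirical size law of curated complex
  catalogs), with size-dependent variance σ²₂,ᵢ = 1000·1.1⁻ⁱ.
* **g₃ (coverage regularizer).** A Gaussian penalty −(s(C) − λ)²/(2σ₃²)
  pulls s(C), the number of proteins inside clusters of size ≥ 2, toward a
  target λ.

Each move relocates one uniformly chosen protein *u*: with probability
β = 0.01 it becomes a new singleton; otherwise it joins cluster *c* with
probability ∝ Σ 1/i² over the ranks *i* of u's neighbors inside *c* (ranks
from sorting u's partners by decreasing weight). Acceptance uses the full
Metropolis–Hastings ratio in log space (the proposal-ratio correction can be
switched off). At the default temperature T = 10⁻⁹ the chain is effectively
a stochastic hill climb; the reported prediction is the minimum-f state seen,
with singleton clusters removed.

Predictions are scored against a catalog *K* of known complexes via the
overlap ratio ov(s,t) = |s∩t|/√(|s||t|) (0 when fewer than 2 proteins are
shared); two sets match when ov ≥ η = √0.2 ≈ 0.4472. Precision is the
fraction of clusters matched to ≥ 1 complex, recall the fraction of
complexes matched to ≥ 1 cluster, F their harmonic mean. Unmatched clusters
can additionally be tested for annotation-term enrichment with an exact
hypergeometric upper-tail p-value (Bonferroni-corrected per cluster), giving
the "extended precision".

## Worked example

Generate a synthetic benchmark (40 planted complexes with five-fold weight
separation over background), run the sampler, and evaluate against the known
truth:

```sh
$ complexsampler simulate --out-network net.tsv --out-truth truth.tsv --seed 1
wrote 205 proteins, 370 edges, 40 planted complexes

$ printf 'iterations = 200000\n"lambda" = 143\n' > run.toml
$ complexsampler predict --network net.tsv --config run.toml --out clusters.tsv --seed 1
best f = -70.1928 at iteration 42896; 42 clusters, 151 proteins, acceptance rate 0.811

$ complexsampler evaluate --clusters clusters.tsv --complexes truth.tsv
Npc=40 Nkc=40 precision=0.952 recall=1.000 F=0.976
```

Here λ = 143 is the number of proteins inside the planted complexes. The
sampler recovers all 40 planted complexes (Nkc = 40, recall 1.0); 40 of its
42 output clusters match a true complex (precision 40/42 ≈ 0.952), and the
best-scoring partition was found after ~43k of the 200k iterations. Each
prediction also writes a `*.manifest.json` with the exact configuration,
input digests and seed needed to reproduce it.

The same operations are available as a library
(`complexsampler.run`, `prf`, `cluster_enrichment`, `generate`, ...), and
`sweep-lambda`, `sweep-iters` and `repeat` drive robustness experiments
(one run per parameter value; mean ± sd over repeated runs).

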
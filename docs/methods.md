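# Methods

## The model

`hmmens` represents each protein family by a nested set of profile HMMs.
The intuition: a single profile built on a large, evolutionarily diverse
seed alignment averages incompatible residue preferences; profiles built
on phylogenetically coherent subsets are sharper, and taking the maximum
bit score over a nested collection lets a query be recognized by whichever
granularity fits it best. The root model on the full seed alignment is
always present, so the ensemble can only add sensitivity relative to the
one-profile-per-family baseline at threshold 0.

### Decomposition

The guide tree is split recursively on its centroid edge — the edge
minimizing ``| |A| − |B| |`` over the induced leaf bipartitions
``(A, B)``. Ties are broken by the lexicographically smallest minimum leaf
label on the smaller side, then by smaller side size, so the hierarchy is
identical across runs and platforms. A subset of size *s* and mean
pairwise identity *p* is split further iff

```
s > hard_floor   and   not (s <= X/100 * n  and  p >= Y/100)
```

* `X` (`max_size_pct`, default 10): maximum decomposition size as a
  percentage of the initial seed size `n`. Larger X stops earlier.
* `Y` (`min_identity_pct`, default 40): minimum average identity, in
  percent, for a small subset to stop. `Y = 0` reduces the rule to a pure
  size criterion; the hierarchy then depends only on the tree and `n`.
* `hard_floor` (default 10): subsets this small never split, so a family
  with ≤ 10 sequences is represented by exactly one profile.

Both X-raising and Y-lowering weakly shrink the hierarchy; the node count
is always odd (1 + 2·splits) and children partition their parent.

**Pairwise identity** is the fraction of columns carrying the same
canonical residue among columns where both rows are non-gap; pairs with no
shared non-gap column score 0, and ambiguity codes (B, Z, X, U, O) never
count as matches — both choices are conservative and bias toward further
splitting of dubious subsets. Mean identity is exact over all pairs up to
100 rows and otherwise the mean of 1,000 pairs sampled without replacement
from a caller-supplied generator, so large families stay cheap and
reproducible.

**Guide trees.** An external newick tree (leaf labels must match the seed
row ids exactly) is used when provided in the manifest. Otherwise a
neighbor-joining tree is built from p-distances, with negative NJ branch
lengths clamped to zero. NJ is a fallback, not a claim about optimality:
the decomposition only consumes the tree's induced bipartitions, which are
fairly robust to the estimator.

### The reference scoring engine

The reference engine makes every test and benchmark self-contained. Its
architecture is a local-alignment profile HMM:

* Match states are the alignment columns with gap fraction < 0.5.
* Match emissions: ``e(a) = (c_a + α f(a)) / (Σ_b c_b + α)`` with uniform
  sequence weights, pseudocount ``α = 1`` and background ``f`` (uniform
  1/20 by default). Ambiguity codes contribute to no residue count and are
  scored at background (zero log-odds). Insert emissions equal the
  background.
* Core transitions (M→M/I/D, I→M/I, D→M/D) are estimated from each
  sequence's state path through the match-column mask with pseudocount 1
  per allowed transition; adjacencies outside the allowed set (D↔I) are
  ignored.
* Locality: uniform free entry ``B → M_k`` with probability ``1/M``, and a
  free-exit hazard ``M_k → E`` of ``1/(M−k+1)`` (learned transitions are
  scaled by the remaining mass), which makes the exit point approximately
  uniform rather than biased toward the model's start. Flanking residues
  are emitted by N/C states at background frequency.
* The score is ``log2 P_fwd(q|model) − log2 P_null(q)`` with a null of
  i.i.d. background residues and geometric length (extension probability
  ``L/(L+1)`` for a length-``L`` query). By default the flank self-loops
  match the null's extension probability, so flank residues are
  score-neutral; a model whose emissions equal the background and whose
  flanks reproduce the null scores exactly 0 bits.

The forward and Viterbi recursions run in log space inside a numba kernel;
the test suite checks the forward score against exhaustive path
enumeration (models with ≤ 3 match states, queries of ≤ 4 residues, within
1e−6 bits) and the forward ≥ Viterbi dominance on random pairs. The
reference engine is a contract-faithful engine in its own right, not a
clone of HMMER's scoring stack (no position-specific weighting, no
Dirichlet mixtures, no E-values); the pyhmmer backend (`engine:
"external"`, default hmmbuild mode, full-sequence bit scores, reporting
threshold opened to E = 1e6 so weak hits remain visible for threshold
sweeps) is the fidelity path for real data. The two engines are
interchangeable behind one contract; "no hit" from the external engine is
treated as −∞, never 0, so a genuine 0-bit hit stays distinguishable from
absence.

### Classification and thresholds

A query's candidate score for family *i* is the maximum bit score over the
family's profiles that exceed ``scale · g_i``; the query goes to the
argmax family, or to UNASSIGNED when every candidate set is empty. Since
``g_i`` is constant within a family, gating before or after the
within-family maximum is equivalent. An effective threshold of 0 — scale
0, an uncurated ``g_i = 0``, or mode "none" — accepts any finite score
(the "no minimum threshold" end of the sweep), so negative reference-engine
scores are still assignable there. Ties break to the lexicographically
smallest family id. Note that raising the scale can change a query's
winning family, not just unassign it: the leading family's cutoff can
exclude it while a lower-scoring family still passes. Raw per-family best
scores are kept alongside assignments so a whole precision/recall sweep
re-gates one scoring pass.

## Evaluation harness

* **Folds**: per family, sequences are shuffled once and dealt round-robin
  into 4 near-equal groups (remainders spread one per fold); fold *f*
  tests group *f* and trains on the rest, so every sequence is tested
  exactly once. Families under 10 sequences are rejected — removing even a
  few sequences from a tiny family distorts it.
* **Fragments**: contiguous substrings of the de-gapped query, length
  ``max(1, floor(fraction · L))``, start uniform; fractions 1, 1/2, 1/4.
* **Precision/recall**: best-hit only. Recall = correct/all queries;
  precision = correct/assigned (undefined when nothing is assigned).
  Unassigned queries therefore hurt recall but not precision.
* **Sweep grid**: scale ∈ {0, 0.25, 0.5, 0.75, 0.9, 1.0} by default,
  giving 5–7 distinct points; interpolation is left to plotting. Subgroup
  points use the *true* family's seed size bin (≤100 / >100) and mean
  identity bin (<20% / 20–30% / ≥30%), which are exhaustive and disjoint.
* **Confusable-family graph**: 10 random sequences per family are scored
  against every other family's single root profile; a mean probe bit
  score (no-hit probes count 0) strictly above 25 in either direction
  draws an undirected edge. Families with degree ≥ 5, plus all their
  neighbors, form the selection. The probe scoring is directional but the
  graph is undirected by construction, and the selection rule is
  idempotent.

## Synthetic data

The generator's purpose is statistical control, not biological realism.
Topologies come from sequential random leaf attachment with exponential
branch lengths; sequences evolve by uniform replacement over the 20
residues (substitution probability ``1 − exp(−rate·b)`` per site per
branch of length ``b``) with indel events at rate 0.05 per site per unit
branch length, split evenly between insertions and deletions of geometric
mean length 2. Indels are tracked as alignment events, so the emitted
seed alignment is the true alignment by construction and no aligner enters
the pipeline. Per family, 75% of sequences form the seed alignment and
25% become held-out queries, mirroring the cross-validation geometry;
fragments are cut from the queries.

Default conditions: 20 families × 40 sequences, root length 80–120.
The tree-height scale is the identity dial; measured across seeds, height
0.030 yields ≈ 0.72 within-family mean identity (the "easy" regime) and
height 0.110 yields ≈ 0.35 (the low-identity regime the stopping rule
targets). Cross-family identity sits near the 1/20 background coincidence
level, so families are statistically separable. The low-identity
fragmentary benchmark in the acceptance script uses 10 families × 40
sequences per replicate over 3 replicate seeds — sizes chosen to exercise
the regime at desk scale.

What the generator does **not** emulate: empirical substitution matrices,
site-rate heterogeneity, domain architecture, alignment error, or
Pfam-scale family counts. Passing tests therefore demonstrate the
machinery's correctness and the qualitative ensemble-vs-single ordering
under controlled heterogeneity — not absolute accuracy on real protein
databases, where curated alignments, realistic substitution processes and
thousands of candidate families make the task much harder.

## Numerical and design notes

* All scoring is in natural-log space (converted to bits at the end);
  ``−inf`` is used freely and `logaddexp` handles it exactly.
* Every stochastic step takes a `numpy` Generator or an integer seed.
  Per-family generators are derived from the global seed plus a SHA-256
  hash of the family id, so adding a family never perturbs another
  family's ensemble.
* Gap dialect: `-` and `.` are normalized to `-` on read and residues are
  uppercased; induced alignments drop columns that are all-gap within the
  subset, which preserves each retained row's residue content.
* Degenerate inputs: single-row families build a one-node decomposition
  without a tree; an alignment whose columns are all gap-dominated has no
  consensus columns and fails loudly; identical rows give an all-zero
  distance matrix and a deterministic (tie-broken) NJ topology.
* Persistence is text-only: decomposition hierarchies and reference models
  as JSON, external models in HMMER's text format, with a configuration
  fingerprint checked on load.

## Known limitations

Reference-engine bit scores are not numerically comparable to HMMER's
(different weighting, priors and null corrections); comparisons across
engines should stay within one engine. The classifier is single-label and
full-sequence — no per-domain hits, no multi-domain architectures, and no
conversion of bit scores to membership probabilities. Longest-edge and
clade-based decompositions are out of scope.
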
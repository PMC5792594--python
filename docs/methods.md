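# Methods

This note documents the models and procedures implemented in `clademiner`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Synthetic data (`clademiner.simulate`)

### What it emulates

A comparative study over 13 species — 5 ingroup species forming a
monophyletic clade (emulating the sampled Asteraceae) and 8 outgroup
species — on a rooted binary guide tree (two ladders joined at the root;
terminal/internal branches 0.05 substitutions/site, clade stems 0.08).
Planted gene families carry controlled sequence structure:

- **Within-subfamily identity** ≥ `within_identity` (default 0.90) and
  **between-subfamily identity** ≤ `between_identity` (default 0.30),
  bracketing the τ = 0.55 clustering threshold with wide margins.
- **Clade-specific families** are evolved only over the ingroup clade
  (a gain on the ingroup stem); by construction they have zero outgroup
  members, which is asserted post hoc.
- **Decoys** are i.i.d. uniform-residue proteins with lengths uniform in
  [200, 800], so a subset deliberately violates the (350, 650) length
  filter and the rest test the E-value filter alone.
- **Domain length** defaults to 400 residues, inside the length window.

### Sequence evolution model

Uniform replacement over the 20 amino acids with per-branch substitution
count `round(rate × branch_length × L)`; a mutated position always changes
(the replacement is drawn from the other 19 residues); no indels. This is
deliberately not a realistic substitution process (no rate heterogeneity,
no exchangeability structure, no indels): its purpose is exact control of
realized identity, for which Hamming fraction is then the correct
positional measure. Consequences: (i) a green mining/clustering test
establishes correct behavior on indel-free, compositionally uniform
sequences, not robustness to alignment ambiguity; (ii) alignment-based
identity can exceed the positional value by a small amount when the
aligner trades gaps for matches, which is why target verification also
uses the alignment measure (below).

### Identity-target enforcement

Two nested bisections, both replaying a fixed per-family random stream so
candidate evaluations are comparable:

1. **Within**: the largest substitution rate whose realized minimum
   within-subfamily identity (Hamming) still meets the floor. A
   `within_identity` of 1.0 forces rate 0 (identical members).
2. **Between**: the smallest number of positions by which each subfamily
   ancestor diverges from the family ancestor such that the realized
   maximum between-subfamily identity meets the ceiling.

The final draw is verified against both bounds using *both* the Hamming
measure and the Needleman–Wunsch identity used downstream (the aligner can
nudge identity up by ~0.01 relative to Hamming); on violation the rate is
damped / the divergence count bumped for up to 8 attempts, after which
generation fails loudly rather than silently missing targets.

### Expression model

FPKM-like values; unit-agnostic (how the original samples were normalized
is unknown, and nothing downstream depends on units). Per gene, a shared
log-normal baseline `exp(N(log 8, 1.2))`; wild and cultivated group means
are the baseline times `exp(N(0, 0.25))` each — correlated across groups
through the shared baseline, emulating the diagonal of a wild-vs-cultivated
mean–mean scatter. Pathway genes (the clade-specific members of the focal
species) draw their baseline from `exp(N(log 8 + 3, 0.5))`, i.e. a ≈20-fold
shift, standing in for the very high expression of flavonoid-pathway genes.
Per-sample noise is `exp(N(0, 0.4))`, independent per column. Defaults: 5
wild and 6 cultivated samples. Zeros are permitted; a pseudocount of 1.0 is
added before any log transform downstream. The shift/noise choices were
made once, a priori, to represent a strong pathway-expression signal over a
typical FPKM spread; the Monte-Carlo test (pathway group means above the
global median in both groups in ≥ 95% of seeds) checks the stated world,
not a tuned one.

### Kinetics

`rates = kcat·E₀·S/(Km+S) × (1 + N(0, noise_sd))`, clipped at 0;
`noise_sd = 0` gives the closed form exactly. Concentrations must be
positive and distinct (replicate information is carried by the noise
model, not by repeated concentration rows).

## 2. Domain search (`clademiner.domains`)

Scoring is an ungapped sliding window of per-position log-odds
`log2((count + 1)/(n + 20) / background)` built from a seed alignment
(gap-majority columns dropped; background from alignment composition
unless supplied). A full profile HMM would add insert/delete states the
indel-free synthetic domain never exercises; the ungapped model keeps the
null calibration exact, and the `--domtblout` importer is the escape hatch
for real searches with real profile HMMs.

**Null model and E-values.** For each protein, `n_shuffles` (default 200)
residue shuffles of that same protein are scanned; the per-sequence tail
probability is

```
p(score) = min( max(#null ≥ score, 1) / n_shuffles ,  GumbelSF(score; μ̂, β̂) )
```

with (μ̂, β̂) fitted to the null best-window scores by the method of
moments. Rationale: the empirical rank is assumption-free but floored at
1/n_shuffles, which can never clear an E < 10⁻¹⁰ cutoff; the Gumbel right
tail — the asymptotic law for maxima of window scores — extrapolates below
the floor for far-outlier scores while agreeing with the empirical rank
inside the bulk to Monte-Carlo error. The minimum of two non-increasing
functions keeps E-values monotone in score. E-values are scaled to the
database size (number of sequences searched) by `search_proteome`;
`scan_sequence` alone reports the per-sequence value.

**Filters.** E < `e_max` and `len_lo` < protein length < `len_hi`, all
strict, applied to the whole protein (not the hit span). Defaults 10⁻¹⁰
and (350, 650). Filtering is order-preserving and idempotent.

The threshold is assumed to apply per sequence (one best hit per gene); a
per-domain reading would only matter for multi-domain architectures the
generator does not produce.

## 3. Identity, trees, subfamilies (`clademiner.phylo`)

**Pairwise identity**: Needleman–Wunsch global alignment, BLOSUM62, gap
open 10 / extend 1, terminal gaps free; identity = identical aligned pairs
/ alignment columns excluding terminal-gap columns. The denominator choice
is the conventional coverage-robust one: tolerant of length differences,
still penalizing internal indels. When several alignments are co-optimal
the identity of the first enumerated one is reported; the argument pair is
canonically ordered first so the function is exactly symmetric. Scoring
parameters are fixed and recorded in `IdentityMatrix.params`.

**Neighbor joining**: Saitou–Nei agglomeration with deterministic
tie-breaking (smallest index pair). Negative branch-length estimates are
clamped to zero with the deficit moved to the sibling edge, preserving
path lengths through the joined pair; termination uses the three-taxon
closed form. On additive matrices the algorithm is an exact inverse
(realized path lengths reproduce the input; tested at 1e-9).

**Midpoint rooting before partitioning.** NJ returns an unrooted topology;
its final trifurcation is an artifact and can fall *inside* a genuine
cluster, which would break any clade-based criterion. `subfamily_tree`
therefore midpoint-roots the NJ tree (root at the midpoint of the longest
leaf-to-leaf path — in a superfamily tree, an edge between the most
divergent clusters). Midpoint rooting preserves all path lengths.

**Subfamily criterion.** Root-to-tip traversal accepting the first
(maximal) clade in which every leaf pair has identity strictly > τ
(default 0.55); leaves failing with all neighbors become singletons. This
all-pairs ("complete-linkage-like") reading is the strictest
operationalization consistent with a dual tree-plus-identity criterion;
an average-linkage reading would merge more aggressively. The output is
always a partition.

**Orthology.** Per species pair, best hits by global-alignment score (ties
keep all co-optimal partners); reciprocal best hits form a graph whose
connected components are kept only if they contain exactly one gene per
species across *all* species and every cross-species pair in the
component is itself an RBH edge. Equal-scoring in-paralogs therefore
knock their component out of the one-to-one set, by design.

**Species tree.** Species-pair distance = mean (1 − identity) over
one-to-one ortholog groups; NJ on that matrix. The bootstrap resamples
ortholog groups (genes) with replacement — not alignment sites, since no
concatenated alignment exists in a pairwise-identity framework — with
default 100 replicates; supports are the percentage of replicates
containing each internal bipartition (unrooted comparison).

## 4. Specificity calls (`clademiner.specificity`)

`specific ⇔ member species ⊆ ingroup`. No minimum ingroup-species count is
required by default (a subfamily private to one ingroup species is still
specific, matching the set-inclusion definition); `min_ingroup_species`
exposes the stricter alternative. Every summary carries a caveat string:
specificity is relative to the sampled outgroup, so the true
clade-specific set is likely a subset of the called one. Class counts for
a focal species are asserted to conserve totals (genes sum to the focal
superfamily size, subfamilies to the focal subfamily count).

## 5. Expression prioritization (`clademiner.expression`)

Group means are arithmetic means over the group's columns, computed on a
canonical C-contiguous array so results are bit-reproducible regardless of
how the table was materialized. The class comparison is a two-sided
Wilcoxon rank-sum on log₂(mean_all + 1): exact enumeration when both
classes have ≤ 20 tie-free values, otherwise the normal approximation with
tie correction and continuity correction. "Highly expressed" has no
published threshold, only a shortlist size — so ranking is top-*k* by raw
mean over all samples (*k* = 36 by default), ties broken lexicographically
by gene id; the log transform is monotone and does not affect ranking.

## 6. Kinetics and yields (`clademiner.kinetics`)

Michaelis–Menten by `scipy.optimize.curve_fit` (Levenberg–Marquardt),
initialized from a Lineweaver–Burk double-reciprocal regression on the
positive-rate points, with up to five multiplicatively perturbed restarts;
standard errors from the Jacobian at the optimum; R² on raw rates. At
least 3 distinct concentrations are required. A Km estimate more than
100× outside the sampled concentration range raises a warning flag rather
than an error. Units are fixed (µM, µM/s, µM enzyme), making kcat = V/[E]₀
dimensionally forced in s⁻¹.

Yield arithmetic: specific yield = titer/DCW (or supplied directly), fold
change = specific yield / baseline with the display value rounded half-up
to 2 decimals (raw ratio kept), intracellular % = 100 − extracellular %,
total titer = Σ components. Molar conversions require a caller-supplied
molecular weight — no compound table is hard-coded.

## 7. Pipeline (`clademiner.pipeline`)

Single dataclass config (YAML-loadable); stages mine → cluster →
specificity → rank; every stage's counts and all parameters (except the
output path) are echoed into `report.json`, which contains no timestamps
or absolute paths and is therefore byte-identical across reruns with the
same config and seed. Failures raise `StageError` naming the stage;
artifacts of completed stages are retained. In synthetic mode the profile
is built from each planted family's seed alignment (its subfamily-ancestor
sequences); in files mode, inputs are a fixture directory as written by
`write_fixture`.

## Numerical choices

- Strict inequalities wherever the published filters are strict
  (E < 10⁻¹⁰; 350 < L < 650; identity > 0.55).
- NJ symmetry tolerance 1e-8 on input; additive-inversion test tolerance
  1e-9; identity-matrix symmetry 1e-12.
- All randomness flows through `numpy.random.SeedSequence` children of the
  caller's seed; no global state.
- Shuffle-null E-values use ≥-with-1e-12-slack when counting exceedances,
  so a self-match is counted against its own permutation copies correctly.

## Known limitations

- No indel realism, codon structure or rate heterogeneity in the
  generator; mining/clustering green lights say nothing about alignment
  ambiguity on real proteomes.
- The ungapped profile scan is not a profile HMM; for real Pfam searches,
  import hmmsearch domtbl output instead.
- Subfamily partitioning depends on the midpoint root; a pathological
  family whose deepest split is *within* a subfamily (impossible under the
  generator's margins, rare in practice) could be oversplit.
- The species-tree bootstrap resamples genes; with few ortholog groups the
  supports are coarse (resolution 100/n_boot).
- The rank-sum exact path is limited to small tie-free samples; ties push
  it to the asymptotic approximation even at small n.
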
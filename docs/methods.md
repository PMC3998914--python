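# Methods

This note documents the models, numerical choices and limitations of
`otuecs` in enough detail to reproduce or audit any number the package
emits.

## Distance model

Distances are computed on a fixed multiple alignment; the package never
aligns. For two aligned rows, columns gapped in **both** sequences and
columns where either sequence carries `N` are skipped outright (`N` is
treated as carrying no signal either way, so it affects neither the
numerator nor the denominator). The remaining columns are matches,
mismatches, or gapped in exactly one sequence, and

    distance = (mismatches + gap_events) / (matches + mismatches + gap_events).

Three calculators differ only in `gap_events`:

* **gap** — each one-sided gap column is one mismatch;
* **onegap** (default) — each *maximal run* of consecutive one-sided gap
  columns, gapped in the same sequence throughout, is one event, so a
  multi-column indel counts once;
* **nogap** — one-sided gap columns are skipped.

Two conventions are fixed deliberately: a skipped column (both-gap or
`N`) terminates a gap run, and two abutting runs gapped in *different*
sequences are two events. Including `gap_events` in the denominator
keeps the distance within [0, 1] even for gap-dominated pairs. For any
pair, `nogap ≤ onegap ≤ gap`. A pair with zero comparable columns has no
defined distance and raises an error rather than returning a sentinel.

## Clustering

Agglomeration is exact: the full condensed distance matrix is held in
memory (the intended scale is up to ~20,000 sequences; there is no
out-of-core mode) and each step merges the globally closest pair under
the linkage rule — minimum (single), maximum (complete), or the
unweighted arithmetic mean over all inter-cluster leaf pairs (average,
i.e. UPGMA). Ties are broken by lowest creation-order index (leaves
first, in input order; merged clusters numbered consecutively), which
makes dendrograms deterministic and platform-independent.

Cutting at nominal similarity `t` applies every merge with height
`≤ 1 − t`, inclusive with an absolute tolerance of 1e-12, so a pair at
exactly the threshold similarity clusters; the boundary convention is
pinned down because an off-by-one here changes the total OTU count N.
Partitions may also be extracted at an exact cluster count (`cut_n`),
which is how methods are compared at matched N. Average-linkage cuts
below 92% similarity are legal but logged, since deep UPGMA heights are
size-weighted averages and are harder to interpret as identity
thresholds.

## Ecological signals

Four binary feature constructions per sequence:

* **terms** — normalized free-text keywords (lower-cased,
  edge-punctuation-stripped, stop-list applied; the stop-list is a
  shipped editable text file). The normalization is intentionally
  simple; no claim is made that it reproduces any particular curated
  keyword list.
* **envo** — ontology term ids expanded with every `is_a` ancestor,
  ontology roots excluded, so sibling terms (e.g. 'lake', 'pond') share
  their common ancestor (e.g. 'water body'). Ids missing from the
  ontology are kept unexpanded with a warning.
* **sampling_site** — one feature per sampling event, the unique
  combination of submitting authors, publication title and isolation
  source after case/whitespace normalization.
* **host_taxonomy** — every taxon name along the host lineage (full
  lineages, not terminal taxa only, so related hosts share ancestral
  features); records without a host get the single feature `NON_HOST`.
  Taxa are matched by name; no taxonomy service is consulted.

Sequences lacking a given signal are excluded from that signal's
universe, hence from the background frequencies p_j, the effective OTU
sizes n_i and the counts k_ij. Including them as all-zero rows would
deflate every p_j and change every likelihood; exclusion treats missing
annotation as missing data, not as absence. Background frequencies are
computed on the dataset actually scored, so a subset run uses subset
frequencies.

## The score

All likelihood math is in natural-log space via log-gamma (OTU sizes up
to 10^6 would overflow the binomial coefficient otherwise). The summed
log-likelihood runs over every feature in every OTU including k = 0
cells; those are folded in analytically as `n_i · ln(1 − p_j)`, so the
sparse non-zero counts are all that is ever materialized. Features with
p_j = 1 contribute ln(1) = 0 and are checked for consistency (any
k < n under p = 1 indicates inconsistent inputs and errors).

The null shuffles the sequence→OTU mapping uniformly with OTU sizes
fixed, moving each sequence's whole feature set as a unit — per-feature
independent shuffling would destroy inter-feature correlation and
inflate the null variance, and is rejected. The default is R = 1000
replicates; σ_rand uses the population convention (ddof = 0), fixed for
reproducibility rather than statistical necessity. A constant null
(single OTU, permutation-invariant features) raises a degenerate-null
error instead of producing ±inf.

Sign convention: a consistent partition concentrates features, so its
LL is *more negative* than the null mean. The reported score is
`ecs = (mu_rand − LL_obs) / sigma_rand`, positive for
more-consistent-than-chance partitions; the raw Z with the opposite
sign is reported alongside as `z`, and `abs_z` for convenience.

What the Z-normalization does and does not buy: random partitions score
mean ≈ 0, sd ≈ 1 regardless of dataset size, OTU count or size
distribution — that is the baseline correction that makes scores
comparable across partitions of the same data. It does **not** make the
score of a *consistent* partition invariant to dataset size: duplicating
a dataset roughly doubles the score, as for any Z statistic
(signal grows linearly, null sd sub-linearly). Comparisons should
therefore be made across partitions of the same sequences, at matched
total cluster counts when comparing methods.

ECS variability is estimated by a delete-one-block jackknife: the
universe is split into `blocks` (default 20) equal random groups,
each is dropped in turn, p_j / n_i / k_ij are re-derived on the
remainder and the score recomputed; the reported coefficient of
variation is the jackknife standard error over the absolute mean of the
block estimates. The block count is a configuration knob, and the
scheme is this package's own design choice for a block jackknife over
sequences.

`ecs_series` scores a family of partitions of the same sequences and
sorts by total cluster count N (including singletons), which compares
methods better than nominal thresholds; one shared derived sub-seed is
used for all rows so identical partitions receive identical scores.

## Similarity analyses and monophyly

The ecology-vs-sequence-similarity curve samples `n_subsets` random
subsets (default 20 × 10,000; clamped with a warning on smaller data),
computes all within-subset pairs of (sequence similarity, Jaccard index
of feature sets), bins by similarity, and averages per-bin means over
subsets, reporting the between-subset sd. Ids are sorted before seeded
sampling, so input order is irrelevant. Habitat-type similarity is the
same Jaccard on singleton habitat sets (1 if shared, else 0) — a
degenerate case, not special code.

Within-group similarity distributions are computed over all pairs, with
a seeded uniform without-replacement cap (default 150,000 pairs) for
large groups. Group-vs-background coherence uses the one-sided
(greater) Mann-Whitney-U test from scipy; a constant pooled sample
returns p = 1 with a warning.

Monophyly uses the unrooted convention: an OTU is monophyletic iff its
leaf set is exactly one side of some edge-induced bipartition of the
reference tree (equivalently, its complement is). The rooted MRCA test
would misclassify complement clades under an arbitrary root, which
matters for ML trees whose root carries no meaning. Singleton OTUs are
excluded from numerator and denominator; sequences absent from the tree
are dropped with a warning; the full leaf set passes trivially.

## Synthetic data

The generator emulates clade-structured aligned sequences whose habitat
labels are conserved within clades at a tunable strength, so the whole
pipeline is testable without external data. Topology is deliberately
star-within-star — ancestor → clade consensus → tips, all sites
independent, substitutions uniform over the three other residues —
because it keeps the expected within- and between-clade identities in
closed form (`expected_identity`; per-branch channel
`M(s) = (1 − 4s/3) I + (s/3) J`, tips from a common source through
channels (a₁,b₁), (a₂,b₂) agree per site with probability
`(a₁+b₁)(a₂+b₂) + 3b₁b₂`). Gap injection is columnar Bernoulli, enough
to exercise the three distance calculators without modelling indel
evolution.

Each clade gets a home habitat assigned by cycling through the habitat
list (balanced, and distinct whenever clades ≤ habitats; random homes
would let clades collide and muddy the conservatism dial). A sequence
inherits its clade's home habitat with probability ρ and otherwise
draws uniformly from all habitats; each habitat emits a fixed term set
into the annotation table, and one sampling event is assigned per
(clade, habitat) pair. A Newick of the true topology is emitted for
monophyly tests. Defaults (20 clades × 50 sequences, L = 300, within-
clade substitution 0.015, between 0.04, ρ = 0.9) describe a modest
survey of related genera with strong niche conservatism.

What passing tests on this generator do and do not show: they validate
the statistic's calibration, monotonicity in ρ, and the qualitative
ranking of linkage regimes under niche conservatism. They do not show
robustness to features of real annotation data — correlated and
hierarchical vocabulary, extreme sampling bias, chimeras, alignment
error — which the generator does not model.

## Validation experiment sizes

The behavioural test suite uses desk-scale configurations chosen to
keep the full run in a few minutes while leaving the effects far above
Monte-Carlo noise: null calibration over 200 random partitions of 150
sequences (R = 200); linkage comparison on 20 clades × 50 sequences at
ρ = 0.9 with between-clade identity ≈ 92% and within ≈ 97% (roughly
genus-level divergence, so the 93–98% threshold range spans the
lump-to-split regime), 20 seeds, scored at matched N with R = 120; the
conservatism sweep on 10 clades × 30 sequences over
ρ ∈ {0, 0.25, 0.5, 0.75, 1} with 10 seeds each.

## Known limitations

* Exact clustering is quadratic in memory and cubic-ish in time; the
  package targets thousands, not millions, of sequences. The heuristic
  clusterers it is designed to evaluate (greedy seed-based methods) are
  not re-implemented — their partitions are ingested via the readers.
* Term normalization is lexical only; synonym resolution beyond the
  ontology signal is out of scope.
* The jackknife block design is a reasonable default, not a canonical
  scheme; cv values depend mildly on the block count.
* The negative tail of the score (partitions *anti*-correlated with
  ecology) is reported as-is but has no established interpretation.
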
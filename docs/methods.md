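# Methods

This note records the model behind `cnvpost`, the conventions and defaults
it commits to, and what its synthetic benchmarks do and do not demonstrate.

## Coordinates, breakends and adjacency signatures

All internal coordinates are 0-based, half-open; conversion from the
1-based variant-call format happens exactly once, at read time, and is
self-inverse (VCF → internal → VCF reproduces the original positions).
A breakend position is a *boundary* coordinate: a `RIGHT_ANCHORED` (`+`)
breakend at boundary `b` keeps the reference bases `< b`; a
`LEFT_ANCHORED` (`-`) breakend keeps bases `≥ b`. The bijections to VCF
bracket notation and BEDPE strands are documented in `cnvpost.model`.
Adjacencies are stored with both mates together, in a canonical order
(natural chromosome order, then position, then orientation), so equality
is representation-independent.

Event signatures in boundary coordinates:

| event | adjacencies |
|---|---|
| deletion `[s, e)` | `(s +, e -)` |
| tandem duplication `[s, e)` | `(s -, e +)` |
| insertion at `p` | `(p +, p -)` with attached sequence |
| dispersed duplication, copy of `[s, e)` at downstream `p` | `(s -, p +)` + `(e +, p -)` |
| … copy at upstream `p` | `(p +, s -)` + `(p -, e +)` |
| … copy on another chromosome at `p` | `(s -, p +)` + `(e +, p -)` across chromosomes |

These were derived by walking the rearranged sample genome across each
junction. For the interchromosomal case the classifier accepts either
assignment of opposite orientations on the acceptor side, since caller
dialects are not uniform in how they orient translocation-style breakend
pairs; the template is always delimited by the two donor-side breakends.

Dispersed duplications with an *inverted* copy have same-orientation
signatures (`(+,+)` + `(-,-)` sharing a breakpoint). These are excluded by
default — indistinguishable in practice from inversion breakends without
further evidence — and recognized only under
`ClassificationConfig(allow_inverted_ddup=True)`.

## Clustering and classification

Same-tool adjacencies whose breakpoints co-locate within
`cluster_window = 10 bp` on either end are clustered by single linkage.
The implementation is a sorted sweep over breakend positions with
union-find (consecutive positions within the window are unioned), which is
provably identical to the quadratic pairwise closure; the test suite and
acceptance script verify this against an independent O(n²) oracle.

Within a cluster, dispersed-duplication pairs are sought first. When a
cluster contains several candidates, pairs are resolved greedily by
smallest shared-breakpoint distance with leftmost-template tie-breaking;
each adjacency joins at most one pair. A recognized pair whose template is
below `min_size = 50 bp` is *consumed* and excluded (`below_min_size`),
never reinterpreted as a deletion plus tandem duplication: the joint
signature has already explained both junctions. Remaining adjacencies are
classified in isolation; anything unclassifiable (inversion-like pairs,
lone interchromosomal breakends) is kept in an excluded side channel with
a reason code, so the input always partitions exactly into calls plus
exclusions.

A breakend pair with an explicitly unknown inserted sequence is read as an
insertion only if its breakends lie within `insertion_site_tolerance =
10 bp` (the cluster window reused; there is no independent tolerance
budget). Insertions with unresolved sequence carry an `UNKNOWN` size
sentinel that cannot enter arithmetic — missingness is a classifier
feature, never a fake zero.

## Merging

Pairwise mergeability: same type, same chromosome, breakpoints within
`breakpoint_window = 1000 bp` on both ends, reciprocal overlap ≥
`min_reciprocal_overlap = 0.5` (not applied to insertions), insertion
sites within `insertion_site_window = 10 bp` (insertions and dispersed
duplications only). For dispersed duplications the window and overlap
tests act on the template and the site test on the insertion point — the
only reading under which all four conditions can apply to that type. Both
the window and the overlap test are always applied, even where one seems
to imply the other for small calls.

Merging takes the transitive (single-linkage) closure of the pairwise
relation: the union-region semantics extends naturally to chains, and the
components are verified against a brute-force closure oracle. Calls from
the *same* tool that survived reclassification as distinct calls are also
eligible; the tool-provenance set disambiguates, and within-tool survivors
would otherwise double-count. Merged support is the median of donor
supports (even count: mean of the central pair, kept as a real number to
preserve information for the classifier); the merged insertion point is
the rounded median of donor insertion points; the merged region is the
minimal interval covering all donors.

## Random-forest filter

Features per merged call: type one-hot (4), `log10` size plus a
`size_known` indicator (0/0 for unknown-size insertions), number of
concordant tools, four per-tool flags, and median paired-end, split-read
and total support — the feature matrix is schema-driven so columns can be
added without code changes. The forest's score is the mean positive-class
probability over trees, a posterior true-positive estimate in [0, 1];
`filter_by_score` keeps calls with score ≥ cutoff (default 0.5, the Bayes
threshold under equal costs, used only when the user gives none).

Hyperparameters are grid-searched with stratified 10-fold
cross-validation (stratification guards the rare classes, e.g. dispersed
duplications, from starving folds), optimizing plain unweighted validation
accuracy; exact ties prefer the smallest forest, then the shallowest
trees. The default grid is `n_estimators ∈ {100, 250, 500}`,
`max_depth ∈ {unbounded, 5, 10}`, `max_features ∈ {sqrt, all}`, and is
config-exposed. One seed fixes fold assignment and tree randomness, so a
run is bit-reproducible. Held-out evaluation always splits by chromosome:
calls on the held-out chromosomes form the test set, preventing leakage
between physically linked calls. A single model is trained on the pooled
training set; sample/species identity is deliberately not a feature.

## Auxiliary filters

Default-off, intended for samples genetically distant from the reference
or for gappy assemblies. Depth: a deletion is kept iff its normalized
median depth (call-region median / chromosome median) is ≤ 0.75, a
duplication iff ≥ 1.25, and any call with raw median depth > 1000× is
removed as a collapsed repeat; insertions are untestable by dosage and
pass through. The ratio thresholds are this package's own defaults, chosen
to sit between the expected heterozygous (~0.5 / ~1.5) and unaffected
(~1.0) modes, and are prominently config-exposed. Gap: calls whose 400 bp
flanks (upstream of the 5' breakend, downstream of the 3'; clipped at
chromosome ends with the denominator adjusted) contain more than 50 % N
are removed; the call interior is not examined. Removal uses strict
inequality so boundary values survive, and both filters are idempotent
subset operators. Depth arrives through a provider contract (in-memory
arrays or a bedgraph-style track); computing depth from alignments is
delegated to standard external tooling.

## Simulator and evaluator

The simulator operates at the adjacency/VCF signal level — it emits the
exact adjacency footprint of each spiked-in event rather than reads, which
keeps the full pipeline testable in seconds without alignment. Events are
placed uniformly at random by rejection sampling, non-overlapping by
construction, at least 1 kb apart (so distinct events cannot co-cluster),
with sizes log-uniform over [50 bp, 100 kb] by default; all parameters,
including ploidy, allele-dosage distribution and the intra-/inter-
chromosomal split for dispersed duplications, are configurable, and one
seed governs all randomness.

Caller emulation models the behaviours that matter downstream: per-type
detection probability scaled by `dosage / ploidy` (variants on fewer
haplotypes have proportionally less supporting coverage), integer
breakpoint jitter drawn from a Gaussian truncated at ±3σ (so a nominal
jitter stays bounded), Poisson support counts at dosage-scaled coverage,
per-Mb false-positive adjacencies, and — the key mis-representation —
`split_ddup`: the two adjacencies of a dispersed duplication are emitted
independently with no linkage, exactly what adjacency-in-isolation callers
produce. What the emulation does *not* model: alignment artefacts,
coverage waves, repeat-mediated ambiguity, or caller-specific breakpoint
biases. Passing benchmarks therefore demonstrate the correctness of the
post-processing logic under its stated signal model, not end-to-end
performance on real sequencing data.

Evaluation matches predictions to truth greedily, best reciprocal overlap
first with deterministic leftmost tie-breaking, one-to-one, same type
required; deletions/duplications need ≥ 50 % reciprocal overlap (dispersed
duplications additionally insertion points within 100 bp), insertions
match on insertion-point distance alone. Precision over an empty
prediction set is reported as missing (NA), never zero.

## Problem sizes and numerical choices

The shipped benchmarks use desk-scale analogues: a 10 Mb synthetic genome
with ~100 events (≥ 50 dispersed duplications) for the correction
benchmark, 2 000 labeled calls with a 10 %-noisy planted labelling rule
for the classifier benchmark (the noise bounds attainable accuracy near
0.90), 30 events × 10 seeds per dosage level for the tetraploid dosage
sweep, and 100 random instances of ≤ 100 elements for the oracle
equivalences. The acceptance script uses a reduced hyperparameter grid
(`n_estimators ∈ {100, 250}` × `max_depth ∈ {unbounded, 10}`, sqrt
features) — a subset of the default grid that recovers the planted rule
identically — so a full run completes in well under a minute on one CPU.

Degenerate inputs are handled explicitly: empty VCFs and empty call sets
produce empty outputs with success status; a cutoff outside [0, 1], a
single-class training set, an empty train/test partition, a zero
chromosome-median depth, and an over-dense simulation request are all
errors, not silent defaults.

## Known limitations

- The adjacency-orientation → type mapping covers the four CNV types and
  their dispersed-duplication compositions; nested or complex events and
  balanced rearrangements are recognized only to be excluded.
- Caller dialect field maps (which INFO/FORMAT keys hold PE/SR evidence)
  ship as editable defaults and will need adjustment across caller
  versions; sample-level counts are preferred where both exist.
- Multi-sample VCFs are out of scope (the first sample's FORMAT fields are
  used); genotyping/copy-number estimation is not attempted.
- The trained filter is only as good as its labels; the package provides
  the training machinery and a planted-rule validation, not a pre-trained
  model.
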
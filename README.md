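# cnvpost

Post-processing, ensemble merging and random-forest filtering of copy-number
variant (CNV) calls from short-read structural-variant callers.

## The problem

Short-read SV callers (Delly, GRIDSS, LUMPY, Manta) each emit VCF, but they
encode calls and read evidence differently, and — critically — callers that
interpret each *novel adjacency* in isolation systematically mis-report
**dispersed duplications**. A copy of a template `[s, e)` inserted at a
distant site `p` imprints two adjacencies on the sample genome:

- the junction *into* the copy looks like a tandem-duplication adjacency
  spanning `[s, p)`, and
- the junction *out of* the copy looks like a deletion adjacency spanning
  `[e, p)`.

Processed independently these become an overlapping pair of large false
positives — often tens of Mb — while the real event (a duplication of
`[s, e)`, frequent in plant genomes rich in copy-and-paste transposable
elements) is missed entirely.

`cnvpost` addresses this for anyone integrating multiple SV callers on
plant (or other) genomes: it converts each caller's output into novel
adjacencies, clusters same-tool adjacencies whose breakpoints co-locate
(≤ 10 bp), reclassifies every cluster into one of four CNV types
(DEL, INS, TDUP, DDUP ≥ 50 bp, everything else excluded with a reason
code), merges concordant calls across callers, and filters the merged set
with a random-forest classifier.

## Method summary

**Reclassification.** An adjacency is a pair of oriented breakends
`(chrom, pos, ±)` joined in the sample but not the reference. Signatures:
`(+,-)` on one chromosome = deletion, `(-,+)` = tandem duplication, a
breakend pair carrying inserted sequence = insertion, and a
TDUP-like/DEL-like pair sharing a breakpoint (≤ 10 bp) = dispersed
duplication with template `[s, e)` and insertion point `p` (mirrored
upstream and interchromosomal signatures included). If only one adjacency
of a dispersed duplication is detected, the survivor is reported as the
deletion or tandem duplication its own signature spells.

**Merging.** Calls merge iff they have the same type, breakpoints within
1000 bp on both ends, ≥ 50 % reciprocal overlap (skipped for insertions)
and insertion sites within 10 bp (insertions and dispersed duplications).
Merging is the single-linkage closure; a merged call covers the union of
donor regions (donors covering positions 12–30 and 14–32 merge to 12–32),
with median donor support per signal and the union of donor tool sets.

**Filtering.** Each merged call is featurized (type one-hot, log10 size
with an explicit unknown-size flag, caller concordance, per-tool flags,
median PE/SR support) and scored by a random forest whose hyperparameters
(`n_estimators`, `max_depth`, `max_features`) are grid-searched with
stratified 10-fold cross-validation; the score is a posterior
true-positive probability in [0, 1] and calls below a user cutoff are
dropped. Evaluation splits by held-out chromosomes, never random rows.
Optional, default-off auxiliary filters remove calls without the expected
read-depth dosage signal or with N-rich (assembly-gap) 400 bp flanks.

**Simulation.** A built-in simulator spikes non-overlapping CNVs into a
synthetic genome, derives each event's exact adjacency signature, and
emulates caller behaviour (dosage-scaled detection, breakpoint jitter,
false positives, and the split-adjacency mis-representation of dispersed
duplications), so the whole pipeline is testable without read data.

## Worked example

The canonical mis-call: a caller reports a tandem duplication over
`chr1:[10000, 50000)` and an overlapping deletion over
`chr1:[12000, 50001)` — the two-adjacency footprint of a 2 kb dispersed
duplication.

```python
from cnvpost import reclassify
from cnvpost.model import Breakend, Orientation, canonicalize_adjacency

RIGHT, LEFT = Orientation.RIGHT_ANCHORED, Orientation.LEFT_ANCHORED

tdup_like = canonicalize_adjacency(
    Breakend("chr1", 10_000, LEFT), Breakend("chr1", 50_000, RIGHT),
    id="delly_dup_1", pe_support=8, sr_support=5, source_tool="DELLY")
del_like = canonicalize_adjacency(
    Breakend("chr1", 12_000, RIGHT), Breakend("chr1", 50_001, LEFT),
    id="delly_del_1", pe_support=7, sr_support=6, source_tool="DELLY")

for call in reclassify([tdup_like, del_like]).calls:
    print(f"{call.cnv_type}  template={call.region}  "
          f"insertion_point={call.insertion_point}  size={call.size}  "
          f"PE={call.pe_support} SR={call.sr_support}")
```

prints

```
DDUP  template=chr1:10000-12000  insertion_point=chr1:50000  size=2000  PE=7 SR=5
```

one dispersed duplication — template `[10000, 12000)`, copy inserted at
50 000, support the per-junction minimum — and zero residual DEL/TDUP
false positives.

From the shell, the same pipeline runs over caller VCFs:

```bash
cnvpost postprocess DELLY=delly.vcf GRIDSS=gridss.vcf LUMPY=lumpy.vcf \
        MANTA=manta.vcf -o merged.bedpe
cnvpost train merged.bedpe --labels labels.tsv --holdout chr2,chr4 \
        --model-out rf.joblib
cnvpost filter merged.bedpe --model rf.joblib --cutoff 0.5 -o final.bedpe
```

`cnvpost simulate` / `cnvpost evaluate` generate truth sets and score
predictions; `cnvpost --help` lists all subcommands.

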
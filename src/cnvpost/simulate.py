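"""Synthetic CNV spike-in simulation, caller emulation and evaluation.

The simulator plants non-overlapping CNVs (deletions, insertions, tandem
and dispersed duplications) on a synthetic genome and derives the exact
novel-adjacency signature each event would imprint on short-read data.  A
:class:`CallerProfile` then emulates what an SV caller reports: adjacencies
are detected with a per-type probability scaled by allele dosage (variants
on few haplotypes have proportionally less supporting coverage), breakpoints
receive integer jitter, support counts are drawn at dosage-scaled coverage,
and false-positive adjacencies are sprinkled in at a per-Mb rate.

Crucially, with ``split_ddup`` set (the behaviour of callers that process
adjacencies in isolation) the two adjacencies of a dispersed duplication
are emitted independently and unlinked — exactly the mis-representation the
reclassifier must undo.  The emulation operates at the adjacency/VCF signal
level; read simulation and alignment are out of scope, so coverage realism
is limited to these dosage-scaled detection and support models.

:func:`evaluate` scores predicted calls against the truth set with greedy
one-to-one matching under reciprocal-overlap (and insertion-site distance)
criteria, reporting per-type recall and precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .model import (
    LEFT,
    RIGHT,
    Breakend,
    CNVCall,
    CNVType,
    GenomicInterval,
    Locus,
    NovelAdjacency,
    ValidationError,
    canonicalize_adjacency,
    chrom_sort_key,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulatedVariant:
    """One planted event.  ``region`` is the affected interval (for
    dispersed duplications: the template); ``dosage`` counts the haplotypes
    carrying the variant, out of the genome's ploidy."""

    cnv_type: CNVType
    region: GenomicInterval
    dosage: int
    insertion_point: Locus | None = None
    inserted_seq: str | None = None

    @property
    def size(self) -> int:
        if self.cnv_type is CNVType.INS:
            return len(self.inserted_seq)
        return self.region.length()

    @property
    def interchromosomal(self) -> bool:
        return (
            self.cnv_type is CNVType.DDUP
            and self.insertion_point.chrom != self.region.chrom
        )


@dataclass
class TruthSet:
    variants: list[SimulatedVariant]
    chrom_lengths: dict[str, int]
    ploidy: int
    seed: int

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def by_type(self, cnv_type: CNVType) -> list[SimulatedVariant]:
        return [v for v in self.variants if v.cnv_type is cnv_type]


def simulate_truth(
    chrom_lengths: dict[str, int] | int,
    n_per_type: dict,
    size_range: tuple[int, int] = (50, 100_000),
    ploidy: int = 2,
    dosages=None,
    ddup_inter_fraction: float = 0.0,
    spacing: int = 1000,
    seed: int = 0,
    max_tries: int = 200,
) -> TruthSet:
    """Place non-overlapping events uniformly at random (rejection sampling).

    Sizes are log-uniform over ``size_range``.  ``dosages`` lists the
    allele-dosage values drawn per event (default: fully homozygous, i.e.
    ``[ploidy]``).  ``spacing`` keeps distinct events at least that many bp
    apart so their adjacency signatures cannot co-cluster.  Deterministic
    under ``seed``; raises if the genome is too dense for the request.
    """
    if isinstance(chrom_lengths, int):
        chrom_lengths = {"chr1": chrom_lengths}
    if dosages is None:
        dosages = [ploidy]
    if any(not 1 <= d <= ploidy for d in dosages):
        raise ValidationError("dosages must lie in [1, ploidy]")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths, key=chrom_sort_key)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    occupied = {c: IntervalTree() for c in chroms}

    def free(chrom, start, end):
        return not occupied[chrom].overlaps(start - spacing, end + spacing)

    def reserve(chrom, start, end):
        occupied[chrom].addi(start, max(end, start + 1))

    def draw_size():
        lo, hi = size_range
        return int(math.exp(rng.uniform(math.log(lo), math.log(hi))))

    def place_interval(size):
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = chrom_lengths[chrom] - size - spacing
            if limit <= spacing:
                continue
            start = int(rng.integers(spacing, limit))
            if free(chrom, start, start + size):
                return chrom, start
        raise ValidationError(
            "could not place event without overlap; lower the event density "
            "or enlarge the genome"
        )

    def place_point(exclude_chrom=None, same_chrom=None):
        for _ in range(max_tries):
            if same_chrom is not None:
                chrom = same_chrom
            else:
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                if exclude_chrom is not None and chrom == exclude_chrom:
                    if len(chroms) == 1:
                        raise ValidationError(
                            "interchromosomal events need >= 2 chromosomes"
                        )
                    continue
            limit = chrom_lengths[chrom] - spacing
            if limit <= spacing:
                continue
            pos = int(rng.integers(spacing, limit))
            if free(chrom, pos, pos + 1):
                return chrom, pos
        raise ValidationError("could not place insertion point; lower density")

    def norm_type(t):
        return t if isinstance(t, CNVType) else CNVType(str(t))

    counts = {norm_type(t): int(n) for t, n in n_per_type.items()}
    variants: list[SimulatedVariant] = []
    for cnv_type in (CNVType.DEL, CNVType.INS, CNVType.TDUP, CNVType.DDUP):
        for _ in range(counts.get(cnv_type, 0)):
            dosage = int(rng.choice(dosages))
            size = draw_size()
            if cnv_type is CNVType.INS:
                chrom, pos = place_point()
                reserve(chrom, pos, pos + 1)
                seq = "".join(rng.choice(_BASES, size=size))
                variants.append(
                    SimulatedVariant(
                        cnv_type, GenomicInterval(chrom, pos, pos), dosage,
                        insertion_point=Locus(chrom, pos), inserted_seq=seq,
                    )
                )
                continue
            chrom, start = place_interval(size)
            region = GenomicInterval(chrom, start, start + size)
            reserve(chrom, start, start + size)
            if cnv_type is CNVType.DDUP:
                inter = rng.random() < ddup_inter_fraction
                if inter:
                    ip_chrom, ip_pos = place_point(exclude_chrom=chrom)
                else:
                    ip_chrom, ip_pos = place_point(same_chrom=chrom)
                reserve(ip_chrom, ip_pos, ip_pos + 1)
                variants.append(
                    SimulatedVariant(
                        cnv_type, region, dosage,
                        insertion_point=Locus(ip_chrom, ip_pos),
                    )
                )
            else:
                variants.append(SimulatedVariant(cnv_type, region, dosage))
    return TruthSet(
        variants=variants, chrom_lengths=dict(chrom_lengths),
        ploidy=ploidy, seed=seed,
    )


def variant_adjacencies(variant: SimulatedVariant, prefix: str = "v") -> list[NovelAdjacency]:
    """Exact adjacency signature one event imprints on the sample genome."""
    c, s, e = variant.region.chrom, variant.region.start, variant.region.end
    t = variant.cnv_type
    if t is CNVType.DEL:
        pairs = [(Breakend(c, s, RIGHT), Breakend(c, e, LEFT), None)]
    elif t is CNVType.TDUP:
        pairs = [(Breakend(c, s, LEFT), Breakend(c, e, RIGHT), None)]
    elif t is CNVType.INS:
        p = variant.insertion_point.pos
        pairs = [(Breakend(c, p, RIGHT), Breakend(c, p, LEFT), variant.inserted_seq)]
    else:  # DDUP: junction into the copy + junction out of the copy
        ip = variant.insertion_point
        pairs = [
            (Breakend(c, s, LEFT), Breakend(ip.chrom, ip.pos, RIGHT), None),
            (Breakend(c, e, RIGHT), Breakend(ip.chrom, ip.pos, LEFT), None),
        ]
    return [
        canonicalize_adjacency(
            b1, b2, id=f"{prefix}_{t.value}_{k}", source_tool="SIM", inserted_seq=seq
        )
        for k, (b1, b2, seq) in enumerate(pairs)
    ]


def truth_adjacencies(truth: TruthSet) -> list[list[NovelAdjacency]]:
    """Per-variant adjacency lists, parallel to ``truth.variants``."""
    return [variant_adjacencies(v, prefix=f"v{i}") for i, v in enumerate(truth.variants)]


def truth_to_calls(truth: TruthSet) -> list[CNVCall]:
    """Idealized call objects for the truth set (for BEDPE export)."""
    calls = []
    for i, v in enumerate(truth.variants):
        calls.append(
            CNVCall(
                cnv_type=v.cnv_type,
                region=v.region,
                adjacencies=variant_adjacencies(v, prefix=f"v{i}"),
                insertion_point=v.insertion_point,
                source_tools=frozenset(["SIM"]),
                inserted_seq=v.inserted_seq,
                name=f"truth{i:05d}",
            )
        )
    return calls


@dataclass(frozen=True)
class CallerProfile:
    """Signal-level behaviour model of one SV caller.

    ``detection`` maps CNV type to the probability of reporting each
    adjacency of a fully homozygous event; the effective probability scales
    with ``dosage / ploidy``.  ``split_ddup`` emulates callers that process
    adjacencies in isolation: the two adjacencies of a dispersed duplication
    are retained (and jittered) independently, with no linkage between them.
    """

    tool: str = "SIM"
    detection: dict | float = 1.0
    jitter_sd: float = 0.0
    fp_per_mb: dict | float = 0.0
    split_ddup: bool = True
    base_support: float = 10.0

    def detection_for(self, cnv_type: CNVType) -> float:
        p = self.detection
        if isinstance(p, dict):
            p = p.get(cnv_type, p.get(cnv_type.value, 1.0))
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"detection probability {p} outside [0, 1]")
        return float(p)

    def fp_rate_for(self, cnv_type: CNVType) -> float:
        r = self.fp_per_mb
        if isinstance(r, dict):
            r = r.get(cnv_type, r.get(cnv_type.value, 0.0))
        return float(r)


def _jitter(rng, sd: float) -> int:
    if sd <= 0:
        return 0
    # truncated at 3 sigma so a small nominal jitter stays bounded
    return int(round(float(np.clip(rng.normal(0.0, sd), -3.0 * sd, 3.0 * sd))))


def emulate_caller(
    truth: TruthSet, profile: CallerProfile, seed: int = 0
) -> list[NovelAdjacency]:
    """Emulate one caller's adjacency output for a truth set."""
    rng = np.random.default_rng(seed)
    out: list[NovelAdjacency] = []

    def observe(adj: NovelAdjacency, lam: float, vid: str):
        b = []
        for bnd in (adj.bnd1, adj.bnd2):
            pos = max(0, bnd.pos + _jitter(rng, profile.jitter_sd))
            b.append(Breakend(bnd.chrom, pos, bnd.orientation))
        out.append(
            canonicalize_adjacency(
                b[0], b[1],
                id=f"{profile.tool}_{vid}",
                pe_support=int(rng.poisson(lam)),
                sr_support=int(rng.poisson(lam)),
                source_tool=profile.tool,
                inserted_seq=adj.inserted_seq,
            )
        )

    for i, variant in enumerate(truth.variants):
        adjs = variant_adjacencies(variant, prefix=f"v{i}")
        frac = variant.dosage / truth.ploidy
        p = profile.detection_for(variant.cnv_type) * frac
        lam = profile.base_support * frac
        if variant.cnv_type is CNVType.DDUP and not profile.split_ddup:
            if rng.random() < p:
                for adj in adjs:
                    observe(adj, lam, adj.id)
        else:
            for adj in adjs:
                if rng.random() < p:
                    observe(adj, lam, adj.id)

    total_mb = truth.total_length / 1e6
    chroms = sorted(truth.chrom_lengths, key=chrom_sort_key)
    lengths = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    for cnv_type in (CNVType.DEL, CNVType.TDUP, CNVType.INS):
        n_fp = rng.poisson(profile.fp_rate_for(cnv_type) * total_mb)
        for k in range(n_fp):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            size = int(math.exp(rng.uniform(math.log(50), math.log(10_000))))
            limit = max(truth.chrom_lengths[chrom] - size - 1, 1)
            start = int(rng.integers(0, limit))
            fake = SimulatedVariant(
                cnv_type,
                GenomicInterval(chrom, start, start if cnv_type is CNVType.INS else start + size),
                dosage=truth.ploidy,
                insertion_point=Locus(chrom, start) if cnv_type is CNVType.INS else None,
                inserted_seq="".join(rng.choice(_BASES, size=size))
                if cnv_type is CNVType.INS
                else None,
            )
            for adj in variant_adjacencies(fake, prefix=f"fp{cnv_type.value}{k}"):
                observe(adj, profile.base_support / 2, adj.id)
    out.sort(key=lambda a: a.sort_key())
    return out


# ---------------------------------------------------------------------------
# Evaluation

@dataclass(frozen=True)
class MatchConfig:
    min_reciprocal_overlap: float = 0.5
    insertion_window: int = 100


@dataclass
class TypeMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def recall(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "recall": self.recall, "precision": self.precision,
        }


@dataclass
class EvalReport:
    per_type: dict[str, TypeMetrics]
    overall: TypeMetrics
    matching: MatchConfig

    def to_dict(self) -> dict:
        return {
            "per_type": {t: m.to_dict() for t, m in self.per_type.items()},
            "overall": self.overall.to_dict(),
            "matching": {
                "min_reciprocal_overlap": self.matching.min_reciprocal_overlap,
                "insertion_window": self.matching.insertion_window,
            },
        }


def _match_score(pred, truth_v, matching: MatchConfig):
    """Return a sort score for a candidate pred/truth pair, or None.

    Region types match on reciprocal template overlap (dispersed
    duplications additionally on insertion-site distance); insertions match
    on insertion-site distance alone.  Higher overlap = better; for
    insertions, smaller distance = better.
    """
    t = truth_v.cnv_type
    if pred.cnv_type is not t:
        return None
    if t is CNVType.INS:
        ip_p, ip_t = pred.insertion_point, truth_v.insertion_point
        if ip_p is None or ip_p.chrom != ip_t.chrom:
            return None
        dist = abs(ip_p.pos - ip_t.pos)
        if dist > matching.insertion_window:
            return None
        return 1.0 - dist / (matching.insertion_window + 1)
    ro = pred.region.reciprocal_overlap(truth_v.region)
    if ro < matching.min_reciprocal_overlap:
        return None
    if t is CNVType.DDUP:
        ip_p, ip_t = pred.insertion_point, truth_v.insertion_point
        if ip_p is None or ip_p.chrom != ip_t.chrom:
            return None
        if abs(ip_p.pos - ip_t.pos) > matching.insertion_window:
            return None
    return ro


def evaluate(predicted, truth: TruthSet, matching: MatchConfig = MatchConfig()) -> EvalReport:
    """Greedy one-to-one matching of predictions against truth.

    Candidate pairs are ranked best-overlap-first with deterministic
    leftmost tie-breaking; each truth event and each prediction is matched
    at most once.  Per-type precision is reported as None (not 0) when no
    prediction of that type exists.
    """
    predicted = list(predicted)
    candidates = []
    for pi, pred in enumerate(predicted):
        for ti, tv in enumerate(truth.variants):
            score = _match_score(pred, tv, matching)
            if score is not None:
                candidates.append(
                    (-score, chrom_sort_key(pred.region.chrom),
                     pred.region.start, pi, ti)
                )
    candidates.sort()
    matched_pred: set[int] = set()
    matched_truth: set[int] = set()
    for _, _, _, pi, ti in candidates:
        if pi in matched_pred or ti in matched_truth:
            continue
        matched_pred.add(pi)
        matched_truth.add(ti)

    per_type = {t.value: TypeMetrics() for t in CNVType}
    for ti, tv in enumerate(truth.variants):
        m = per_type[tv.cnv_type.value]
        if ti in matched_truth:
            m.tp += 1
        else:
            m.fn += 1
    for pi, pred in enumerate(predicted):
        if pi not in matched_pred:
            per_type[pred.cnv_type.value].fp += 1
    overall = TypeMetrics(
        tp=sum(m.tp for m in per_type.values()),
        fp=sum(m.fp for m in per_type.values()),
        fn=sum(m.fn for m in per_type.values()),
    )
    return EvalReport(per_type=per_type, overall=overall, matching=matching)


# ---------------------------------------------------------------------------
# Synthetic labeled call sets for classifier exercises

def simulate_labeled_calls(
    n: int,
    seed: int = 0,
    label_noise: float = 0.1,
    chromosomes: tuple = ("chr1", "chr2", "chr3", "chr4", "chr5"),
):
    """Random merged calls whose labels follow a noisy concordance rule.

    The clean label is 1 iff at least three callers concur or the total
    read support reaches 25; ``label_noise`` of the labels are then
    flipped.  This is the planted-signal setting used to exercise the
    random-forest filter: any consistent learner can recover the rule, and
    the noise bounds attainable accuracy.
    """
    from .model import MergedCall

    rng = np.random.default_rng(seed)
    tools = np.array(["DELLY", "GRIDSS", "LUMPY", "MANTA"])
    types = [CNVType.DEL, CNVType.INS, CNVType.TDUP, CNVType.DDUP]
    type_p = [0.7, 0.06, 0.2, 0.04]
    calls, labels = [], []
    for i in range(n):
        cnv_type = types[rng.choice(4, p=type_p)]
        chrom = str(rng.choice(list(chromosomes)))
        size = int(math.exp(rng.uniform(math.log(50), math.log(100_000))))
        start = int(rng.integers(0, 10_000_000))
        n_tools = int(rng.integers(1, 5))
        toolset = frozenset(rng.choice(tools, size=n_tools, replace=False))
        pe = int(rng.poisson(9))
        sr = int(rng.poisson(7))
        if cnv_type is CNVType.INS:
            region = GenomicInterval(chrom, start, start)
            ip = Locus(chrom, start)
            seq = "".join(rng.choice(_BASES, size=min(size, 200)))
        else:
            region = GenomicInterval(chrom, start, start + size)
            ip = Locus(chrom, start + size + 5000) if cnv_type is CNVType.DDUP else None
            seq = None
        donor_type = cnv_type
        donors = []
        for tool in sorted(toolset):
            donors.append(
                CNVCall(
                    cnv_type=donor_type,
                    region=region,
                    adjacencies=_donor_adjacencies(donor_type, region, ip, seq, tool),
                    insertion_point=ip,
                    pe_support=pe,
                    sr_support=sr,
                    source_tools=frozenset([tool]),
                    inserted_seq=seq,
                )
            )
        calls.append(
            MergedCall(
                cnv_type=cnv_type,
                region=region,
                donors=donors,
                insertion_point=ip,
                pe_support=float(pe),
                sr_support=float(sr),
                source_tools=toolset,
                inserted_seq=seq,
                name=f"sim{i:05d}",
            )
        )
        clean = int(n_tools >= 3 or pe + sr >= 25)
        flip = rng.random() < label_noise
        labels.append(1 - clean if flip else clean)

    from .rf_filter import LabeledCallSet

    return LabeledCallSet(calls, np.array(labels))


def _donor_adjacencies(cnv_type, region, ip, seq, tool):
    from .caller_io import _canonical_adjacencies

    adjs = _canonical_adjacencies(cnv_type, region, ip, seq)
    for a in adjs:
        a.source_tool = tool
    return adjs


# ---------------------------------------------------------------------------
# Truth-set persistence (tab-separated variant table)

_TRUTH_HEADER = [
    "cnv_type", "chrom", "start", "end", "ip_chrom", "ip_pos",
    "dosage", "inserted_seq",
]


def write_truth_table(truth: TruthSet, path):
    lines = [
        "##ploidy=%d\tseed=%d" % (truth.ploidy, truth.seed),
        "##chrom_lengths=" + ",".join(
            f"{c}:{l}" for c, l in sorted(truth.chrom_lengths.items())
        ),
        "#" + "\t".join(_TRUTH_HEADER),
    ]
    for v in truth.variants:
        ip = v.insertion_point
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    v.cnv_type.value, v.region.chrom, v.region.start, v.region.end,
                    ip.chrom if ip else ".", ip.pos if ip else ".",
                    v.dosage, v.inserted_seq or ".",
                )
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_table(path) -> TruthSet:
    variants = []
    ploidy, seed, chrom_lengths = 2, 0, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##ploidy="):
                head, seed_part = line.split("\t")
                ploidy = int(head.split("=")[1])
                seed = int(seed_part.split("=")[1])
                continue
            if line.startswith("##chrom_lengths="):
                for item in line.split("=", 1)[1].split(","):
                    c, l = item.rsplit(":", 1)
                    chrom_lengths[c] = int(l)
                continue
            if not line or line.startswith("#"):
                continue
            t, chrom, start, end, ipc, ipp, dosage, seq = line.split("\t")
            variants.append(
                SimulatedVariant(
                    CNVType(t), GenomicInterval(chrom, int(start), int(end)),
                    int(dosage),
                    insertion_point=Locus(ipc, int(ipp)) if ipc != "." else None,
                    inserted_seq=None if seq == "." else seq,
                )
            )
    return TruthSet(variants, chrom_lengths, ploidy, seed)
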
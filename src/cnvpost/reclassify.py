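"""Cluster same-tool adjacencies and classify them into CNV calls.

Short-read SV callers that interpret each novel adjacency in isolation
mis-report an intrachromosomal dispersed duplication (a copy of a template
``[s, e)`` landing at a distant site ``p``) as an overlapping pair of a
large deletion and a large tandem duplication: the junction from the
reference into the start of the copy looks like a tandem-duplication
adjacency spanning ``[s, p)``, and the junction out of the copy back into
the reference looks like a deletion adjacency spanning ``[e, p)``.  The two
share the breakpoint ``p``, so clustering adjacencies whose breakpoints
co-locate (within 10 bp by default) and examining the joint signature
recovers the dispersed duplication and removes both false positives.

Adjacency signatures (canonical breakend order, boundary coordinates):

==================  ==========================================
deletion            ``(s RIGHT, e LEFT)``, no inserted sequence
tandem duplication  ``(s LEFT, e RIGHT)``
insertion           both breakends at the site, sequence attached
dispersed dup.      TDUP-like ``[s, p)`` + DEL-like ``[e, p)`` (copy
                    downstream), mirrored for an upstream copy, or a
                    translocation-style pair for an interchromosomal copy
==================  ==========================================

Anything else (inversion-like same-orientation pairs, lone
interchromosomal breakends) is not a copy-number variant and is excluded,
retained in a side channel with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    LEFT,
    RIGHT,
    AdjacencyCluster,
    Breakend,
    CNVCall,
    CNVType,
    GenomicInterval,
    Locus,
    NovelAdjacency,
    chrom_sort_key,
)


@dataclass(frozen=True)
class ClassificationConfig:
    """Knobs of the reclassification stage.

    cluster_window: max breakpoint distance (bp) for same-tool adjacencies
        to be considered part of one variant.
    min_size: smallest event (bp) reported as a CNV.
    insertion_site_tolerance: max breakend distance (bp) for an adjacency
        with unresolved inserted sequence to be read as an insertion site.
    allow_inverted_ddup: also pair same-orientation adjacency signatures
        into inverted-copy dispersed duplications (off by default).
    """

    cluster_window: int = 10
    min_size: int = 50
    insertion_site_tolerance: int = 10
    allow_inverted_ddup: bool = False

    def __post_init__(self):
        if self.cluster_window < 0 or self.min_size < 0:
            raise ValueError("cluster_window and min_size must be >= 0")


# exclusion reason codes
INVERSION_LIKE = "inversion_like"
INTERCHROM_SINGLETON = "interchromosomal_singleton"
BELOW_MIN_SIZE = "below_min_size"
UNCLASSIFIABLE = "unclassifiable_cluster"


@dataclass
class ExcludedAdjacency:
    adjacency: NovelAdjacency
    reason: str


@dataclass
class ReclassifyResult:
    calls: list[CNVCall]
    excluded: list[ExcludedAdjacency]

    def excluded_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ex in self.excluded:
            out[ex.reason] = out.get(ex.reason, 0) + 1
        return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_adjacencies(
    adjacencies, cfg: ClassificationConfig = ClassificationConfig()
) -> list[AdjacencyCluster]:
    """Single-linkage clustering of same-tool adjacencies.

    Two adjacencies are linked iff they come from the same tool and any
    breakend of one lies within ``cluster_window`` bp of any breakend of the
    other on the same chromosome.  Implemented as a sorted sweep over all
    breakend positions (per tool, per chromosome): consecutive positions
    within the window are unioned, which yields exactly the transitive
    closure of the pairwise relation.
    """
    adjacencies = list(adjacencies)
    by_tool: dict[str, list[int]] = {}
    for i, adj in enumerate(adjacencies):
        by_tool.setdefault(adj.source_tool, []).append(i)

    uf = _UnionFind(len(adjacencies))
    for indices in by_tool.values():
        points = []
        for i in indices:
            adj = adjacencies[i]
            points.append((chrom_sort_key(adj.bnd1.chrom), adj.bnd1.pos, i))
            points.append((chrom_sort_key(adj.bnd2.chrom), adj.bnd2.pos, i))
        points.sort()
        for (c1, p1, i1), (c2, p2, i2) in zip(points, points[1:]):
            if c1 == c2 and p2 - p1 <= cfg.cluster_window:
                uf.union(i1, i2)

    groups: dict[int, list[NovelAdjacency]] = {}
    for i, adj in enumerate(adjacencies):
        groups.setdefault(uf.find(i), []).append(adj)
    clusters = [
        AdjacencyCluster(
            members=sorted(members, key=lambda a: a.sort_key()),
            linkage_window=cfg.cluster_window,
        )
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: c.sort_key())
    return clusters


def classify_singleton(
    adj: NovelAdjacency, cfg: ClassificationConfig = ClassificationConfig()
):
    """Classify one adjacency in isolation.

    Returns a :class:`CNVCall` or an :class:`ExcludedAdjacency`.  This is
    also the documented fallback when only one of a dispersed duplication's
    two adjacencies was detected: the survivor is reported as the deletion
    or tandem duplication its own signature spells.
    """
    b1, b2 = adj.bnd1, adj.bnd2
    chrom = b1.chrom

    if isinstance(adj.inserted_seq, str):
        return _make_call(
            CNVType.INS, GenomicInterval(chrom, b1.pos, b1.pos), [adj],
            insertion_point=Locus(chrom, b1.pos), inserted_seq=adj.inserted_seq,
            cfg=cfg,
        )
    if adj.inserted_seq is not None:  # UNKNOWN sentinel
        if adj.intrachromosomal and adj.span <= cfg.insertion_site_tolerance:
            return _make_call(
                CNVType.INS, GenomicInterval(chrom, b1.pos, b1.pos), [adj],
                insertion_point=Locus(chrom, b1.pos), inserted_seq=adj.inserted_seq,
                cfg=cfg,
            )
        return ExcludedAdjacency(adj, UNCLASSIFIABLE)
    if not adj.intrachromosomal:
        return ExcludedAdjacency(adj, INTERCHROM_SINGLETON)
    if adj.orientations == (RIGHT, LEFT):
        return _make_call(
            CNVType.DEL, GenomicInterval(chrom, b1.pos, b2.pos), [adj], cfg=cfg
        )
    if adj.orientations == (LEFT, RIGHT):
        return _make_call(
            CNVType.TDUP, GenomicInterval(chrom, b1.pos, b2.pos), [adj], cfg=cfg
        )
    return ExcludedAdjacency(adj, INVERSION_LIKE)


def _make_call(cnv_type, region, adjacencies, cfg, insertion_point=None,
               inserted_seq=None):
    size = len(inserted_seq) if isinstance(inserted_seq, str) else region.length()
    if cnv_type is not CNVType.INS or isinstance(inserted_seq, str):
        if size < cfg.min_size:
            if len(adjacencies) == 1:
                return ExcludedAdjacency(adjacencies[0], BELOW_MIN_SIZE)
            return [ExcludedAdjacency(a, BELOW_MIN_SIZE) for a in adjacencies]
    pe = min(a.pe_support for a in adjacencies)
    sr = min(a.sr_support for a in adjacencies)
    return CNVCall(
        cnv_type=cnv_type,
        region=region,
        adjacencies=list(adjacencies),
        insertion_point=insertion_point,
        pe_support=pe,
        sr_support=sr,
        source_tools=frozenset(a.source_tool for a in adjacencies),
        inserted_seq=inserted_seq,
        name="+".join(a.id for a in adjacencies if a.id),
    )


def _is_del_like(adj: NovelAdjacency) -> bool:
    return (
        adj.intrachromosomal
        and adj.inserted_seq is None
        and adj.orientations == (RIGHT, LEFT)
    )


def _is_tdup_like(adj: NovelAdjacency) -> bool:
    return (
        adj.intrachromosomal
        and adj.inserted_seq is None
        and adj.orientations == (LEFT, RIGHT)
    )


def _ddup_candidate(a, b, cfg):
    """Test an adjacency pair for a dispersed-duplication signature.

    Returns ``(shared_breakpoint_distance, template, insertion_locus)`` or
    None.  The three default signatures (see module docstring):

    - downstream copy: TDUP-like ``[s, p)`` + DEL-like ``[e, p')``,
      ``s < e < min(p, p')``, shared high breakpoints;
    - upstream copy: DEL-like ``[p, s)`` + TDUP-like ``[p', e)``,
      ``max(p, p') < s < e``, shared low breakpoints;
    - interchromosomal: two translocation adjacencies whose breakends on
      the acceptor chromosome co-locate with opposite orientations and
      whose donor breakends delimit the template with opposite orientations.
    """
    w = cfg.cluster_window
    for t, d in ((a, b), (b, a)):
        if _is_tdup_like(t) and _is_del_like(d) and t.bnd1.chrom == d.bnd1.chrom:
            chrom = t.bnd1.chrom
            # downstream copy: shared high breakpoints
            s, p = t.bnd1.pos, t.bnd2.pos
            e, p2 = d.bnd1.pos, d.bnd2.pos
            if abs(p - p2) <= w and s < e < min(p, p2):
                return (abs(p - p2), GenomicInterval(chrom, s, e), Locus(chrom, p))
            # upstream copy: shared low breakpoints
            p, s2 = d.bnd1.pos, d.bnd2.pos
            p2, e = t.bnd1.pos, t.bnd2.pos
            if abs(p - p2) <= w and max(p, p2) < s2 < e:
                return (abs(p - p2), GenomicInterval(chrom, s2, e), Locus(chrom, p))
    if not a.intrachromosomal and not b.intrachromosomal:
        cand = _inter_ddup_candidate(a, b, cfg)
        if cand is not None:
            return cand
    if cfg.allow_inverted_ddup:
        cand = _inverted_ddup_candidate(a, b, cfg)
        if cand is not None:
            return cand
    return None


def _inter_ddup_candidate(a, b, cfg):
    chroms_a = {a.bnd1.chrom, a.bnd2.chrom}
    if chroms_a != {b.bnd1.chrom, b.bnd2.chrom} or len(chroms_a) != 2:
        return None
    best = None
    for acceptor in chroms_a:
        ba = a.bnd1 if a.bnd1.chrom == acceptor else a.bnd2
        bb = b.bnd1 if b.bnd1.chrom == acceptor else b.bnd2
        da = a.bnd2 if ba is a.bnd1 else a.bnd1
        db = b.bnd2 if bb is b.bnd1 else b.bnd1
        dist = abs(ba.pos - bb.pos)
        if dist > cfg.cluster_window:
            continue
        if ba.orientation == bb.orientation or da.orientation == db.orientation:
            continue
        lo, hi = sorted((da.pos, db.pos))
        if hi <= lo:
            continue
        entering = ba if ba.orientation is RIGHT else bb
        cand = (
            dist,
            GenomicInterval(da.chrom, lo, hi),
            Locus(acceptor, entering.pos),
        )
        if best is None or cand[0] < best[0]:
            best = cand
    return best


def _inverted_ddup_candidate(a, b, cfg):
    """Inverted-copy signature: one (RIGHT, RIGHT) and one (LEFT, LEFT)
    intrachromosomal adjacency sharing a breakpoint; the remaining breakends
    delimit the template.  Flag-gated (allow_inverted_ddup)."""
    if not (a.intrachromosomal and b.intrachromosomal):
        return None
    if a.bnd1.chrom != b.bnd1.chrom:
        return None
    pairs = {a.orientations, b.orientations}
    if pairs != {(RIGHT, RIGHT), (LEFT, LEFT)}:
        return None
    rr = a if a.orientations == (RIGHT, RIGHT) else b
    ll = b if rr is a else a
    best = None
    for r_shared, r_free in ((rr.bnd1, rr.bnd2), (rr.bnd2, rr.bnd1)):
        for l_shared, l_free in ((ll.bnd1, ll.bnd2), (ll.bnd2, ll.bnd1)):
            dist = abs(r_shared.pos - l_shared.pos)
            if dist > cfg.cluster_window:
                continue
            s, e = l_free.pos, r_free.pos
            if not s < e:
                continue
            p = r_shared.pos
            if s <= p <= e:
                continue
            cand = (dist, GenomicInterval(rr.bnd1.chrom, s, e), Locus(rr.bnd1.chrom, p))
            if best is None or cand[0] < best[0]:
                best = cand
    return best


def classify_cluster(
    cluster: AdjacencyCluster, cfg: ClassificationConfig = ClassificationConfig()
) -> tuple[list[CNVCall], list[ExcludedAdjacency]]:
    """Classify one cluster; dispersed-duplication pairs are found first.

    Candidate pairs are resolved greedily by smallest shared-breakpoint
    distance (ties: leftmost template), each adjacency participating in at
    most one dispersed duplication.  An adjacency pair recognized as a
    dispersed duplication whose template is below ``min_size`` is consumed
    and excluded, never reinterpreted as a deletion + tandem duplication.
    Remaining members fall through to singleton classification.
    """
    members = cluster.members
    calls: list[CNVCall] = []
    excluded: list[ExcludedAdjacency] = []

    candidates = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            cand = _ddup_candidate(members[i], members[j], cfg)
            if cand is not None:
                dist, template, ip = cand
                candidates.append(
                    (dist, chrom_sort_key(template.chrom), template.start,
                     template.end, i, j, template, ip)
                )
    candidates.sort(key=lambda c: c[:6])

    used: set[int] = set()
    for dist, _, _, _, i, j, template, ip in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pair = [members[i], members[j]]
        if template.length() < cfg.min_size:
            excluded.extend(ExcludedAdjacency(a, BELOW_MIN_SIZE) for a in pair)
            continue
        calls.append(
            CNVCall(
                cnv_type=CNVType.DDUP,
                region=template,
                adjacencies=sorted(pair, key=lambda a: a.sort_key()),
                insertion_point=ip,
                pe_support=min(a.pe_support for a in pair),
                sr_support=min(a.sr_support for a in pair),
                source_tools=frozenset(a.source_tool for a in pair),
                name="+".join(a.id for a in pair if a.id),
            )
        )

    for k, adj in enumerate(members):
        if k in used:
            continue
        result = classify_singleton(adj, cfg)
        if isinstance(result, CNVCall):
            calls.append(result)
        elif isinstance(result, list):
            excluded.extend(result)
        else:
            excluded.append(result)

    calls.sort(key=lambda c: c.sort_key())
    return calls, excluded


def reclassify(
    adjacencies, cfg: ClassificationConfig = ClassificationConfig()
) -> ReclassifyResult:
    """Full reclassification: cluster per tool, classify every cluster.

    Accepts a flat adjacency list (tool provenance is on each adjacency) or
    a mapping tool -> adjacencies.  Every input adjacency ends up in exactly
    one classified call or in the excluded side channel.
    """
    if isinstance(adjacencies, dict):
        adjacencies = [a for sub in adjacencies.values() for a in sub]
    calls: list[CNVCall] = []
    excluded: list[ExcludedAdjacency] = []
    for cluster in cluster_adjacencies(adjacencies, cfg):
        c, e = classify_cluster(cluster, cfg)
        calls.extend(c)
        excluded.extend(e)
    calls.sort(key=lambda c: c.sort_key())
    return ReclassifyResult(calls=calls, excluded=excluded)
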
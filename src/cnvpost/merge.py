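"""Collapse concordant calls from different tools into merged calls.

Two calls are mergeable iff all of the following hold: same CNV type; same
chromosome; 5' breakpoints within ``breakpoint_window`` bp of each other
AND 3' breakpoints within the window; at least ``min_reciprocal_overlap``
reciprocal overlap (skipped for insertions, whose regions are points); and
insertion sites within ``insertion_site_window`` bp (applies to insertions
and dispersed duplications only).  For dispersed duplications the window
and overlap tests apply to the template region and the site test to the
insertion point.

Merging takes the single-linkage (transitive) closure of the pairwise
relation.  A merged call covers the union of its donors' regions — donors
covering positions 12-30 and 14-32 merge into a call covering 12-32 — and
carries the median donor support per signal (mean of the central pair for
even counts, kept as a real number) and the union of donor tool sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CNVCall,
    CNVType,
    GenomicInterval,
    Locus,
    MergedCall,
    UNKNOWN,
    ValidationError,
    chrom_sort_key,
)


@dataclass(frozen=True)
class MergeConfig:
    breakpoint_window: int = 1000
    min_reciprocal_overlap: float = 0.5
    insertion_site_window: int = 10

    def __post_init__(self):
        if not (0.0 < self.min_reciprocal_overlap <= 1.0):
            raise ValidationError("min_reciprocal_overlap must be in (0, 1]")
        if self.breakpoint_window < 0 or self.insertion_site_window < 0:
            raise ValidationError("windows must be >= 0")


def mergeable(a, b, cfg: MergeConfig = MergeConfig()) -> bool:
    """Pairwise merge test; see module docstring for the four conditions."""
    if a.cnv_type is not b.cnv_type:
        return False
    if a.region.chrom != b.region.chrom:
        return False
    if abs(a.region.start - b.region.start) > cfg.breakpoint_window:
        return False
    if abs(a.region.end - b.region.end) > cfg.breakpoint_window:
        return False
    if a.cnv_type is not CNVType.INS:
        if a.region.reciprocal_overlap(b.region) < cfg.min_reciprocal_overlap:
            return False
    if a.cnv_type in (CNVType.INS, CNVType.DDUP):
        ip_a, ip_b = a.insertion_point, b.insertion_point
        if ip_a.chrom != ip_b.chrom:
            return False
        if abs(ip_a.pos - ip_b.pos) > cfg.insertion_site_window:
            return False
    return True


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_calls(calls, cfg: MergeConfig = MergeConfig()) -> list[MergedCall]:
    """Merge a mixed-tool call set; single-linkage over :func:`mergeable`.

    Calls are bucketed by (type, chromosome, insertion chromosome) and
    swept in start order; a pair is only tested while the start distance
    can still satisfy the breakpoint window, which prunes the quadratic
    pair scan without changing the connected components.  Output is
    deterministic and order-invariant: components are rebuilt from sorted
    donors and sorted by genomic position.
    """
    calls = list(calls)
    buckets: dict[tuple, list[int]] = {}
    for i, call in enumerate(calls):
        ip_chrom = call.insertion_point.chrom if call.insertion_point else None
        buckets.setdefault(
            (call.cnv_type.value, call.region.chrom, ip_chrom), []
        ).append(i)

    uf = _UnionFind(len(calls))
    for indices in buckets.values():
        indices = sorted(indices, key=lambda i: calls[i].region.start)
        for a_pos, i in enumerate(indices):
            for j in indices[a_pos + 1:]:
                if calls[j].region.start - calls[i].region.start > cfg.breakpoint_window:
                    break
                if mergeable(calls[i], calls[j], cfg):
                    uf.union(i, j)

    components: dict[int, list[CNVCall]] = {}
    for i, call in enumerate(calls):
        components.setdefault(uf.find(i), []).append(call)

    merged = [_merge_component(sorted(c, key=lambda x: x.sort_key()))
              for c in components.values()]
    merged.sort(key=lambda m: m.sort_key())
    for k, m in enumerate(merged):
        m.name = m.name or f"M{k:05d}"
    return merged


def _merge_component(donors: list[CNVCall]) -> MergedCall:
    first = donors[0]
    region = GenomicInterval(
        first.region.chrom,
        min(d.region.start for d in donors),
        max(d.region.end for d in donors),
    )
    insertion_point = None
    if first.insertion_point is not None:
        insertion_point = Locus(
            first.insertion_point.chrom,
            int(round(float(np.median([d.insertion_point.pos for d in donors])))),
        )
    inserted_seq = None
    known = sorted(
        (d.inserted_seq for d in donors if isinstance(d.inserted_seq, str)), key=len
    )
    if known:
        inserted_seq = known[-1]  # longest resolved sequence among donors
    elif any(d.inserted_seq is UNKNOWN for d in donors):
        inserted_seq = UNKNOWN
    return MergedCall(
        cnv_type=first.cnv_type,
        region=region,
        donors=donors,
        insertion_point=insertion_point,
        pe_support=float(np.median([d.pe_support for d in donors])),
        sr_support=float(np.median([d.sr_support for d in donors])),
        source_tools=frozenset().union(*(d.source_tools for d in donors)),
        inserted_seq=inserted_seq,
    )
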
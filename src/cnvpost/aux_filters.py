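"""Optional read-depth and assembly-gap post-filters.

A genuine deletion should show clearly reduced read depth over its span and
a duplication clearly elevated depth, relative to the chromosome it sits
on; calls in assembly gaps (N-rich flanks) are untrustworthy regardless of
read evidence.  These filters remove calls violating those expectations.
They are deliberately conservative, default-off, and intended for samples
genetically distant from the reference or for gappy assemblies, where the
trained classifier alone leaves more false positives.

Depth is consumed through a small provider contract (`chrom`, `start`,
`end` -> per-base depths) so tests can feed synthetic arrays and production
can feed a bedgraph-style track computed by standard external tooling;
depth computation from alignments is not re-implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import CNVType, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AuxFilterConfig:
    """Thresholds for the auxiliary filters.

    Ratio cutoffs sit between the modes expected for diploid heterozygous
    (~0.5 / ~1.5) and unaffected (~1.0) regions; removal uses strict
    inequality so boundary values survive.  ``excessive_depth`` removes
    calls in collapsed-repeat regions regardless of ratio.
    """

    del_max_depth_ratio: float = 0.75
    dup_min_depth_ratio: float = 1.25
    excessive_depth: float = 1000.0
    flank_bp: int = 400
    max_flank_n_fraction: float = 0.5
    enabled: bool = False

    def __post_init__(self):
        if not (0.0 < self.del_max_depth_ratio < 1.0 < self.dup_min_depth_ratio):
            raise ValidationError(
                "need 0 < del_max_depth_ratio < 1 < dup_min_depth_ratio"
            )
        if self.flank_bp <= 0:
            raise ValidationError("flank_bp must be > 0")


class ArrayDepthTrack:
    """Per-base depth from in-memory arrays, one per chromosome."""

    def __init__(self, depths: dict):
        self._depths = {c: np.asarray(v, dtype=float) for c, v in depths.items()}
        for chrom, arr in self._depths.items():
            if (arr < 0).any():
                raise ValidationError(f"negative depth on {chrom}")
        self._medians: dict[str, float] = {}

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._depths:
            raise ValidationError(f"chromosome {chrom} absent from depth track")
        arr = self._depths[chrom]
        if start < 0 or end > len(arr) or start > end:
            raise ValidationError(
                f"region {chrom}:{start}-{end} outside depth track extent"
            )
        return arr[start:end]

    def chrom_median(self, chrom: str) -> float:
        if chrom not in self._medians:
            self._medians[chrom] = float(np.median(self.depth(chrom, 0, len(self._depths[chrom]))))
        return self._medians[chrom]

    @classmethod
    def from_bedgraph(cls, path, chrom_lengths: dict) -> "ArrayDepthTrack":
        """Load a bedgraph-style text track (chrom, start, end, depth)."""
        arrays = {c: np.zeros(l, dtype=float) for c, l in chrom_lengths.items()}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split()[:4]
                if chrom in arrays:
                    arrays[chrom][int(start):int(end)] = float(value)
        return cls(arrays)


def normalized_median_depth(call, depth_track) -> float:
    """Median per-base depth over the call region, normalized by the median
    depth of the chromosome the call sits on."""
    region = call.region
    if region.length() == 0:
        raise ValidationError("cannot compute depth over a zero-length region")
    chrom_median = depth_track.chrom_median(region.chrom)
    if chrom_median == 0:
        raise ValidationError(f"zero median depth on {region.chrom}")
    med = float(np.median(depth_track.depth(region.chrom, region.start, region.end)))
    return med / chrom_median


def depth_filter(calls, depth_track, cfg: AuxFilterConfig) -> list:
    """Keep deletions with depressed depth and duplications with elevated
    depth; drop anything with excessive raw depth.  Insertions are not
    testable by dosage and pass through."""
    if not cfg.enabled:
        return list(calls)
    if depth_track is None:
        raise ValidationError("depth filter enabled but no depth track provided")
    retained = []
    for call in calls:
        if call.cnv_type is CNVType.INS:
            retained.append(call)
            continue
        raw = float(
            np.median(
                depth_track.depth(call.region.chrom, call.region.start, call.region.end)
            )
        )
        if raw > cfg.excessive_depth:
            logger.info("depth filter: %s removed (excessive depth %.0fx)", call.name, raw)
            continue
        ratio = normalized_median_depth(call, depth_track)
        if call.cnv_type is CNVType.DEL:
            keep = ratio <= cfg.del_max_depth_ratio
        else:  # TDUP / DDUP dosage gain
            keep = ratio >= cfg.dup_min_depth_ratio
        if keep:
            retained.append(call)
        else:
            logger.info("depth filter: %s removed (ratio %.2f)", call.name, ratio)
    return retained


class DictGenome:
    """Sequence provider backed by an in-memory chrom -> sequence mapping."""

    def __init__(self, sequences: dict):
        self._seqs = sequences

    def length(self, chrom: str) -> int:
        if chrom not in self._seqs:
            raise ValidationError(f"chromosome {chrom} absent from genome")
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise ValidationError(f"chromosome {chrom} absent from genome")
        return str(self._seqs[chrom][start:end])


class FastaGenome:
    """Sequence provider over an indexed FASTA file (pyfaidx-backed)."""

    def __init__(self, path):
        from pyfaidx import Fasta

        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=False)

    def length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise ValidationError(f"chromosome {chrom} absent from genome")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise ValidationError(f"chromosome {chrom} absent from genome")
        return str(self._fasta[chrom][start:end])


def flank_gap_fraction(call, genome, cfg: AuxFilterConfig) -> float:
    """Fraction of N bases in the flanking windows of a call.

    Flanks are the ``flank_bp`` bases upstream of the 5' breakend and
    downstream of the 3' breakend, clipped at chromosome boundaries; the
    denominator counts only bases actually available.
    """
    chrom = call.region.chrom
    length = genome.length(chrom)
    up = genome.fetch(chrom, max(0, call.region.start - cfg.flank_bp), call.region.start)
    down = genome.fetch(chrom, call.region.end, min(length, call.region.end + cfg.flank_bp))
    seq = up + down
    if not seq:
        return 0.0
    return sum(1 for b in seq if b in "Nn") / len(seq)


def gap_filter(calls, genome, cfg: AuxFilterConfig) -> list:
    """Drop calls whose flank N-fraction strictly exceeds the threshold."""
    if not cfg.enabled:
        return list(calls)
    if genome is None:
        raise ValidationError("gap filter enabled but no genome provided")
    retained = []
    for call in calls:
        frac = flank_gap_fraction(call, genome, cfg)
        if frac > cfg.max_flank_n_fraction:
            logger.info("gap filter: %s removed (flank N fraction %.2f)", call.name, frac)
        else:
            retained.append(call)
    return retained
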
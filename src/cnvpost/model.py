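"""Shared data model for CNV post-processing.

Copy-number variants are represented through *novel adjacencies*: pairs of
bases that are neighbours in the sample genome but not in the reference.
Each end of an adjacency is a :class:`Breakend`.  Deletions, insertions and
tandem duplications are backed by a single adjacency; dispersed duplications
by two.

Coordinate convention
---------------------
All coordinates are 0-based, half-open.  A breakend position is a *boundary*
coordinate in that system: a ``RIGHT_ANCHORED`` breakend at boundary ``b``
means the retained reference segment is the sequence left of ``b`` (bases
``< b``); a ``LEFT_ANCHORED`` breakend means the retained segment starts at
``b`` and extends rightward.  Conversion from the 1-based variant-call format
happens exactly once, at read time (see :mod:`cnvpost.caller_io`).

Orientation bijections
----------------------
====================  ==============  =====================================
orientation           BEDPE strand    VCF breakend bracket (local side)
====================  ==============  =====================================
RIGHT_ANCHORED        ``+``           ``t[p[`` / ``t]p]`` (t before bracket)
LEFT_ANCHORED         ``-``           ``]p]t`` / ``[p[t`` (t after bracket)
====================  ==============  =====================================

The bracket shape itself (``[`` vs ``]``) encodes the *mate's* orientation:
``[p[`` joins onto a LEFT_ANCHORED mate, ``]p]`` onto a RIGHT_ANCHORED one.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace


class Unknown:
    """Sentinel for an unknown quantity (e.g. size of an unresolved insertion).

    Deliberately not comparable to or usable in arithmetic with numbers, so
    missingness can never silently flow into a computation.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNKNOWN"

    def __reduce__(self):
        return (Unknown, ())


#: Module-level singleton; identity comparison (``x is UNKNOWN``) is safe.
UNKNOWN = Unknown()


class Orientation(enum.Enum):
    """Which side of a breakend the retained reference segment lies on."""

    RIGHT_ANCHORED = "+"  # retained segment extends to coordinates < pos
    LEFT_ANCHORED = "-"  # retained segment extends to coordinates >= pos

    @property
    def strand(self) -> str:
        return self.value

    @classmethod
    def from_strand(cls, strand: str) -> "Orientation":
        for o in cls:
            if o.value == strand:
                return o
        raise ValueError(f"unknown strand symbol {strand!r}")


RIGHT = Orientation.RIGHT_ANCHORED
LEFT = Orientation.LEFT_ANCHORED


class CNVType(enum.Enum):
    DEL = "DEL"
    INS = "INS"
    TDUP = "TDUP"
    DDUP = "DDUP"

    def __str__(self) -> str:
        return self.value


#: Caller identifiers understood by the pipeline.
KNOWN_TOOLS = ("DELLY", "GRIDSS", "LUMPY", "MANTA", "SIM")

_NAT_SPLIT = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str):
    """Natural ordering of chromosome names: ``chr2`` sorts before ``chr10``."""
    return tuple(int(p) if p.isdigit() else p for p in _NAT_SPLIT.split(chrom))


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval; ``start == end`` encodes a point feature."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start > self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len(a), overlap/len(b)); 0 for empty intervals."""
        ov = self.overlap(other)
        if ov == 0 or self.length() == 0 or other.length() == 0:
            return 0.0
        return min(ov / self.length(), ov / other.length())

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Locus:
    """A point position (boundary coordinate), e.g. an insertion site."""

    chrom: str
    pos: int

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError(f"negative position {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    orientation: Orientation

    def __post_init__(self):
        if not isinstance(self.chrom, str) or not self.chrom:
            raise ValidationError(f"bad chromosome name {self.chrom!r}")
        if self.pos < 0:
            raise ValidationError(f"negative breakend position {self.pos}")
        if not isinstance(self.orientation, Orientation):
            raise ValidationError(f"bad orientation {self.orientation!r}")

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos)

    def full_key(self):
        # orientation breaks ties at equal positions (RIGHT before LEFT),
        # so canonical ordering is total and order-insensitive
        return (chrom_sort_key(self.chrom), self.pos,
                0 if self.orientation is Orientation.RIGHT_ANCHORED else 1)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}({self.orientation.strand})"


@dataclass
class NovelAdjacency:
    """A pair of mated breakends joined in the sample but not the reference.

    Constructors enforce canonical ordering: ``bnd1`` is the breakend with
    the smaller (chromosome, position) under natural chromosome order, so an
    adjacency compares equal regardless of the order its mates were seen in.
    """

    id: str
    bnd1: Breakend
    bnd2: Breakend
    pe_support: int = 0
    sr_support: int = 0
    source_tool: str = "SIM"
    inserted_seq: "str | Unknown | None" = None

    def __post_init__(self):
        if self.bnd1.full_key() > self.bnd2.full_key():
            self.bnd1, self.bnd2 = self.bnd2, self.bnd1
        if self.pe_support < 0 or self.sr_support < 0:
            raise ValidationError("negative support count")

    @property
    def intrachromosomal(self) -> bool:
        return self.bnd1.chrom == self.bnd2.chrom

    @property
    def span(self) -> int | None:
        """Distance between breakends for intrachromosomal adjacencies."""
        if not self.intrachromosomal:
            return None
        return self.bnd2.pos - self.bnd1.pos

    @property
    def orientations(self) -> tuple[Orientation, Orientation]:
        return (self.bnd1.orientation, self.bnd2.orientation)

    def sort_key(self):
        return self.bnd1.sort_key() + self.bnd2.sort_key()

    def __str__(self) -> str:
        return f"{self.bnd1}--{self.bnd2}[{self.source_tool}]"


def canonicalize_adjacency(
    bnd_a: Breakend,
    bnd_b: Breakend,
    *,
    id: str = "",
    pe_support: int = 0,
    sr_support: int = 0,
    source_tool: str = "SIM",
    inserted_seq: "str | Unknown | None" = None,
) -> NovelAdjacency:
    """Build an adjacency from an unordered breakend pair.

    Idempotent and order-insensitive: swapping the two breakends yields an
    identical adjacency, with each orientation travelling with its breakend.
    """
    return NovelAdjacency(
        id=id,
        bnd1=bnd_a,
        bnd2=bnd_b,
        pe_support=pe_support,
        sr_support=sr_support,
        source_tool=source_tool,
        inserted_seq=inserted_seq,
    )


@dataclass
class CNVCall:
    """A typed copy-number event backed by one (DEL/INS/TDUP) or two (DDUP)
    novel adjacencies.

    For dispersed duplications ``region`` is the duplicated *template*, and
    ``insertion_point`` gives where the copy landed.  For insertions
    ``region`` is the zero-length insertion site interval.
    """

    cnv_type: CNVType
    region: GenomicInterval
    adjacencies: list[NovelAdjacency]
    insertion_point: Locus | None = None
    pe_support: float = 0
    sr_support: float = 0
    source_tools: frozenset = frozenset()
    inserted_seq: "str | Unknown | None" = None
    score: float | None = None
    name: str = ""

    def __post_init__(self):
        n_expected = 2 if self.cnv_type is CNVType.DDUP else 1
        if len(self.adjacencies) != n_expected:
            raise ValidationError(
                f"{self.cnv_type} call must have {n_expected} adjacencies, "
                f"got {len(self.adjacencies)}"
            )
        if self.cnv_type in (CNVType.INS, CNVType.DDUP) and self.insertion_point is None:
            raise ValidationError(f"{self.cnv_type} call requires an insertion_point")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")
        if not isinstance(self.source_tools, frozenset):
            self.source_tools = frozenset(self.source_tools)

    @property
    def size(self) -> "int | Unknown":
        return cnv_size(self)

    def with_score(self, score: float) -> "CNVCall":
        return replace(self, score=score)

    def sort_key(self):
        return (
            chrom_sort_key(self.region.chrom),
            self.region.start,
            self.region.end,
            self.cnv_type.value,
        )


def cnv_size(call: CNVCall) -> "int | Unknown":
    """Event size in bp; UNKNOWN for insertions with unresolved sequence."""
    if call.cnv_type is CNVType.INS:
        if isinstance(call.inserted_seq, str):
            return len(call.inserted_seq)
        return UNKNOWN
    return call.region.length()


@dataclass
class AdjacencyCluster:
    """Single-linkage group of same-tool adjacencies whose breakpoints
    co-locate within ``linkage_window`` bp on either end."""

    members: list[NovelAdjacency]
    linkage_window: int = 10

    def __post_init__(self):
        tools = {m.source_tool for m in self.members}
        if len(tools) > 1:
            raise ValidationError(f"cluster mixes source tools: {sorted(tools)}")

    @property
    def source_tool(self) -> str:
        return self.members[0].source_tool

    def sort_key(self):
        return min(m.sort_key() for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MergedCall:
    """A cross-tool consensus call.

    The region is the minimal interval covering every donor region; the
    paired-end and split-read supports are the medians over donors (mean of
    the central pair for an even donor count, kept as a real number); the
    tool set is the union of donor tool sets.
    """

    cnv_type: CNVType
    region: GenomicInterval
    donors: list[CNVCall]
    insertion_point: Locus | None = None
    pe_support: float = 0.0
    sr_support: float = 0.0
    source_tools: frozenset = frozenset()
    inserted_seq: "str | Unknown | None" = None
    score: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")
        if not isinstance(self.source_tools, frozenset):
            self.source_tools = frozenset(self.source_tools)

    @property
    def adjacencies(self) -> list[NovelAdjacency]:
        return [a for d in self.donors for a in d.adjacencies]

    @property
    def size(self) -> "int | Unknown":
        if self.cnv_type is CNVType.INS:
            if isinstance(self.inserted_seq, str):
                return len(self.inserted_seq)
            return UNKNOWN
        return self.region.length()

    def with_score(self, score: float) -> "MergedCall":
        return replace(self, score=score)

    def sort_key(self):
        return (
            chrom_sort_key(self.region.chrom),
            self.region.start,
            self.region.end,
            self.cnv_type.value,
        )
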
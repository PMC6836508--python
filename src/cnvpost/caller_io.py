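"""Reading caller VCF dialects into novel adjacencies; BEDPE output.

Every supported short-read SV caller emits VCF, but each encodes calls and
their read support differently: some report symbolic ALT records
(``<DEL>``, ``<DUP>``, ``<INS>``), some only paired breakend (``BND``)
records, and the INFO/FORMAT keys holding paired-end and split-read counts
vary per tool.  Dialects are data-driven (:class:`CallerDialect`): adding a
tool means adding a field map, not a code path.

Coordinates are converted to the internal 0-based half-open boundary
convention exactly once, on read (see :mod:`cnvpost.model`), and converted
back on write, so VCF -> internal -> VCF reproduces the original 1-based
positions.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import re
from dataclasses import dataclass, field

from cyvcf2 import VCF

from .model import (
    LEFT,
    RIGHT,
    UNKNOWN,
    Breakend,
    CNVCall,
    CNVType,
    GenomicInterval,
    Locus,
    MergedCall,
    NovelAdjacency,
    Orientation,
    Unknown,
    ValidationError,
    canonicalize_adjacency,
)

logger = logging.getLogger(__name__)

SYMBOLIC = "SYMBOLIC"
BREAKEND_ONLY = "BREAKEND_ONLY"
MIXED = "MIXED"


@dataclass(frozen=True)
class CallerDialect:
    """How one caller encodes calls and read support in its VCF.

    ``pe_fields``/``sr_fields`` are ordered candidate lists of
    ``(location, key)`` pairs, where location is ``"FORMAT"`` or ``"INFO"``;
    the first key present on a record wins.  Sample-level (FORMAT) keys are
    listed before site-level (INFO) ones, since the single-sample workflow
    wants per-sample evidence.
    """

    tool: str
    record_style: str
    pe_fields: tuple
    sr_fields: tuple

    def __post_init__(self):
        if self.record_style not in (SYMBOLIC, BREAKEND_ONLY, MIXED):
            raise ValidationError(f"unknown record style {self.record_style!r}")


#: Default dialect maps for the supported callers.  The INFO ``PE``/``SR``
#: fallbacks let emulated (simulator-written) VCFs be read through any
#: dialect.  Keys are editable defaults; caller versions change them.
DIALECTS = {
    "DELLY": CallerDialect(
        "DELLY", MIXED,
        pe_fields=(("FORMAT", "DV"), ("INFO", "PE")),
        sr_fields=(("FORMAT", "RV"), ("INFO", "SR")),
    ),
    "LUMPY": CallerDialect(
        "LUMPY", SYMBOLIC,
        pe_fields=(("FORMAT", "PE"), ("INFO", "PE")),
        sr_fields=(("FORMAT", "SR"), ("INFO", "SR")),
    ),
    "MANTA": CallerDialect(
        "MANTA", MIXED,
        pe_fields=(("FORMAT", "PR"), ("INFO", "PE")),
        sr_fields=(("FORMAT", "SR"), ("INFO", "SR")),
    ),
    "GRIDSS": CallerDialect(
        "GRIDSS", BREAKEND_ONLY,
        pe_fields=(("INFO", "RP"), ("INFO", "PE")),
        sr_fields=(("INFO", "SR"),),
    ),
    "SIM": CallerDialect(
        "SIM", SYMBOLIC,
        pe_fields=(("INFO", "PE"),),
        sr_fields=(("INFO", "SR"),),
    ),
}

_BND_RE = re.compile(
    r"^(?P<before>[ACGTNacgtn]*)"
    r"(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)(?P<b2>[\[\]])"
    r"(?P<after>[ACGTNacgtn]*)$"
)


@dataclass
class ReadStats:
    n_records: int = 0
    n_adjacencies: int = 0
    n_unmatched_bnd: int = 0
    n_missing_support: int = 0


def _scalar_count(value) -> int | None:
    """Coerce an INFO/FORMAT value into a non-negative int count.

    FORMAT arrays are per-sample (first sample used); tuple-valued fields
    such as Manta's ``PR=(ref, alt)`` contribute their last element, the
    alt-supporting count.
    """
    if value is None:
        return None
    try:
        import numpy as np

        if isinstance(value, np.ndarray):
            value = value.reshape(value.shape[0], -1)[0]
            value = value[-1]
        elif isinstance(value, (tuple, list)):
            value = value[-1]
        v = int(value)
    except (TypeError, ValueError, IndexError):
        return None
    return max(v, 0)


def _support(variant, fields, stats: ReadStats) -> int:
    for location, key in fields:
        if location == "INFO":
            v = _scalar_count(variant.INFO.get(key))
        else:
            try:
                v = _scalar_count(variant.format(key))
            except KeyError:
                v = None
        if v is not None:
            return v
    stats.n_missing_support += 1
    return 0


def _ci(variant, key):
    v = variant.INFO.get(key)
    if v is None:
        return None
    if isinstance(v, (tuple, list)):
        return (int(v[0]), int(v[1]))
    return None


def _parse_bnd_local(variant):
    """Local breakend + mate locus + inserted sequence from a BND record."""
    alt = variant.ALT[0]
    m = _BND_RE.match(alt)
    if m is None:
        return None
    before, after = m.group("before"), m.group("after")
    if before:
        local_orient = RIGHT
        local_pos = variant.POS  # 1-based anchored base == boundary coordinate
        inserted = before[len(variant.REF):] or None
    else:
        local_orient = LEFT
        local_pos = variant.POS - 1
        inserted = after[: len(after) - len(variant.REF)] or None
    bnd = Breakend(variant.CHROM, local_pos, local_orient)
    return bnd, inserted


def _svtype(variant) -> str | None:
    alt = variant.ALT[0] if variant.ALT else None
    if alt and ("[" in alt or "]" in alt):
        return "BND"
    info_type = variant.INFO.get("SVTYPE")
    if alt and alt.startswith("<"):
        sym = alt.strip("<>").split(":")[0]
        return sym
    if info_type:
        return str(info_type)
    # literal REF/ALT records
    if alt and len(variant.REF) == 1 and len(alt) > 1:
        return "INS"
    if alt and len(alt) == 1 and len(variant.REF) > 1:
        return "DEL"
    return None


def _record_end(variant) -> int:
    end = variant.INFO.get("END")
    if end is not None:
        return int(end)
    svlen = variant.INFO.get("SVLEN")
    if svlen is not None:
        return variant.POS + abs(int(svlen if not isinstance(svlen, (tuple, list)) else svlen[0]))
    return variant.POS + max(len(variant.REF) - 1, 0)


def read_caller_vcf_with_stats(path, dialect: CallerDialect):
    """Parse one caller VCF into canonical novel adjacencies.

    Symbolic DEL/DUP/INS/INV records become one adjacency each; BND records
    are paired via MATEID, each mate pair consumed exactly once.  Unmatched
    BND mates are skipped with a warning and counted in the returned stats.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    stats = ReadStats()
    adjacencies: list[NovelAdjacency] = []
    pending_bnd: dict[str, tuple] = {}  # record ID -> (mate id, breakend, meta)

    for variant in VCF(str(path)):
        stats.n_records += 1
        svtype = _svtype(variant)
        pe = _support(variant, dialect.pe_fields, stats)
        sr = _support(variant, dialect.sr_fields, stats)
        cipos = _ci(variant, "CIPOS")
        ciend = _ci(variant, "CIEND")
        vid = variant.ID or f"{dialect.tool}_rec{stats.n_records}"

        if svtype == "BND":
            parsed = _parse_bnd_local(variant)
            mate_id = variant.INFO.get("MATEID")
            if parsed is None or mate_id is None:
                stats.n_unmatched_bnd += 1
                logger.warning("skipping unpairable BND record %s", vid)
                continue
            bnd, inserted = parsed
            mate_id = str(mate_id)
            if mate_id in pending_bnd:
                expected_mate, other_bnd, other_meta = pending_bnd.pop(mate_id)
                if expected_mate != vid:
                    stats.n_unmatched_bnd += 2
                    logger.warning("BND mate mismatch for %s / %s", vid, mate_id)
                    continue
                o_pe, o_sr, o_ins, o_ci = other_meta
                adjacencies.append(
                    canonicalize_adjacency(
                        other_bnd,
                        bnd,
                        id=mate_id,
                        pe_support=max(pe, o_pe),
                        sr_support=max(sr, o_sr),
                        source_tool=dialect.tool,
                        inserted_seq=inserted or o_ins,
                    )
                )
            else:
                pending_bnd[vid] = (mate_id, bnd, (pe, sr, inserted, cipos))
            continue

        if svtype is None:
            logger.warning("record %s has no recognizable variant type; skipped", vid)
            continue

        pos, end = variant.POS, _record_end(variant)
        if svtype == "DEL":
            b1, b2 = Breakend(variant.CHROM, pos, RIGHT), Breakend(variant.CHROM, end, LEFT)
            inserted = None
            if variant.ALT and not variant.ALT[0].startswith("<"):
                # literal deletion: boundaries from REF length
                b2 = Breakend(variant.CHROM, pos + len(variant.REF) - 1, LEFT)
        elif svtype == "DUP":
            b1, b2 = Breakend(variant.CHROM, pos, LEFT), Breakend(variant.CHROM, end, RIGHT)
            inserted = None
        elif svtype == "INS":
            b1, b2 = Breakend(variant.CHROM, pos, RIGHT), Breakend(variant.CHROM, pos, LEFT)
            seq = variant.INFO.get("SVINSSEQ")
            if seq is None and variant.ALT and not variant.ALT[0].startswith("<"):
                seq = variant.ALT[0][1:]
            inserted = str(seq) if seq else UNKNOWN
        elif svtype == "INV":
            # recognized only to be excluded later: same-orientation pair
            b1, b2 = Breakend(variant.CHROM, pos, RIGHT), Breakend(variant.CHROM, end, RIGHT)
            inserted = None
        else:
            logger.warning("unknown symbolic ALT %s in record %s; skipped", svtype, vid)
            continue
        adjacencies.append(
            canonicalize_adjacency(
                b1, b2, id=vid, pe_support=pe, sr_support=sr,
                source_tool=dialect.tool, inserted_seq=inserted,
            )
        )

    if pending_bnd:
        stats.n_unmatched_bnd += len(pending_bnd)
        logger.warning("%d BND records had no mate and were skipped", len(pending_bnd))
    stats.n_adjacencies = len(adjacencies)
    return adjacencies, stats


def read_caller_vcf(path, dialect) -> list[NovelAdjacency]:
    adjacencies, _ = read_caller_vcf_with_stats(path, dialect)
    return adjacencies


# ---------------------------------------------------------------------------
# VCF writing (used by the caller emulator and for coordinate round-trips)

def _vcf_pos(bnd: Breakend) -> int:
    """1-based VCF position of the anchored base at a boundary breakend."""
    return bnd.pos if bnd.orientation is RIGHT else bnd.pos + 1


def _bnd_alt(local: Breakend, mate: Breakend, inserted) -> str:
    bracket = "]" if mate.orientation is RIGHT else "["
    mate_part = f"{bracket}{mate.chrom}:{_vcf_pos(mate)}{bracket}"
    seq = inserted if isinstance(inserted, str) else ""
    if local.orientation is RIGHT:
        return f"N{seq}{mate_part}"
    return f"{mate_part}{seq}N"


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=SVINSSEQ,Number=1,Type=String,Description="Inserted sequence">',
    '##INFO=<ID=PE,Number=1,Type=Integer,Description="Discordant read pair support">',
    '##INFO=<ID=SR,Number=1,Type=Integer,Description="Split read support">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">',
    '##ALT=<ID=INS,Description="Insertion">',
]


def write_adjacency_vcf(
    adjacencies,
    path,
    chrom_lengths: dict | None = None,
    style: str = SYMBOLIC,
):
    """Write adjacencies as a caller-style VCF (symbolic where possible, or
    breakend-only), suitable for re-reading through any dialect."""
    if chrom_lengths is None:
        chrom_lengths = {}
        for adj in adjacencies:
            for bnd in (adj.bnd1, adj.bnd2):
                chrom_lengths[bnd.chrom] = max(
                    chrom_lengths.get(bnd.chrom, 0), bnd.pos + 1000
                )
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in chrom_lengths.items()]
    lines += _VCF_HEADER_LINES
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def emit(chrom, pos, vid, alt, info):
        lines.append(f"{chrom}\t{pos}\t{vid}\tN\t{alt}\t.\tPASS\t{info}")

    records = []
    for k, adj in enumerate(adjacencies):
        vid = adj.id or f"adj{k}"
        support = f"PE={adj.pe_support};SR={adj.sr_support}"
        symbolic = None
        if style != BREAKEND_ONLY and adj.intrachromosomal:
            o = adj.orientations
            if isinstance(adj.inserted_seq, (str, Unknown)) and adj.span == 0:
                info = f"SVTYPE=INS;END={_vcf_pos(adj.bnd1)};{support}"
                if isinstance(adj.inserted_seq, str):
                    info += f";SVINSSEQ={adj.inserted_seq}"
                symbolic = (adj.bnd1.chrom, _vcf_pos(adj.bnd1), vid, "<INS>", info)
            elif adj.inserted_seq is None and o == (RIGHT, LEFT) and adj.span > 0:
                symbolic = (
                    adj.bnd1.chrom, adj.bnd1.pos, vid, "<DEL>",
                    f"SVTYPE=DEL;END={adj.bnd2.pos};{support}",
                )
            elif adj.inserted_seq is None and o == (LEFT, RIGHT) and adj.span > 0:
                symbolic = (
                    adj.bnd1.chrom, adj.bnd1.pos, vid, "<DUP:TANDEM>",
                    f"SVTYPE=DUP;END={adj.bnd2.pos};{support}",
                )
        if symbolic is not None:
            records.append((symbolic[0], symbolic[1], symbolic[2:]))
        else:
            id1, id2 = f"{vid}_1", f"{vid}_2"
            for local, mate, lid, mid in (
                (adj.bnd1, adj.bnd2, id1, id2),
                (adj.bnd2, adj.bnd1, id2, id1),
            ):
                alt = _bnd_alt(local, mate, adj.inserted_seq)
                info = f"SVTYPE=BND;MATEID={mid};{support}"
                records.append((local.chrom, _vcf_pos(local), (lid, alt, info)))

    from .model import chrom_sort_key

    records.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
    for chrom, pos, (vid, alt, info) in records:
        emit(chrom, pos, vid, alt, info)
    _write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BEDPE

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "cnv_type", "size", "pe_support", "sr_support", "source_tools",
    "insertion_point", "detail",
]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _write_text(path, text):
    try:
        with _open_text(path, "wt") as fh:
            fh.write(text)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def _breakend_intervals(call):
    """Presentational breakend loci + strand pair for one call.

    DEL-type adjacencies anchor ``+/-`` (last retained base / first retained
    base); duplications ``-/+`` (the copied segment opens at its 5' end).
    """
    s, e = call.region.start, call.region.end
    if call.cnv_type is CNVType.DEL:
        return (max(0, s - 1), s, e, e + 1, "+", "-")
    if call.cnv_type in (CNVType.TDUP, CNVType.DDUP):
        return (s, s + 1, max(s, e - 1), e, "-", "+")
    p = call.region.start  # INS: zero-length site
    return (max(0, p - 1), p, p, p + 1, "+", "-")


def _adj_to_json(adj: NovelAdjacency) -> dict:
    return {
        "id": adj.id,
        "b1": [adj.bnd1.chrom, adj.bnd1.pos, adj.bnd1.orientation.strand],
        "b2": [adj.bnd2.chrom, adj.bnd2.pos, adj.bnd2.orientation.strand],
        "pe": adj.pe_support,
        "sr": adj.sr_support,
        "tool": adj.source_tool,
        "ins": _seq_to_json(adj.inserted_seq),
    }


def _adj_from_json(d: dict) -> NovelAdjacency:
    return NovelAdjacency(
        id=d["id"],
        bnd1=Breakend(d["b1"][0], d["b1"][1], Orientation.from_strand(d["b1"][2])),
        bnd2=Breakend(d["b2"][0], d["b2"][1], Orientation.from_strand(d["b2"][2])),
        pe_support=d["pe"],
        sr_support=d["sr"],
        source_tool=d["tool"],
        inserted_seq=_seq_from_json(d["ins"]),
    )


def _seq_to_json(seq):
    if seq is UNKNOWN:
        return "UNKNOWN"
    return seq


def _seq_from_json(v):
    if v == "UNKNOWN":
        return UNKNOWN
    return v


def _call_to_json(call) -> dict:
    d = {
        "type": call.cnv_type.value,
        "region": [call.region.chrom, call.region.start, call.region.end],
        "ip": [call.insertion_point.chrom, call.insertion_point.pos]
        if call.insertion_point
        else None,
        "pe": call.pe_support,
        "sr": call.sr_support,
        "tools": sorted(call.source_tools),
        "ins": _seq_to_json(call.inserted_seq),
        "score": call.score,
        "name": call.name,
    }
    if isinstance(call, MergedCall):
        d["donors"] = [_call_to_json(x) for x in call.donors]
    else:
        d["adj"] = [_adj_to_json(a) for a in call.adjacencies]
    return d


def _call_from_json(d: dict):
    region = GenomicInterval(*d["region"])
    ip = Locus(*d["ip"]) if d["ip"] else None
    common = dict(
        cnv_type=CNVType(d["type"]),
        region=region,
        insertion_point=ip,
        pe_support=d["pe"],
        sr_support=d["sr"],
        source_tools=frozenset(d["tools"]),
        inserted_seq=_seq_from_json(d["ins"]),
        score=d["score"],
        name=d["name"],
    )
    if "donors" in d:
        return MergedCall(donors=[_call_from_json(x) for x in d["donors"]], **common)
    return CNVCall(adjacencies=[_adj_from_json(a) for a in d["adj"]], **common)


def write_bedpe(calls, path):
    """Write calls (plain or merged) as BEDPE, 0-based half-open.

    The first ten columns are standard BEDPE (paired breakend loci, name,
    score, strand pair); the extra columns carry the call type, size, median
    supports, tool provenance and insertion point.  The final ``detail``
    column is a JSON blob holding the exact adjacency (and, for merged
    calls, donor) structure so that :func:`read_bedpe` is lossless.
    """
    lines = ["#" + "\t".join(BEDPE_COLUMNS)]
    for call in calls:
        s1, e1, s2, e2, st1, st2 = _breakend_intervals(call)
        size = call.size
        ip = call.insertion_point
        row = [
            call.region.chrom, s1, e1,
            ip.chrom if call.cnv_type is CNVType.DDUP and ip else call.region.chrom,
            *( (max(0, ip.pos - 1), ip.pos + 1) if call.cnv_type is CNVType.DDUP and ip
               else (s2, e2) ),
            call.name or ".",
            repr(call.score) if call.score is not None else ".",
            st1, st2,
            call.cnv_type.value,
            "." if size is UNKNOWN else size,
            repr(float(call.pe_support)),
            repr(float(call.sr_support)),
            ",".join(sorted(call.source_tools)) or ".",
            str(ip) if ip else ".",
            json.dumps(_call_to_json(call), separators=(",", ":")),
        ]
        lines.append("\t".join(str(x) for x in row))
    _write_text(path, "\n".join(lines) + "\n")


def read_bedpe(path):
    """Read a BEDPE file written by :func:`write_bedpe`; exact inverse.

    Lines missing the ``detail`` column (hand-written files following the
    documented columns) are reconstructed from the standard columns, with
    canonical adjacencies derived from type and region.
    """
    calls = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 16:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >= 16 BEDPE columns, "
                    f"got {len(fields)}"
                )
            try:
                if len(fields) >= 17 and fields[16] != ".":
                    calls.append(_call_from_json(json.loads(fields[16])))
                else:
                    calls.append(_call_from_columns(fields))
            except (ValueError, KeyError, ValidationError) as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: malformed record ({exc})"
                ) from exc
    return calls


def _call_from_columns(f):
    """Reconstruct a call from the documented columns (no detail blob)."""
    chrom1, s1, e1 = f[0], int(f[1]), int(f[2])
    chrom2, s2, e2 = f[3], int(f[4]), int(f[5])
    cnv_type = CNVType(f[10])
    if cnv_type is CNVType.DEL:
        region = GenomicInterval(chrom1, e1, s2)
    elif cnv_type is CNVType.TDUP:
        region = GenomicInterval(chrom1, s1, e2)
    elif cnv_type is CNVType.DDUP:
        size = int(f[11])
        region = GenomicInterval(chrom1, s1, s1 + size)
    else:
        region = GenomicInterval(chrom1, e1, e1)
    ip = None
    if f[15] != ".":
        c, p = f[15].rsplit(":", 1)
        ip = Locus(c, int(p))
    adjacencies = _canonical_adjacencies(cnv_type, region, ip, None)
    return CNVCall(
        cnv_type=cnv_type,
        region=region,
        adjacencies=adjacencies,
        insertion_point=ip,
        pe_support=float(f[12]),
        sr_support=float(f[13]),
        source_tools=frozenset(f[14].split(",")) if f[14] != "." else frozenset(),
        score=float(f[7]) if f[7] != "." else None,
        name=f[6] if f[6] != "." else "",
    )


def _canonical_adjacencies(cnv_type, region, ip, inserted_seq):
    """Idealized adjacency signature for a call of known type and region."""
    c, s, e = region.chrom, region.start, region.end
    if cnv_type is CNVType.DEL:
        return [canonicalize_adjacency(Breakend(c, s, RIGHT), Breakend(c, e, LEFT))]
    if cnv_type is CNVType.TDUP:
        return [canonicalize_adjacency(Breakend(c, s, LEFT), Breakend(c, e, RIGHT))]
    if cnv_type is CNVType.INS:
        return [
            canonicalize_adjacency(
                Breakend(c, s, RIGHT), Breakend(c, s, LEFT),
                inserted_seq=inserted_seq if inserted_seq is not None else UNKNOWN,
            )
        ]
    p = ip.pos
    if ip.chrom != c or p >= e:
        return [
            canonicalize_adjacency(Breakend(c, s, LEFT), Breakend(ip.chrom, p, RIGHT)),
            canonicalize_adjacency(Breakend(c, e, RIGHT), Breakend(ip.chrom, p, LEFT)),
        ]
    return [
        canonicalize_adjacency(Breakend(ip.chrom, p, RIGHT), Breakend(c, s, LEFT)),
        canonicalize_adjacency(Breakend(ip.chrom, p, LEFT), Breakend(c, e, RIGHT)),
    ]
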
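"""Domain records and format I/O.

All public records use 0-based, half-open coordinates. Conversion to the
1-based conventions of VCF/segment dialects happens only inside the readers
and writers in this module.

Supported dialects
------------------
* SV VCF 4.2 — paired breakend (BND) records with ``MATEID``, or typed records
  (``SVTYPE=DEL/DUP/INV/TRA`` with ``END``/``CHR2``/``STRANDS``).
* SNV/indel VCF 4.2 with per-sample ``DP`` and ``AD``.
* CNVkit ``.cns``-style tab-separated segments (extra columns ignored).
* BED3 / BED12, tab-separated impact and depth tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

from .genome import chrom_sort_key, normalize_chrom

SV_TYPES = ("DEL", "DUP", "h2hINV", "t2tINV", "TRA")

_ORIENT_TO_TYPE = {("+", "-"): "DEL", ("-", "+"): "DUP",
                   ("+", "+"): "h2hINV", ("-", "-"): "t2tINV"}


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chromosome: str, pos: int) -> bool:
        return chromosome == self.chromosome and self.start <= pos < self.end


@dataclass(frozen=True)
class SvCall:
    """One structural variant as an oriented breakpoint pair.

    ``strand`` follows the breakend convention: '+' means the sequence to the
    left of the breakpoint is retained in the derivative junction, '-' the
    sequence to the right. Orientation determines the type for
    intrachromosomal events: +- DEL, -+ DUP, ++ h2hINV, -- t2tINV.
    """

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_type: str
    vaf: float | None = None
    alt_reads: int | None = None
    depth: int | None = None
    sample_id: str | None = None
    sv_id: str | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if (self.chrom1 != self.chrom2) != (self.sv_type == "TRA"):
            raise ValueError("TRA if and only if breakpoints on different chromosomes")
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            raise ValueError("intrachromosomal breakpoints must be ordered pos1 <= pos2")

    @property
    def interval(self) -> tuple[int, int]:
        """[pos1, pos2] span for intrachromosomal events."""
        if self.sv_type == "TRA":
            raise ValueError("translocations have no single-chromosome span")
        return (self.pos1, self.pos2)

    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


def canonical_sv(chrom1: str, pos1: int, strand1: str,
                 chrom2: str, pos2: int, strand2: str, **kw) -> SvCall:
    """Build an SvCall with breakpoints in canonical order, deriving the type.

    Canonical order is (chromosome, position) ascending; each end keeps its
    own orientation when the ends are swapped.
    """
    key1 = (chrom_sort_key(chrom1), pos1)
    key2 = (chrom_sort_key(chrom2), pos2)
    if key2 < key1:
        chrom1, pos1, strand1, chrom2, pos2, strand2 = (
            chrom2, pos2, strand2, chrom1, pos1, strand1)
    if chrom1 != chrom2:
        sv_type = "TRA"
    else:
        sv_type = _ORIENT_TO_TYPE[(strand1, strand2)]
    return SvCall(chrom1, pos1, strand1, chrom2, pos2, strand2, sv_type, **kw)


@dataclass(frozen=True)
class SnvCall:
    chromosome: str
    position: int  # 0-based
    ref: str
    alt: str
    depth: int | None = None
    alt_count: int | None = None
    callers: frozenset[str] = frozenset()
    hq_alt_count: int | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.alt_count is not None:
            if not (0 <= self.alt_count <= self.depth):
                raise ValueError(
                    f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
                )

    @property
    def vaf(self) -> float | None:
        if self.depth in (None, 0) or self.alt_count is None:
            return None
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class CnSegment:
    chromosome: str
    start: int
    end: int
    log2_fold_change: float
    copy_number: float | None = None
    gene: str = "-"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start: {self.chromosome}:{self.start}-{self.end}"
            )
        if self.copy_number is not None and self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    name: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for exon in self.exons:
            if exon.chromosome != self.chromosome:
                raise ValueError(f"exon of {self.name} on wrong chromosome")
            if exon.start < self.start or exon.end > self.end:
                raise ValueError(f"exon outside gene body of {self.name}")

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end, self.strand)


# ---------------------------------------------------------------------------
# SV VCF

_BND_RE = re.compile(
    r"^(?P<head>[A-Za-z.*]*)(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<tail>[A-Za-z.*]*)$"
)


def _bnd_alt(strand1: str, strand2: str, chrom2: str, pos2_1based: int, ref: str) -> str:
    inner = f"{chrom2}:{pos2_1based}"
    if strand1 == "+":
        return f"{ref}[{inner}[" if strand2 == "-" else f"{ref}]{inner}]"
    return f"]{inner}]{ref}" if strand2 == "+" else f"[{inner}[{ref}"


def _parse_bnd_alt(alt: str) -> tuple[str, str, str, int]:
    """ALT breakend string -> (strand1, strand2, mate_chrom, mate_pos0)."""
    m = _BND_RE.match(alt)
    if m is None:
        raise ParseError(f"unparseable breakend ALT {alt!r}")
    strand1 = "+" if m.group("head") else "-"
    strand2 = "+" if m.group("b1") == "]" else "-"
    return strand1, strand2, m.group("chrom"), int(m.group("pos")) - 1


_SV_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at the junction">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_sv_vcf(calls: list[SvCall], path: str | Path, sample_id: str = "TUMOR") -> None:
    """Write SVs as paired BND records (VCF 4.2, MATEID-linked)."""
    lines = [_SV_VCF_HEADER]
    contigs = sorted({c for call in calls for c in (call.chrom1, call.chrom2)},
                     key=chrom_sort_key)
    for chrom in contigs:
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
    for i, call in enumerate(calls):
        base = call.sv_id or f"sv{i}"
        dp = call.depth if call.depth is not None else "."
        if call.depth is not None and call.alt_reads is not None:
            ad = f"{call.depth - call.alt_reads},{call.alt_reads}"
        else:
            ad = "."
        fmt = f"GT:DP:AD\t./.:{dp}:{ad}"
        ends = [
            (call.chrom1, call.pos1, call.strand1, call.chrom2, call.pos2, call.strand2),
            (call.chrom2, call.pos2, call.strand2, call.chrom1, call.pos1, call.strand1),
        ]
        for j, (c1, p1, s1, c2, p2, s2) in enumerate(ends):
            rid, mate = f"{base}_{j + 1}", f"{base}_{2 - j}"
            alt = _bnd_alt(s1, s2, c2, p2 + 1, "N")
            lines.append(
                f"{c1}\t{p1 + 1}\t{rid}\tN\t{alt}\t.\tPASS\t"
                f"SVTYPE=BND;MATEID={mate}\t{fmt}\n"
            )
    Path(path).write_text("".join(lines))


def _sv_format_fields(rec) -> dict:
    out: dict = {}
    if rec.samples:
        sample = rec.samples[next(iter(rec.samples))]
        dp = sample.get("DP")
        ad = sample.get("AD")
        if isinstance(ad, tuple):
            ad = ad[0] if len(ad) == 1 else ad[-1]
        out["depth"] = dp
        out["alt_reads"] = ad
        if dp not in (None, 0) and ad is not None:
            out["vaf"] = ad / dp
    return out


def read_sv_vcf(path: str | Path, sample_id: str | None = None) -> list[SvCall]:
    """Read SVs from a VCF with BND pairs and/or typed SV records."""
    calls: list[SvCall] = []
    bnd: dict[str, object] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype == "BND":
                bnd[rec.id] = rec
                continue
            calls.append(_typed_record_to_call(rec, svtype, sample_id))
    paired: set[str] = set()
    for rid, rec in bnd.items():
        if rid in paired:
            continue
        mate_id = rec.info.get("MATEID")
        if isinstance(mate_id, tuple):
            mate_id = mate_id[0]
        if mate_id is None or mate_id not in bnd:
            raise ParseError(f"orphan breakend record {rid!r} (mate {mate_id!r} missing)")
        paired.update((rid, mate_id))
        strand1, strand2, mchrom, mpos = _parse_bnd_alt(rec.alts[0])
        kw = _sv_format_fields(rec)
        kw.setdefault("vaf", None)
        calls.append(canonical_sv(
            rec.chrom, rec.pos - 1, strand1, mchrom, mpos, strand2,
            sample_id=sample_id, sv_id=str(rid).rsplit("_", 1)[0], **kw))
    calls.sort(key=lambda c: (chrom_sort_key(c.chrom1), c.pos1,
                              chrom_sort_key(c.chrom2), c.pos2, c.sv_type))
    return calls


def _typed_record_to_call(rec, svtype, sample_id) -> SvCall:
    if svtype not in ("DEL", "DUP", "INV", "TRA"):
        raise ParseError(f"unknown SVTYPE {svtype!r} in record {rec.id!r}")
    kw = _sv_format_fields(rec)
    pos1 = rec.pos - 1
    if svtype == "TRA":
        chrom2 = rec.info.get("CHR2")
        end = rec.info.get("END2", rec.stop)
        strands = rec.info.get("STRANDS", "+-")
        return canonical_sv(rec.chrom, pos1, strands[0], chrom2, int(end) - 1,
                            strands[1], sample_id=sample_id, sv_id=rec.id, **kw)
    pos2 = rec.stop - 1  # END is 1-based inclusive
    if svtype == "DEL":
        s1, s2 = "+", "-"
    elif svtype == "DUP":
        s1, s2 = "-", "+"
    else:  # INV: breakend orientation from STRANDS
        strands = rec.info.get("STRANDS")
        if strands is None or strands[0] not in "+-":
            raise ParseError(f"INV record {rec.id!r} lacks STRANDS orientation")
        s1 = s2 = strands[0]
    return canonical_sv(rec.chrom, pos1, s1, rec.chrom, pos2, s2,
                        sample_id=sample_id, sv_id=rec.id, **kw)


# ---------------------------------------------------------------------------
# SNV / indel VCF

_SNV_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers reporting this variant">
##INFO=<ID=HQAC,Number=1,Type=Integer,Description="Alt reads with MAPQ>=30 and BQ>=20">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_snv_vcf(calls: list[SnvCall], path: str | Path, sample_id: str = "TUMOR") -> None:
    calls = sorted(calls, key=lambda c: (chrom_sort_key(c.chromosome), c.position,
                                         c.ref, c.alt))
    lines = [_SNV_VCF_HEADER]
    for chrom in sorted({c.chromosome for c in calls}, key=chrom_sort_key):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
    for call in calls:
        info = []
        if call.callers:
            info.append("CALLERS=" + ",".join(sorted(call.callers)))
        if call.hq_alt_count is not None:
            info.append(f"HQAC={call.hq_alt_count}")
        dp = call.depth if call.depth is not None else "."
        if call.depth is not None and call.alt_count is not None:
            ad = f"{call.depth - call.alt_count},{call.alt_count}"
        else:
            ad = "."
        lines.append(
            f"{call.chromosome}\t{call.position + 1}\t.\t{call.ref}\t{call.alt}\t.\t"
            f"PASS\t{';'.join(info) or '.'}\tGT:DP:AD\t./.:{dp}:{ad}\n"
        )
    Path(path).write_text("".join(lines))


def read_snv_vcf(path: str | Path, sample_id: str | None = None) -> list[SnvCall]:
    calls: list[SnvCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            callers = rec.info.get("CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            depth = alt_count = None
            if rec.samples:
                sample = rec.samples[next(iter(rec.samples))]
                depth = sample.get("DP")
                ad = sample.get("AD")
                if isinstance(ad, tuple) and len(ad) >= 2 and ad[-1] is not None:
                    alt_count = ad[-1]
            hqac = rec.info.get("HQAC")
            calls.append(SnvCall(
                chromosome=rec.chrom, position=rec.pos - 1,
                ref=rec.ref, alt=rec.alts[0], depth=depth, alt_count=alt_count,
                callers=frozenset(callers), hq_alt_count=hqac, sample_id=sample_id))
    return calls


# ---------------------------------------------------------------------------
# tab-separated dialects


def write_segments(segments: list[CnSegment], path: str | Path) -> None:
    """CNVkit ``.cns``-style output (1-based inclusive start, like CNVkit)."""
    lines = ["chromosome\tstart\tend\tgene\tlog2\tcn\n"]
    for seg in segments:
        cn = f"{seg.copy_number:.6g}" if seg.copy_number is not None else ""
        lines.append(f"{seg.chromosome}\t{seg.start + 1}\t{seg.end}\t{seg.gene}\t"
                     f"{seg.log2_fold_change:.6g}\t{cn}\n")
    Path(path).write_text("".join(lines))


def read_segments(path: str | Path) -> list[CnSegment]:
    """Read CNVkit ``.cns``-style segments; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "start", "end", "log2"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"segment file {path} missing columns {sorted(missing)}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        start = int(row.start) - 1
        end = int(row.end)
        if start < 0 or end <= start:
            raise ParseError(f"{path}: line {i}: invalid coordinates {row.start}-{row.end}")
        cn = None
        if "cn" in df.columns and pd.notna(getattr(row, "cn", None)) \
                and getattr(row, "cn") != "":
            cn = float(row.cn)
        segments.append(CnSegment(
            chromosome=normalize_chrom(str(row.chromosome)), start=start, end=end,
            log2_fold_change=float(row.log2), copy_number=cn,
            gene=str(getattr(row, "gene", "-"))))
    return segments


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
        try:
            start, end = int(fields[1]), int(fields[2])
            intervals.append(GenomicInterval(normalize_chrom(fields[0]), start, end))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return intervals


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blocks become exons)."""
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"{path}: line {lineno}: expected 12 BED12 columns")
        try:
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != int(fields[9]) or len(starts) != int(fields[9]):
                raise ValueError("blockCount does not match block lists")
            exons = tuple(GenomicInterval(chrom, start + off, start + off + size)
                          for off, size in zip(starts, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    lines = []
    for g in genes:
        sizes = ",".join(str(len(e)) for e in g.exons)
        starts = ",".join(str(e.start - g.start) for e in g.exons)
        lines.append(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                     f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n")
    Path(path).write_text("".join(lines))


def read_impact_table(path: str | Path) -> pd.DataFrame:
    """Variant impact annotations: variant_key, gene, consequence, impact[, deleterious]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_key", "gene", "consequence", "impact"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"impact table {path} missing columns {sorted(missing)}")
    if "deleterious" in df.columns:
        df["deleterious"] = df["deleterious"].map(
            lambda v: str(v).strip().lower() in ("1", "true", "yes"))
    else:
        df["deleterious"] = False
    return df


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Depth summaries: sample, region, mean_depth."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "region": str})
    required = {"sample", "region", "mean_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"depth table {path} missing columns {sorted(missing)}")
    return df


def snv_with_call_metadata(call: SnvCall, **kw) -> SnvCall:
    """Return a copy of ``call`` with fields replaced (convenience)."""
    return replace(call, **kw)
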
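"""Per-gene, per-tumor alteration calling and the cohort alteration matrix.

Rules: amplification at weighted gene CN >= 5; focal deletion at weighted gene
CN <= 0.5 AND at least 0.5 copies below the chromosome average; SV disruption
when an intrachromosomal SV breaks an exon or a translocation breaks anywhere
in the gene body; small variants must be HIGH/MODERATE impact with a listed
consequence (missense additionally requires the deleterious flag).
Amplifications are flagged for CGR co-occurrence on the same chromosome and
for direct footprint overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cgr import CgrCluster
from .genomic_io import CnSegment, GeneModel, SvCall

__all__ = [
    "AlterationCall", "ImpactFilter", "gene_weighted_cn", "call_gene_cn",
    "call_sv_disruption", "call_small_variants", "flag_cgr_cooccurrence",
    "build_alteration_matrix",
]

AMP_MIN_COPIES = 5.0
HOMDEL_MAX_COPIES = 0.5
FOCAL_DELTA_COPIES = 0.5

CATEGORY_PRIORITY = ("amplification", "focal_deletion", "sv_breakpoint", "small_variant")


@dataclass
class AlterationCall:
    gene: str
    sample: str
    category: str
    evidence: str
    cgr_same_chromosome: bool = False
    cgr_direct_overlap: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_PRIORITY:
            raise ValueError(f"unknown alteration category {self.category!r}")


@dataclass(frozen=True)
class ImpactFilter:
    allowed_impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    allowed_consequences: frozenset[str] = frozenset({
        "missense_variant", "stop_gained", "frameshift", "start_lost", "stop_lost"})
    missense_requires_deleterious: bool = True


def gene_weighted_cn(gene: GeneModel, segments: list[CnSegment]) -> float | None:
    """Length-weighted mean copy number over gene body covered by segments.

    None when no segment covers any base of the gene body.
    """
    num = den = 0.0
    for seg in segments:
        if seg.chromosome != gene.chromosome or seg.copy_number is None:
            continue
        ov = max(0, min(gene.end, seg.end) - max(gene.start, seg.start))
        if ov > 0:
            num += ov * seg.copy_number
            den += ov
    return num / den if den > 0 else None


def call_gene_cn(gene: GeneModel, gene_cn: float,
                 chromosome_average: float, sample: str = "") -> AlterationCall | None:
    """Amplification (>=5 copies) or focal deletion (<=0.5 and >=0.5 below the
    chromosome average); None otherwise. Boundaries inclusive."""
    if gene_cn >= AMP_MIN_COPIES:
        return AlterationCall(gene.name, sample, "amplification",
                              evidence=f"cn={gene_cn:.3g}")
    if gene_cn <= HOMDEL_MAX_COPIES and \
            (chromosome_average - gene_cn) >= FOCAL_DELTA_COPIES:
        return AlterationCall(gene.name, sample, "focal_deletion",
                              evidence=f"cn={gene_cn:.3g};chrom_avg={chromosome_average:.3g}")
    return None


def _breakpoint_in_exon(gene: GeneModel, chrom: str, pos: int) -> bool:
    return any(e.contains(chrom, pos) for e in gene.exons)


def call_sv_disruption(gene: GeneModel, svs: list[SvCall],
                       sample: str = "") -> list[AlterationCall]:
    """SV disruption calls: intrachromosomal SVs need a breakpoint in an exon;
    translocations need a breakpoint anywhere in the gene body."""
    calls = []
    for sv in svs:
        if sv.sv_type == "TRA":
            hit = any(gene.body.contains(chrom, pos) for chrom, pos in sv.breakpoints())
        else:
            hit = any(_breakpoint_in_exon(gene, chrom, pos)
                      for chrom, pos in sv.breakpoints())
        if hit:
            calls.append(AlterationCall(gene.name, sample, "sv_breakpoint",
                                        evidence=sv.sv_id or sv.sv_type))
    return calls


def call_small_variants(variant_keys: list[str], impact_table: pd.DataFrame,
                        impact_filter: ImpactFilter = ImpactFilter(),
                        sample: str = "") -> tuple[list[AlterationCall], int]:
    """Impactful small-variant calls for annotated variants.

    ``variant_keys`` are joined against the annotation table on
    ``variant_key``. Returns (calls, number of unannotated variants skipped).
    """
    by_key = impact_table.set_index("variant_key")
    calls: list[AlterationCall] = []
    skipped = 0
    for key in variant_keys:
        if key not in by_key.index:
            skipped += 1
            continue
        rows = by_key.loc[[key]]
        for _, row in rows.iterrows():
            if row["impact"] not in impact_filter.allowed_impacts:
                continue
            if row["consequence"] not in impact_filter.allowed_consequences:
                continue
            if (row["consequence"] == "missense_variant"
                    and impact_filter.missense_requires_deleterious
                    and not bool(row.get("deleterious", False))):
                continue
            calls.append(AlterationCall(row["gene"], sample, "small_variant",
                                        evidence=key))
    return calls, skipped


def flag_cgr_cooccurrence(amplification_calls: list[AlterationCall],
                          clusters: list[CgrCluster],
                          gene_models: dict[str, GeneModel]) -> list[AlterationCall]:
    """Set CGR co-occurrence flags on amplification calls (in place, returned).

    cgr_same_chromosome: any cluster on the gene's chromosome.
    cgr_direct_overlap: gene body intersects a cluster footprint.
    """
    for call in amplification_calls:
        if call.category != "amplification":
            continue
        gene = gene_models[call.gene]
        same = [cl for cl in clusters if cl.chromosome == gene.chromosome]
        call.cgr_same_chromosome = bool(same)
        call.cgr_direct_overlap = any(
            cl.footprint.overlap(gene.body) > 0 for cl in same)
    return amplification_calls


@dataclass
class AlterationMatrix:
    matrix: pd.DataFrame  # genes x mice, highest-priority category or ""
    frequencies: pd.DataFrame  # gene, altered, eligible, frequency
    unknown_genes: list[str] = field(default_factory=list)


def build_alteration_matrix(calls: list[AlterationCall],
                            sample_to_mouse: dict[str, str],
                            gene_panel: list[str],
                            ortholog_map: dict[str, str] | None = None,
                            engineered_exclusions: dict[str, set[str]] | None = None
                            ) -> AlterationMatrix:
    """Genes x mice matrix and per-gene cohort frequencies.

    Multi-region samples of one mouse count once. ``engineered_exclusions``
    maps gene -> set of mouse ids excluded from that gene's denominator
    (e.g. mice in which the gene was engineered).

    ``ortholog_map`` translates call gene names into the panel namespace;
    genes absent from the panel are reported in ``unknown_genes``, not
    silently dropped.
    """
    ortholog_map = ortholog_map or {}
    engineered_exclusions = engineered_exclusions or {}
    mice = sorted(set(sample_to_mouse.values()))
    priority = {cat: i for i, cat in enumerate(CATEGORY_PRIORITY)}

    matrix = pd.DataFrame("", index=list(gene_panel), columns=mice, dtype=object)
    unknown: set[str] = set()
    for call in calls:
        gene = ortholog_map.get(call.gene, call.gene)
        if gene not in matrix.index:
            unknown.add(gene)
            continue
        mouse = sample_to_mouse[call.sample]
        current = matrix.at[gene, mouse]
        if current == "" or priority[call.category] < priority[current]:
            matrix.at[gene, mouse] = call.category

    rows = []
    for gene in gene_panel:
        excluded = engineered_exclusions.get(gene, set())
        eligible = [m for m in mice if m not in excluded]
        altered = sum(1 for m in eligible if matrix.at[gene, m] != "")
        rows.append({"gene": gene, "altered": altered, "eligible": len(eligible),
                     "frequency": altered / len(eligible) if eligible else 0.0})
    freq = pd.DataFrame(rows)
    return AlterationMatrix(matrix=matrix, frequencies=freq,
                            unknown_genes=sorted(unknown))
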
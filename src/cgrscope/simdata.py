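"""Synthetic multi-region tumor cohorts with known ground truth.

One cohort = one mouse: ``n_samples`` tumor regions related by a caterpillar
clone tree, plus a panel of unmatched normal controls. Somatic SNVs/SVs are
planted on tree branches (truncal on the root edge, shared on internal edges,
private on leaf edges), CGRs are planted as connected interleaving chains
with style-specific copy-number signatures, and log2 segment ratios are
distorted by per-sample purity so the absolute-CN inversion has something to
undo.

Noise knobs (breakpoint jitter, call dropout, germline leakage into tumor
calls) default to 0 so oracle tests can run on noise-free cohorts.
A single RNG stream (numpy Generator) is threaded explicitly; the same seed
yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .copynumber import log2fc_from_cn
from .genome import Genome, default_mouse_genome
from .genomic_io import (
    CnSegment, GeneModel, GenomicInterval, SnvCall, SvCall, canonical_sv,
    write_gene_models, write_segments, write_snv_vcf, write_sv_vcf,
)
from .somatic_consensus import PairedAnalysisResult

__all__ = ["SimConfig", "CgrSpec", "SyntheticCohort", "simulate_cohort",
           "plant_cgr", "emit_depth_table"]

_BASES = ("A", "C", "G", "T")
_TYPE_STRANDS = {"DEL": ("+", "-"), "DUP": ("-", "+"),
                 "h2hINV": ("+", "+"), "t2tINV": ("-", "-")}


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class CgrSpec:
    """One planted complex rearrangement.

    ``n_svs`` is the size of the interleaved chain; for multichromosomal
    style each named chromosome receives its own chain of ``n_svs`` SVs and
    the chains are joined by planted translocations.
    """

    chromosomes: tuple[str, ...]
    n_svs: int = 6
    style: str = "chromothripsis"
    amplified_gene: str | None = None
    target_copies: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if self.n_svs < 4:
            raise ConfigError(f"n_svs must be >= 4 for a detectable cluster, got {self.n_svs}")
        if self.style not in ("chromothripsis", "bfb", "multichromosomal"):
            raise ConfigError(f"style must be chromothripsis/bfb/multichromosomal, got {self.style!r}")
        if self.style == "multichromosomal" and len(self.chromosomes) < 2:
            raise ConfigError("multichromosomal style requires >= 2 chromosomes")
        if not self.chromosomes:
            raise ConfigError("chromosomes must be non-empty")
        if self.target_copies <= 0:
            raise ConfigError("target_copies must be positive")


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 4
    n_truncal_snvs: int = 50
    n_shared_snvs: int = 20  # per internal (shared) branch
    n_private_snvs: int = 10  # per sample
    n_background_svs: int = 10
    cgr_specs: tuple[CgrSpec, ...] = ()
    purity_per_sample: float | tuple[float, ...] = 0.7
    ploidy: float = 2.0
    depth_mean: float = 100.0
    seed: int = 0
    n_controls: int = 17
    n_germline_snvs: int = 20
    n_germline_svs: int = 5
    breakpoint_jitter: int = 0
    dropout_rate: float = 0.0
    germline_leakage: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cgr_specs", tuple(self.cgr_specs))
        if self.n_samples < 1:
            raise ConfigError(f"n_samples must be >= 1, got {self.n_samples}")
        for fname in ("n_truncal_snvs", "n_shared_snvs", "n_private_snvs",
                      "n_background_svs", "n_controls", "n_germline_snvs",
                      "n_germline_svs", "breakpoint_jitter"):
            if getattr(self, fname) < 0:
                raise ConfigError(f"{fname} must be >= 0")
        for p in self.purities(self.n_samples):
            if not (0 < p <= 1):
                raise ConfigError(f"purity_per_sample must be in (0, 1], got {p}")
        if self.ploidy <= 0:
            raise ConfigError(f"ploidy must be positive, got {self.ploidy}")
        if self.depth_mean <= 0:
            raise ConfigError(f"depth_mean must be positive, got {self.depth_mean}")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if not (0 <= self.germline_leakage <= 1):
            raise ConfigError("germline_leakage must be in [0, 1]")

    def purities(self, n: int) -> tuple[float, ...]:
        if isinstance(self.purity_per_sample, (int, float)):
            return (float(self.purity_per_sample),) * n
        if len(self.purity_per_sample) != n:
            raise ConfigError("purity_per_sample length must equal n_samples")
        return tuple(float(p) for p in self.purity_per_sample)


@dataclass
class SyntheticCohort:
    config: SimConfig
    genome: Genome
    samples: list[str]
    topology: object  # nested-tuple clone tree (None for 1 sample)
    branch_snvs: dict[frozenset, list[tuple]]  # clade -> SNV keys
    branch_svs: dict[frozenset, list[str]]  # clade -> SV ids
    snv_calls: dict[str, list[SnvCall]]
    site_tables: dict[str, pd.DataFrame]
    sv_calls: dict[str, list[SvCall]]
    segments: dict[str, list[CnSegment]]
    paired_sv_results: dict[str, list[PairedAnalysisResult]]
    control_snv_sets: list[set]
    gene_models: list[GeneModel]
    depth_table: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Emit the cohort as plain-text files (deterministic under seed)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for sample in self.samples:
            write_sv_vcf(self.sv_calls[sample], out / f"{sample}.sv.vcf", sample)
            write_snv_vcf(self.snv_calls[sample], out / f"{sample}.snv.vcf", sample)
            write_segments(self.segments[sample], out / f"{sample}.cns")
            self.site_tables[sample].to_csv(out / f"{sample}.sites.tsv",
                                            sep="\t", index=False)
            manifest_rows.append({
                "sample": sample, "mouse": self.truth.get("mouse_id", "m1"),
                "site": "primary" if sample == self.samples[0] else "metastasis",
                "sv_vcf": f"{sample}.sv.vcf", "snv_vcf": f"{sample}.snv.vcf",
                "segments": f"{sample}.cns", "sites": f"{sample}.sites.tsv",
                "matched_normal": "tumor-only",
            })
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
        self.depth_table.to_csv(out / "depths.tsv", sep="\t", index=False)
        write_gene_models(self.gene_models, out / "genes.bed")
        rows = [{"snv_key": "|".join(map(str, key)),
                 "clonality": label, "samples": ",".join(sorted(clade))}
                for clade, keys in sorted(self.branch_snvs.items(),
                                          key=lambda kv: sorted(kv[0]))
                for key, label in ((k, self._label(clade)) for k in keys)]
        pd.DataFrame(rows).to_csv(out / "truth_snvs.tsv", sep="\t", index=False)
        sv_rows = [{"sv_id": sv_id, "clonality": self._label(clade),
                    "samples": ",".join(sorted(clade))}
                   for clade, ids in sorted(self.branch_svs.items(),
                                            key=lambda kv: sorted(kv[0]))
                   for sv_id in ids]
        pd.DataFrame(sv_rows).to_csv(out / "truth_svs.tsv", sep="\t", index=False)
        pd.DataFrame(self.truth.get("cgr", [])).to_csv(
            out / "truth_cgr.tsv", sep="\t", index=False)
        pd.DataFrame(self.truth.get("genes", [])).to_csv(
            out / "truth_genes.tsv", sep="\t", index=False)

    def _label(self, clade: frozenset) -> str:
        if len(clade) == len(self.samples):
            return "truncal"
        return "private" if len(clade) == 1 else "shared"


# ---------------------------------------------------------------------------
# CGR planting


def _interleaved_chain(chrom: str, lo: int, hi: int, n: int, rng,
                       id_prefix: str) -> list[SvCall]:
    """n intrachromosomal SVs whose [pos1, pos2] intervals form one fully
    connected interleaving component: interval i = [p_i, p_{i+n}] over 2n
    sorted distinct points (all pairs partially overlap, none contained)."""
    while True:  # redraw on the (tiny-probability) collision
        draw = rng.integers(lo, hi, size=2 * n)
        if len(np.unique(draw)) == 2 * n:
            break
    points = np.sort(draw)
    types = [str(rng.choice(["DEL", "DUP", "h2hINV", "t2tINV"])) for _ in range(n)]
    svs = []
    for i in range(n):
        s1, s2 = _TYPE_STRANDS[types[i]]
        svs.append(canonical_sv(chrom, int(points[i]), s1,
                                chrom, int(points[i + n]), s2,
                                sv_id=f"{id_prefix}_{i + 1}"))
    return svs


def plant_cgr(spec: CgrSpec, genome: Genome, rng
              ) -> tuple[list[SvCall], list[CnSegment], dict]:
    """Plant one CGR; returns (SVs, absolute-CN segments, truth record).

    chromothripsis: copy number oscillates between two states across the
    footprint. bfb: the chain contains >= 1 foldback (h2hINV) and the
    chromosome suffers terminal loss beyond the footprint. multichromosomal:
    one chain per named chromosome plus translocations joining consecutive
    footprints. ``amplified_gene`` adds a segment at ``target_copies`` within
    the first footprint.
    """
    for chrom in spec.chromosomes:
        if chrom not in genome:
            raise ConfigError(f"chromosomes: {chrom!r} not in genome")
    svs: list[SvCall] = []
    segments: list[CnSegment] = []
    footprints: dict[str, tuple[int, int]] = {}
    hi_lo = (3.0, 2.0)  # oscillation states

    chroms = spec.chromosomes if spec.style == "multichromosomal" \
        else spec.chromosomes[:1]
    for ci, chrom in enumerate(chroms):
        length = genome.length(chrom)
        span = min(20_000_000, length // 4)
        lo = length // 3
        hi = lo + span
        chain = _interleaved_chain(chrom, lo, hi, spec.n_svs, rng,
                                   id_prefix=f"{spec.style}_{chrom}")
        if spec.style == "bfb" and not any(sv.sv_type == "h2hINV" for sv in chain):
            first = chain[0]
            chain[0] = canonical_sv(first.chrom1, first.pos1, "+",
                                    first.chrom2, first.pos2, "+",
                                    sv_id=first.sv_id)
        svs.extend(chain)
        left = min(sv.pos1 for sv in chain)
        right = max(sv.pos2 for sv in chain)
        footprints[chrom] = (left, right)
        # oscillating copy number across the footprint
        bounds = np.linspace(left, right, spec.n_svs + 1).astype(int)
        for k in range(len(bounds) - 1):
            if bounds[k + 1] > bounds[k]:
                segments.append(CnSegment(chrom, int(bounds[k]), int(bounds[k + 1]),
                                          0.0, copy_number=hi_lo[k % 2]))
        if spec.style == "bfb":
            # terminal loss distal to the footprint
            if right < length:
                segments.append(CnSegment(chrom, right, length, 0.0, copy_number=1.0))

    # translocations joining consecutive chromosomes' footprints
    for a, b in zip(chroms, chroms[1:]):
        (la, ra), (lb, rb) = footprints[a], footprints[b]
        for t in range(3):
            pa = int(rng.integers(la, ra))
            pb = int(rng.integers(lb, rb))
            svs.append(canonical_sv(a, pa, "+", b, pb, "-",
                                    sv_id=f"tra_{a}_{b}_{t + 1}"))

    truth = {"style": spec.style, "chromosomes": list(chroms),
             "footprints": dict(footprints),
             "sv_ids": [sv.sv_id for sv in svs]}
    if spec.amplified_gene:
        chrom = chroms[0]
        left, right = footprints[chrom]
        g_start = left + (right - left) // 3
        g_end = min(g_start + 200_000, right)
        segments.append(CnSegment(chrom, g_start, g_end, 0.0,
                                  copy_number=float(spec.target_copies)))
        truth["amplified_gene"] = spec.amplified_gene
        truth["gene_interval"] = (chrom, g_start, g_end)
        truth["target_copies"] = float(spec.target_copies)
    return svs, segments, truth


# ---------------------------------------------------------------------------
# cohort simulation


def _caterpillar(samples: list[str]):
    if len(samples) == 1:
        return samples[0]
    tree = (samples[0], samples[1])
    for s in samples[2:]:
        tree = (tree, s)
    return tree


def _branch_clades(samples: list[str]) -> list[frozenset]:
    """Root edge first, then internal (shared) edges, then leaves."""
    n = len(samples)
    clades = [frozenset(samples)]
    for k in range(2, n):
        clades.append(frozenset(samples[:k]))
    clades.extend(frozenset([s]) for s in samples)
    return clades


def _random_snv(genome: Genome, rng, used: set) -> tuple:
    while True:
        chrom = str(rng.choice(genome.chromosomes))
        pos = int(rng.integers(0, genome.length(chrom)))
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        key = (chrom, pos, _BASES[ref], _BASES[alt])
        if key not in used:
            used.add(key)
            return key


def _flat_segments(genome: Genome, overrides: list[CnSegment],
                   base_cn: float = 2.0) -> list[CnSegment]:
    """Non-overlapping whole-genome segmentation: baseline plus overrides.

    Later overrides win where they overlap earlier ones.
    """
    out: list[CnSegment] = []
    by_chrom: dict[str, list[CnSegment]] = {}
    for seg in overrides:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom in genome.chromosomes:
        length = genome.length(chrom)
        boundaries = {0, length}
        for seg in by_chrom.get(chrom, ()):
            boundaries.update((seg.start, seg.end))
        cuts = sorted(boundaries)
        for s, e in zip(cuts, cuts[1:]):
            cn = base_cn
            for seg in by_chrom.get(chrom, ()):  # last override wins
                if seg.start <= s and e <= seg.end:
                    cn = seg.copy_number
            out.append(CnSegment(chrom, s, e, 0.0, copy_number=cn))
    return out


def simulate_cohort(config: SimConfig, genome: Genome | None = None) -> SyntheticCohort:
    """Generate a deterministic synthetic multi-region cohort."""
    genome = genome or default_mouse_genome()
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    purities = dict(zip(samples, config.purities(config.n_samples)))
    topology = _caterpillar(samples) if config.n_samples > 1 else None

    # --- branch structure
    clades = _branch_clades(samples)
    root = frozenset(samples)
    internal = [c for c in clades if 1 < len(c) < len(samples)]
    leaves = [frozenset([s]) for s in samples]

    # --- SNVs
    used: set = set()
    branch_snvs: dict[frozenset, list[tuple]] = {c: [] for c in clades}
    for _ in range(config.n_truncal_snvs):
        branch_snvs[root].append(_random_snv(genome, rng, used))
    for clade in internal:
        for _ in range(config.n_shared_snvs):
            branch_snvs[clade].append(_random_snv(genome, rng, used))
    for leaf in leaves:
        for _ in range(config.n_private_snvs):
            branch_snvs[leaf].append(_random_snv(genome, rng, used))
    germline_snvs = [_random_snv(genome, rng, used)
                     for _ in range(config.n_germline_snvs)]

    # --- CGRs (truncal)
    cgr_svs: list[SvCall] = []
    cgr_segments: list[CnSegment] = []
    cgr_truth: list[dict] = []
    gene_truth: list[dict] = []
    gene_models: list[GeneModel] = []
    cgr_chroms: set[str] = set()
    for spec in config.cgr_specs:
        svs, segs, truth = plant_cgr(spec, genome, rng)
        cgr_svs.extend(svs)
        cgr_segments.extend(segs)
        cgr_truth.append({"style": truth["style"],
                          "chromosomes": ",".join(truth["chromosomes"]),
                          "sv_ids": ",".join(truth["sv_ids"]),
                          "footprints": ";".join(
                              f"{c}:{s}-{e}" for c, (s, e)
                              in sorted(truth["footprints"].items()))})
        cgr_chroms.update(truth["chromosomes"])
        if spec.amplified_gene:
            chrom, g_start, g_end = truth["gene_interval"]
            mid = (g_start + g_end) // 2
            exons = (GenomicInterval(chrom, g_start, min(g_start + 2000, mid)),
                     GenomicInterval(chrom, mid, min(mid + 2000, g_end)))
            gene_models.append(GeneModel(spec.amplified_gene, chrom, "+",
                                         g_start, g_end, exons))
            gene_truth.append({"gene": spec.amplified_gene, "chromosome": chrom,
                               "category": "amplification",
                               "copies": truth["target_copies"]})

    # --- background SVs (disjoint slots, never interleaving, off CGR chromosomes)
    branch_svs: dict[frozenset, list[str]] = {c: [] for c in clades}
    for sv in cgr_svs:
        branch_svs[root].append(sv.sv_id)
    bg_chroms = [c for c in genome.chromosomes if c not in cgr_chroms] \
        or genome.chromosomes
    bg_cycle = [root] + leaves
    background: list[tuple[frozenset, SvCall]] = []
    cursor = {c: 1_000_000 for c in bg_chroms}
    for i in range(config.n_background_svs):
        chrom = bg_chroms[i % len(bg_chroms)]
        size = int(rng.integers(10_000, 100_000))
        start = cursor[chrom]
        cursor[chrom] = start + size + 50_000
        if cursor[chrom] >= genome.length(chrom):
            continue
        sv_type = str(rng.choice(["DEL", "DUP", "h2hINV", "t2tINV"]))
        s1, s2 = _TYPE_STRANDS[sv_type]
        clade = bg_cycle[i % len(bg_cycle)]
        sv = canonical_sv(chrom, start, s1, chrom, start + size, s2,
                          sv_id=f"bg_{i + 1}")
        background.append((clade, sv))
        branch_svs[clade].append(sv.sv_id)

    # germline SVs: disjoint slots on the last background chromosome
    germline_svs = []
    g_chrom = bg_chroms[-1]
    g_cursor = genome.length(g_chrom) // 2
    for i in range(config.n_germline_svs):
        size = int(rng.integers(10_000, 50_000))
        germline_svs.append(canonical_sv(g_chrom, g_cursor, "+",
                                         g_chrom, g_cursor + size, "-",
                                         sv_id=f"germ_{i + 1}"))
        g_cursor += size + 60_000

    # --- per-sample call sets
    snv_calls: dict[str, list[SnvCall]] = {}
    site_tables: dict[str, pd.DataFrame] = {}
    sv_calls: dict[str, list[SvCall]] = {}
    segments: dict[str, list[CnSegment]] = {}
    paired: dict[str, list[PairedAnalysisResult]] = {}
    depth = config.depth_mean
    all_sites = [key for c in clades for key in branch_snvs[c]]
    site_clade = {key: c for c in clades for key in branch_snvs[c]}

    for sample in samples:
        purity = purities[sample]
        vaf = 0.5 * purity
        alt = int(round(depth * vaf))
        calls, rows = [], []
        for key in all_sites:
            present = sample in site_clade[key]
            if present and config.dropout_rate > 0 \
                    and rng.random() < config.dropout_rate:
                present = False
            chrom, pos, ref, alt_base = key
            rows.append({"chromosome": chrom, "position": pos, "ref": ref,
                         "alt": alt_base, "depth": int(depth),
                         "hq_alt_count": alt if present else 0,
                         "detected": present})
            if present:
                calls.append(SnvCall(chrom, pos, ref, alt_base,
                                     depth=int(depth), alt_count=alt,
                                     callers=frozenset({"callerA", "callerB"}),
                                     hq_alt_count=alt, sample_id=sample))
        if config.germline_leakage > 0:
            for key in germline_snvs:
                if rng.random() < config.germline_leakage:
                    chrom, pos, ref, alt_base = key
                    calls.append(SnvCall(chrom, pos, ref, alt_base,
                                         depth=int(depth),
                                         alt_count=int(round(depth * 0.5)),
                                         callers=frozenset({"callerA", "callerB"}),
                                         hq_alt_count=int(round(depth * 0.5)),
                                         sample_id=sample))
        snv_calls[sample] = calls
        site_tables[sample] = pd.DataFrame(
            rows, columns=["chromosome", "position", "ref", "alt",
                           "depth", "hq_alt_count", "detected"])

        sample_svs = []
        for sv in cgr_svs:
            sample_svs.append(_with_af(sv, vaf, depth, sample, rng,
                                       config.breakpoint_jitter))
        for clade, sv in background:
            if sample in clade:
                sample_svs.append(_with_af(sv, vaf, depth, sample, rng,
                                           config.breakpoint_jitter))
        sv_calls[sample] = sample_svs

        # paired tumor-vs-control analyses for the panel-of-normals route
        results = []
        for c in range(config.n_controls):
            somatic = list(sample_svs)
            germ = list(germline_svs)
            # control 0 always recognizes germline variants; later controls may
            # mislabel them as somatic with probability germline_leakage
            if config.germline_leakage > 0 and c > 0:
                leaked = [g for g in germline_svs
                          if rng.random() < config.germline_leakage]
                somatic = somatic + leaked
                germ = [g for g in germline_svs if g not in leaked]
            results.append(PairedAnalysisResult(
                control_id=f"N{c + 1}", somatic=somatic, germline=germ))
        paired[sample] = results

        # segments: truth CN -> log2 distorted by purity
        abs_segments = _flat_segments(genome, cgr_segments, base_cn=config.ploidy)
        sample_segs = []
        for seg in abs_segments:
            log2fc = log2fc_from_cn(seg.copy_number, purity, config.ploidy)
            sample_segs.append(CnSegment(seg.chromosome, seg.start, seg.end,
                                         float(log2fc)))
        segments[sample] = sample_segs

    control_snv_sets = [set(germline_snvs) for _ in range(config.n_controls)]

    cohort = SyntheticCohort(
        config=config, genome=genome, samples=samples, topology=topology,
        branch_snvs=branch_snvs, branch_svs=branch_svs, snv_calls=snv_calls,
        site_tables=site_tables, sv_calls=sv_calls, segments=segments,
        paired_sv_results=paired, control_snv_sets=control_snv_sets,
        gene_models=gene_models, depth_table=pd.DataFrame(),
        truth={"purity": purities, "cgr": cgr_truth, "genes": gene_truth,
               "mouse_id": f"m{config.seed}"})
    cohort.depth_table = emit_depth_table(cohort, rng=rng)
    return cohort


def _with_af(sv: SvCall, vaf: float, depth: float, sample: str, rng,
             jitter: int) -> SvCall:
    pos1, pos2 = sv.pos1, sv.pos2
    if jitter > 0:
        pos1 = max(0, pos1 + int(rng.integers(-jitter, jitter + 1)))
        pos2 = max(pos1 + 1 if sv.chrom1 == sv.chrom2 else 0,
                   pos2 + int(rng.integers(-jitter, jitter + 1)))
    return canonical_sv(sv.chrom1, pos1, sv.strand1, sv.chrom2, pos2, sv.strand2,
                        vaf=vaf, alt_reads=int(round(depth * vaf)),
                        depth=int(depth), sample_id=sample, sv_id=sv.sv_id)


def emit_depth_table(cohort: SyntheticCohort, n_positions: int = 200,
                     rng=None) -> pd.DataFrame:
    """Depth summary for purity estimation.

    The edit region is biallelically deleted in tumor cells, so its expected
    depth is depth_mean * (1 - purity); the flank keeps depth_mean. Each
    region mean is the average of ``n_positions`` iid Poisson draws.
    """
    rng = rng if rng is not None else np.random.default_rng(cohort.config.seed + 1)
    depth = cohort.config.depth_mean
    rows = []
    for sample in cohort.samples:
        purity = cohort.truth["purity"][sample]
        lam_edit = depth * (1.0 - purity)
        edit = float(rng.poisson(lam_edit, size=n_positions).mean()) \
            if lam_edit > 0 else 0.0
        flank = float(rng.poisson(depth, size=n_positions).mean())
        rows.append({"sample": sample, "region": "edit",
                     "mean_depth": edit, "n_positions": n_positions})
        rows.append({"sample": sample, "region": "flank",
                     "mean_depth": flank, "n_positions": n_positions})
    return pd.DataFrame(rows)
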
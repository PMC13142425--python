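"""End-to-end orchestration over a cohort manifest.

The manifest is tab-separated with columns: sample, mouse, site
(primary/metastasis), sv_vcf, snv_vcf, segments, sites, matched_normal.
File paths are resolved relative to the manifest location. Stages run as
pure functions of their inputs plus the config, so a rerun with identical
inputs is bit-identical; every run writes a run-metadata JSON (package
version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cgr import breakpoint_fraction_in_cgr, detect_clusters, link_multichromosomal
from .cohort_stats import sv_burden
from .copynumber import annotate_absolute_cn, bin_copy_number, cosine_similarity, filter_blacklist
from .genome import Genome, default_mouse_genome
from .genomic_io import read_bed, read_depth_table, read_segments, read_sv_vcf
from .phylogeny import (assign_branch_lengths, build_presence_matrix,
                        classify_clonality, search_parsimony_tree)
from .purity import estimate_purity_from_table

__all__ = ["CohortManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, sample: str | None, message: str):
        self.stage, self.sample = stage, sample
        super().__init__(f"[{stage}{':' + sample if sample else ''}] {message}")


@dataclass
class CohortManifest:
    entries: pd.DataFrame
    base_dir: Path

    REQUIRED = ("sample", "mouse", "site", "sv_vcf", "snv_vcf", "segments",
                "sites", "matched_normal")

    @classmethod
    def read(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(cls.REQUIRED) - set(df.columns)
        if missing:
            raise PipelineError("manifest", None,
                                f"missing columns {sorted(missing)}")
        manifest = cls(entries=df, base_dir=path.parent)
        manifest.validate()
        return manifest

    def validate(self) -> None:
        if self.entries["sample"].duplicated().any():
            raise PipelineError("manifest", None, "duplicate sample ids")
        for _, row in self.entries.iterrows():
            for col in ("sv_vcf", "snv_vcf", "segments", "sites"):
                p = self.base_dir / row[col]
                if not p.exists():
                    raise PipelineError("manifest", row["sample"],
                                        f"missing file {p}")
        for mouse, group in self.entries.groupby("mouse"):
            if (group["site"] == "primary").sum() != 1:
                raise PipelineError(
                    "manifest", None,
                    f"mouse {mouse} must have exactly one primary sample")

    def path(self, sample_row, col: str) -> Path:
        return self.base_dir / sample_row[col]


@dataclass
class PipelineResult:
    outdir: Path
    purity: pd.DataFrame
    burden: pd.DataFrame
    clusters: pd.DataFrame
    phylogenies: dict[str, str] = field(default_factory=dict)  # mouse -> newick


def run_pipeline(manifest: CohortManifest | str | Path, outdir: str | Path,
                 seed: int = 0, depth_table: str | Path | None = None,
                 blacklist: str | Path | None = None,
                 default_purity: float = 1.0, ploidy: float = 2.0,
                 genome: Genome | None = None) -> PipelineResult:
    """Run purity -> copy number -> CGR -> burden -> per-mouse phylogeny."""
    if not isinstance(manifest, CohortManifest):
        manifest = CohortManifest.read(manifest)
    genome = genome or default_mouse_genome()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = {"seed": seed, "default_purity": default_purity, "ploidy": ploidy}

    # --- purity
    purity_by_sample: dict[str, float] = {}
    purity_rows = []
    if depth_table is not None:
        estimates = estimate_purity_from_table(read_depth_table(depth_table))
        for est in estimates:
            purity_by_sample[est.sample_id] = est.purity
            purity_rows.append({"sample": est.sample_id, "purity": est.purity,
                                "depth_edit": est.depth_edit,
                                "depth_flank": est.depth_flank,
                                "qc_flag": est.qc_flag})
    purity_df = pd.DataFrame(purity_rows,
                             columns=["sample", "purity", "depth_edit",
                                      "depth_flank", "qc_flag"])

    blacklist_ivs = read_bed(blacklist) if blacklist else []

    burden_rows, cluster_rows = [], []
    profiles = {}
    for _, row in manifest.entries.iterrows():
        sample = row["sample"]
        try:
            svs = read_sv_vcf(manifest.path(row, "sv_vcf"), sample_id=sample)
            segments = read_segments(manifest.path(row, "segments"))
        except Exception as exc:  # halt with stage + sample context
            raise PipelineError("load", sample, str(exc)) from exc
        purity = purity_by_sample.get(sample, default_purity)
        segments = filter_blacklist(segments, blacklist_ivs) if blacklist_ivs \
            else segments
        segments = annotate_absolute_cn(segments, purity, ploidy)
        try:
            profiles[sample] = bin_copy_number(segments, genome, sample_id=sample)
        except ValueError as exc:
            raise PipelineError("copynumber", sample, str(exc)) from exc
        clusters = detect_clusters(svs)
        translocations = [sv for sv in svs if sv.sv_type == "TRA"]
        multi = link_multichromosomal(clusters, translocations)
        linked = {cl.cluster_id for m in multi for cl in m.clusters}
        for cl in clusters:
            cluster_rows.append({
                "sample": sample, "cluster_id": cl.cluster_id,
                "chromosome": cl.chromosome, "start": cl.footprint.start,
                "end": cl.footprint.end, "n_svs": cl.size,
                "multichromosomal": cl.cluster_id in linked})
        frac = breakpoint_fraction_in_cgr(svs, clusters)
        burden_rows.append({
            "sample": sample, "mouse": row["mouse"], "site": row["site"],
            "sv_breakpoints": sv_burden(svs, genome),
            "n_cgr_clusters": len(clusters),
            "fraction_in_cgr": frac if frac is not None else float("nan")})

    burden_df = pd.DataFrame(burden_rows)
    clusters_df = pd.DataFrame(
        cluster_rows, columns=["sample", "cluster_id", "chromosome", "start",
                               "end", "n_svs", "multichromosomal"])

    # --- pairwise copy-number similarity within each mouse
    cosine_rows = []
    for mouse, group in manifest.entries.groupby("mouse"):
        ids = list(group["sample"])
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                cosine_rows.append({"mouse": mouse, "sample_a": a, "sample_b": b,
                                    "cosine": cosine_similarity(profiles[a],
                                                                profiles[b])})
    cosine_df = pd.DataFrame(cosine_rows,
                             columns=["mouse", "sample_a", "sample_b", "cosine"])

    # --- phylogeny per multi-region mouse
    phylogenies: dict[str, str] = {}
    clonality_rows = []
    for mouse, group in manifest.entries.groupby("mouse"):
        if len(group) < 2:
            continue
        tables = {}
        for _, row in group.iterrows():
            tables[row["sample"]] = pd.read_csv(manifest.path(row, "sites"),
                                                sep="\t")
        try:
            matrix = build_presence_matrix(tables)
            labels = classify_clonality(matrix)
            topology = search_parsimony_tree(matrix, seed=seed)
            tree = assign_branch_lengths(topology, matrix)
        except Exception as exc:
            raise PipelineError("phylogeny", str(mouse), str(exc)) from exc
        phylogenies[str(mouse)] = tree.newick()
        for label in ("truncal", "shared", "private"):
            clonality_rows.append({"mouse": mouse, "clonality": label,
                                   "n_snvs": labels.count(label)})

    # --- write bundle
    purity_df.to_csv(outdir / "purity.tsv", sep="\t", index=False)
    burden_df.to_csv(outdir / "burden.tsv", sep="\t", index=False)
    clusters_df.to_csv(outdir / "cgr_clusters.tsv", sep="\t", index=False)
    cosine_df.to_csv(outdir / "cn_cosine.tsv", sep="\t", index=False)
    pd.DataFrame(clonality_rows,
                 columns=["mouse", "clonality", "n_snvs"]).to_csv(
        outdir / "clonality.tsv", sep="\t", index=False)
    (outdir / "trees.nwk").write_text(
        "".join(f"{m}\t{nwk}\n" for m, nwk in sorted(phylogenies.items())))
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()
    (outdir / "run_metadata.json").write_text(json.dumps(
        {"package": "cgrscope", "version": __version__, "seed": seed,
         "config": config, "config_sha256": config_hash}, indent=2,
        sort_keys=True) + "\n")
    return PipelineResult(outdir=outdir, purity=purity_df, burden=burden_df,
                          clusters=clusters_df, phylogenies=phylogenies)
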
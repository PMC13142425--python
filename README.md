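# cgrscope

Analysis toolkit for somatic call sets from high-depth, multi-region tumor
whole-genome sequencing, centered on complex genomic rearrangements (CGRs) and
clonal evolution. It covers:

- **purity** — tumor purity from coverage depth at an engineered
  biallelic-deletion locus relative to a flanking region
  (`purity = 1 - depth_edit / depth_flank`).
- **copynumber** — ENCODE-style blacklist filtering (segments with >= 20%
  overlap removed), absolute copy number from relative log2 ratios
  (`CN = (ploidy * 2**log2fc - 2*(1-purity)) / purity`), state classification
  (gain >= 2.5, loss <= 1.5, amplification >= 5, homozygous loss <= 0.5
  copies), 1 Mb binning, cohort recurrence and pairwise cosine similarity.
- **somatic_consensus** — two-caller SNV/indel intersections for matched
  cases; panel-of-normals consensus for tumor-only cases (SV identity = same
  type + both breakpoints within < 10 bp; keep only calls somatic in *all*
  paired analyses and germline in *none*; tumor-only SNVs need VAF > 0.1 and
  absence from every control).
- **cgr** — CGR detection as connected components of the interleaving graph
  (partial overlap without containment) with >= 4 SVs; multi-chromosomal
  linking by direct translocations or translocation enrichment (one-sided
  Fisher, Benjamini-Hochberg, q < 0.01); breakpoint-in-CGR fraction.
- **gene_alterations** — per-gene amplification / focal-deletion / SV
  disruption / impactful-small-variant calls, CGR co-occurrence flags, and the
  cohort alteration matrix with per-gene frequencies (one sample per mouse,
  engineered cases excluded from their own denominators).
- **phylogeny** — presence/absence matrices (depth >= 40 in all samples,
  >= 3 high-quality alt reads rescue), truncal/shared/private clonality,
  maximum parsimony (exhaustive to 8 samples, seeded parsimony ratchet above),
  mutation-count branch lengths, UPGMA trees from SV profiles, bootstrap
  support.
- **cohort_stats** — SV breakpoint burden (autosomes + X), TMB, Welch's t,
  Pearson chi-square (no continuity correction), Fisher's exact test,
  Benjamini-Hochberg FDR, cross-cohort gene enrichment with a >= 10-case
  filter.
- **simdata** — synthetic multi-region cohorts with known ground truth:
  caterpillar clone trees, planted chromothripsis / BFB / multi-chromosomal
  CGRs with oscillating copy number, foldback inversions and oncogene
  amplification, purity-distorted log2 ratios, panel-of-normals germline
  variants, and machine-readable truth tables.
- **pipeline** / CLI — end-to-end orchestration over a cohort manifest with
  deterministic, hash-stable outputs and run metadata.

All coordinates are 0-based, half-open internally; conversion happens only at
format boundaries (VCF 4.2 breakends and typed SVs, CNVkit `.cns`-style
segments, BED3/BED12, tab-separated impact/depth tables).

## CLI

```sh
cgrscope simdata generate --seed 7 --outdir sim/      # synthetic cohort
cgrscope purity estimate --depth-table sim/depths.tsv
cgrscope cn absolute --segments sim/S1.cns --purity 0.7 --out abs.cns
cgrscope cgr detect --sv-vcf sim/S1.sv.vcf
cgrscope phylo tree sim/S1.sites.tsv sim/S2.sites.tsv sim/S3.sites.tsv
cgrscope stats compare --test chisq --a 12,10,11,35
cgrscope run --manifest sim/manifest.tsv --outdir out/ --seed 17 \
    --depth-table sim/depths.tsv
```

`cgrscope run` executes purity -> copy number -> CGR detection/linking ->
burden -> per-mouse phylogeny and writes a tab-separated report bundle plus
`run_metadata.json`; reruns on identical inputs are bit-identical.

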
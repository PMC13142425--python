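"""Copy-number analysis: blacklist filtering, absolute copy number, state
classification, 1-Mb binning, cohort recurrence and profile similarity.

Absolute copy number from a relative log2 ratio:

    CN = (ploidy * 2**log2fc - 2 * (1 - purity)) / purity

and the algebraic inverse used by the simulator and the round-trip property:

    log2fc = log2((CN * purity + 2 * (1 - purity)) / ploidy)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .genome import Genome
from .genomic_io import CnSegment, GenomicInterval

__all__ = [
    "CnThresholds", "BinnedProfile", "filter_blacklist", "absolute_cn",
    "log2fc_from_cn", "classify_cn_state", "bin_copy_number",
    "recurrence_profile", "cosine_similarity", "chromosome_average_cn",
]

CN_STATES = ("homozygous_loss", "loss", "neutral", "gain", "amplification")


@dataclass(frozen=True)
class CnThresholds:
    """Copy-number state thresholds (boundaries inclusive)."""

    gain_min: float = 2.5
    loss_max: float = 1.5
    amp_min: float = 5.0
    homdel_max: float = 0.5

    def __post_init__(self) -> None:
        if not (self.homdel_max < self.loss_max < self.gain_min < self.amp_min):
            raise ValueError("thresholds must satisfy homdel < loss < gain < amp")


def _merged(intervals: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chromosome, []).append((iv.start, iv.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def _overlap_with_union(chrom: str, start: int, end: int,
                        merged: dict[str, list[tuple[int, int]]]) -> int:
    total = 0
    for s, e in merged.get(chrom, ()):
        total += max(0, min(end, e) - max(start, s))
    return total


def filter_blacklist(segments: list[CnSegment],
                     blacklist: list[GenomicInterval],
                     max_overlap_fraction: float = 0.20) -> list[CnSegment]:
    """Drop segments overlapping the blacklist union by >= 20% of their length."""
    merged = _merged(blacklist)
    kept = []
    for seg in segments:
        overlap = _overlap_with_union(seg.chromosome, seg.start, seg.end, merged)
        if overlap / len(seg) < max_overlap_fraction:
            kept.append(seg)
    return kept


def absolute_cn(log2_fold_change, tumor_purity: float, tumor_ploidy: float = 2.0):
    """Absolute copy number from a relative log2 ratio (scalar or array).

    Negative results clamp to 0 with a warning.
    """
    if not (0 < tumor_purity <= 1):
        raise ValueError(f"tumor_purity must be in (0, 1], got {tumor_purity}")
    if tumor_ploidy <= 0:
        raise ValueError("tumor_ploidy must be positive")
    log2fc = np.asarray(log2_fold_change, dtype=float)
    cn = (tumor_ploidy * np.exp2(log2fc) - 2.0 * (1.0 - tumor_purity)) / tumor_purity
    if np.any(cn < 0):
        warnings.warn("negative copy number clamped to 0", stacklevel=2)
        cn = np.maximum(cn, 0.0)
    return float(cn) if np.ndim(log2_fold_change) == 0 else cn


def log2fc_from_cn(copy_number, tumor_purity: float, tumor_ploidy: float = 2.0):
    """Inverse of :func:`absolute_cn` (used by the simulator)."""
    if not (0 < tumor_purity <= 1):
        raise ValueError(f"tumor_purity must be in (0, 1], got {tumor_purity}")
    cn = np.asarray(copy_number, dtype=float)
    ratio = (cn * tumor_purity + 2.0 * (1.0 - tumor_purity)) / tumor_ploidy
    out = np.log2(ratio)
    return float(out) if np.ndim(copy_number) == 0 else out


def annotate_absolute_cn(segments: list[CnSegment], tumor_purity: float,
                         tumor_ploidy: float = 2.0) -> list[CnSegment]:
    """Return segments with ``copy_number`` filled in from their log2 ratios."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seg in segments:
            cn = absolute_cn(seg.log2_fold_change, tumor_purity, tumor_ploidy)
            out.append(replace(seg, copy_number=max(cn, 0.0)))
    return out


def classify_cn_state(copy_number: float, thresholds: CnThresholds = CnThresholds()) -> str:
    """Total partition of [0, inf): homdel <= 0.5 < loss <= 1.5 < neutral
    < 2.5 <= gain < 5 <= amplification. Extreme states take precedence."""
    if copy_number < 0:
        raise ValueError("copy_number must be >= 0")
    t = thresholds
    if copy_number <= t.homdel_max:
        return "homozygous_loss"
    if copy_number <= t.loss_max:
        return "loss"
    if copy_number >= t.amp_min:
        return "amplification"
    if copy_number >= t.gain_min:
        return "gain"
    return "neutral"


@dataclass
class BinnedProfile:
    """Length-weighted mean copy number on a fixed genome-wide bin grid."""

    bin_size: int
    chromosomes: list[str]
    bins: list[tuple[str, int, int]]  # (chrom, start, end), tiling each chromosome
    values: np.ndarray  # NaN where no segment covers the bin
    sample_id: str | None = None

    def compatible_with(self, other: "BinnedProfile") -> bool:
        return self.bin_size == other.bin_size and self.bins == other.bins

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


def bin_copy_number(segments: list[CnSegment], genome: Genome,
                    bin_size: int = 1_000_000,
                    sample_id: str | None = None) -> BinnedProfile:
    """Bin absolute copy number into fixed windows (1 Mb default).

    Bin value = sum(overlap * CN) / sum(overlap) over covering segments;
    uncovered bins are NaN (missing, not zero). Overlapping segments on a
    chromosome are a validation error.
    """
    by_chrom: dict[str, list[CnSegment]] = {}
    for seg in segments:
        if seg.copy_number is None:
            raise ValueError("segments must carry absolute copy_number; "
                             "run annotate_absolute_cn first")
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}")

    bins: list[tuple[str, int, int]] = []
    values: list[float] = []
    for chrom in genome.chromosomes:
        length = genome.length(chrom)
        segs = by_chrom.get(chrom, [])
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            bins.append((chrom, start, end))
            num = den = 0.0
            for seg in segs:
                ov = max(0, min(end, seg.end) - max(start, seg.start))
                if ov > 0:
                    num += ov * seg.copy_number
                    den += ov
            values.append(num / den if den > 0 else np.nan)
    return BinnedProfile(bin_size=bin_size, chromosomes=genome.chromosomes,
                         bins=bins, values=np.array(values), sample_id=sample_id)


def recurrence_profile(profiles: list[BinnedProfile],
                       thresholds: CnThresholds = CnThresholds()
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (gain count, loss count) across tumors.

    Callers are responsible for passing one profile per mouse (one primary
    sample for multi-region cases). Gains count bins >= gain_min; losses
    count bins <= loss_max; missing bins count as neither.
    """
    if not profiles:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    first = profiles[0]
    for p in profiles[1:]:
        if not first.compatible_with(p):
            raise ValueError("profiles must share the same bin grid")
    stack = np.vstack([p.values for p in profiles])
    present = ~np.isnan(stack)
    with np.errstate(invalid="ignore"):
        gains = np.sum(present & (stack >= thresholds.gain_min), axis=0).astype(int)
        losses = np.sum(present & (stack <= thresholds.loss_max), axis=0).astype(int)
    return gains, losses


def cosine_similarity(profile_a: BinnedProfile, profile_b: BinnedProfile) -> float:
    """Cosine of the two bin vectors over bins non-missing in both."""
    if not profile_a.compatible_with(profile_b):
        raise ValueError("profiles must share the same bin grid")
    mask = ~(profile_a.missing | profile_b.missing)
    if not mask.any():
        raise ValueError("no shared non-missing bins")
    a = profile_a.values[mask]
    b = profile_b.values[mask]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero profile")
    return float(np.dot(a, b) / (na * nb))


def chromosome_average_cn(segments: list[CnSegment], chromosome: str) -> float | None:
    """Length-weighted mean copy number over a chromosome's segments."""
    num = den = 0.0
    for seg in segments:
        if seg.chromosome == chromosome and seg.copy_number is not None:
            num += len(seg) * seg.copy_number
            den += len(seg)
    return num / den if den > 0 else None
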
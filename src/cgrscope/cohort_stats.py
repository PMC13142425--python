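"""Burden metrics and cohort statistics.

The 2x2 chi-square is Pearson's without continuity correction (df=1); the
two-sided Fisher exact test uses the minimum-likelihood convention. BH is the
standard step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import Genome, default_mouse_genome
from .genomic_io import GenomicInterval, SvCall

__all__ = [
    "BurdenRecord", "sv_burden", "tmb", "coding_territory_mb", "percent_of",
    "welch_t", "chisq_2x2", "fisher_2x2", "bh_adjust",
    "cross_cohort_enrichment",
]


@dataclass(frozen=True)
class BurdenRecord:
    sample_id: str
    sv_breakpoint_count: int
    tmb: float | None = None
    fraction_in_cgr: float | None = None


def sv_burden(svs: list[SvCall], genome: Genome | None = None) -> int:
    """Number of SV breakpoints on autosomes + X (2 per SV, each end counted
    independently; Y breakpoints excluded)."""
    genome = genome or default_mouse_genome()
    allowed = set(genome.autosomes_and_x())
    return sum(1 for sv in svs for chrom, _ in sv.breakpoints() if chrom in allowed)


def percent_of(count: int, total: int) -> int:
    """Integer percentage, rounding halves away from zero (62.5 -> 63)."""
    if total <= 0:
        raise ValueError("total must be positive")
    import math
    return int(math.floor(100 * count / total + 0.5))


def coding_territory_mb(exons: list[GenomicInterval]) -> float:
    """Merged exon length in Mb (union per chromosome)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in exons:
        by_chrom.setdefault(iv.chromosome, []).append((iv.start, iv.end))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total / 1e6


def tmb(n_nonsynonymous_coding_snvs: int, coding_territory: float) -> float:
    """Non-synonymous coding SNVs per Mb of coding territory."""
    if coding_territory <= 0:
        raise ValueError("coding territory must be positive")
    if n_nonsynonymous_coding_snvs < 0:
        raise ValueError("SNV count must be >= 0")
    return n_nonsynonymous_coding_snvs / coding_territory


def welch_t(sample_a, sample_b) -> tuple[float, float]:
    """Welch's unequal-variance t test (two-sided), Satterthwaite df.

    Degenerate inputs (both samples zero-variance) return t=0, p=1 when the
    means are equal, else t=+/-inf, p=0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on [[a, b], [c, d]] without continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), p from chi2 df=1.
    """
    for count in (a, b, c, d):
        if count < 0:
            raise ValueError("counts must be >= 0")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined with a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def _log_choose(n, k):
    from scipy.special import gammaln
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_2x2(a: int, b: int, c: int, d: int,
               sided: str = "two-sided") -> float:
    """Fisher exact p on [[a, b], [c, d]].

    two-sided: minimum-likelihood method (sum of tables with point
    probability <= observed, with a 1e-9 relative tie tolerance).
    'greater'/'less' are one-sided in ``a``. Computed over the hypergeometric
    support directly (vectorized log-binomials), which is much faster than
    per-call scipy.stats.fisher_exact and agrees with it to float precision.
    """
    for count in (a, b, c, d):
        if count < 0:
            raise ValueError("counts must be >= 0")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = (_log_choose(r1, support) + _log_choose(r2, c1 - support)
              - _log_choose(n, c1))
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    obs = pmf[a - lo]
    if sided == "two-sided":
        p = pmf[pmf <= obs * (1 + 1e-9)].sum()
    elif sided == "greater":
        p = pmf[support >= a].sum()
    elif sided == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError(f"unknown alternative {sided!r}")
    return float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cross_cohort_enrichment(matrix_a, matrix_b, min_cases: int = 10,
                            min_cases_cohort: str = "b"):
    """Per-gene enrichment between two boolean gene x sample matrices.

    Parameters
    ----------
    matrix_a, matrix_b:
        pandas DataFrames (genes x samples, boolean) sharing a gene
        namespace (orthology mapping applied upstream).
    min_cases:
        Test only genes altered in at least ``min_cases`` samples of the
        reference cohort (``min_cases_cohort``: 'a', 'b' or 'either').

    Returns a DataFrame with columns gene, altered_a, n_a, altered_b, n_b,
    direction, p, q (BH across tested genes).
    """
    import pandas as pd

    shared = sorted(set(matrix_a.index) & set(matrix_b.index))
    if not shared:
        raise ValueError("no shared genes between cohorts")
    n_a, n_b = matrix_a.shape[1], matrix_b.shape[1]
    rows = []
    for gene in shared:
        alt_a = int(matrix_a.loc[gene].sum())
        alt_b = int(matrix_b.loc[gene].sum())
        reference = {"a": alt_a, "b": alt_b, "either": max(alt_a, alt_b)}[min_cases_cohort]
        if reference < min_cases:
            continue
        p = fisher_2x2(alt_a, n_a - alt_a, alt_b, n_b - alt_b)
        direction = "a>b" if alt_a / n_a > alt_b / n_b else (
            "a<b" if alt_a / n_a < alt_b / n_b else "=")
        rows.append({"gene": gene, "altered_a": alt_a, "n_a": n_a,
                     "altered_b": alt_b, "n_b": n_b,
                     "direction": direction, "p": p})
    result = pd.DataFrame(rows, columns=["gene", "altered_a", "n_a", "altered_b",
                                         "n_b", "direction", "p"])
    result["q"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    return result
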
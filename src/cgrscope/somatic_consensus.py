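"""Somatic consensus filtering.

Matched cases use two-caller intersections; tumor-only cases use a
panel-of-normals scheme: a variant is somatic only if every paired analysis
against a control labels it 'somatic' and none labels it 'germline'.

SV identity is fuzzy (same type, both breakpoints within <10 bp after
canonical ordering); identity across the N paired comparisons is therefore
resolved by single-linkage grouping under that relation, which is symmetric
but not transitive at fixed tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genomic_io import SnvCall, SvCall

__all__ = [
    "PairedAnalysisResult", "sv_equal", "group_svs", "tumor_only_svs",
    "consensus_snvs_paired", "tumor_only_snvs", "consensus_indels",
]

SV_MATCH_TOLERANCE_BP = 10


class ConsensusError(ValueError):
    pass


@dataclass
class PairedAnalysisResult:
    """Outcome of one tumor-vs-control paired analysis."""

    control_id: str
    somatic: list[SvCall] = field(default_factory=list)
    germline: list[SvCall] = field(default_factory=list)


def sv_equal(a: SvCall, b: SvCall, tolerance: int = SV_MATCH_TOLERANCE_BP) -> bool:
    """Same SV: identical type, matching chromosomes, both breakpoint
    distances strictly below ``tolerance`` (calls are canonically ordered
    at construction, so end-for-end comparison is well defined)."""
    return (a.sv_type == b.sv_type
            and a.chrom1 == b.chrom1 and a.chrom2 == b.chrom2
            and abs(a.pos1 - b.pos1) < tolerance
            and abs(a.pos2 - b.pos2) < tolerance)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_svs(calls: list[SvCall],
              tolerance: int = SV_MATCH_TOLERANCE_BP) -> list[list[int]]:
    """Single-linkage grouping of calls under :func:`sv_equal`.

    Returns groups as lists of indices into ``calls``. Candidate pairs are
    pre-bucketed by (type, chromosome pair) and sorted by pos1 so the pair
    scan stays near-linear.
    """
    uf = _UnionFind(len(calls))
    buckets: dict[tuple, list[int]] = {}
    for i, call in enumerate(calls):
        buckets.setdefault((call.sv_type, call.chrom1, call.chrom2), []).append(i)
    for indices in buckets.values():
        indices.sort(key=lambda i: calls[i].pos1)
        for a_pos, i in enumerate(indices):
            for j in indices[a_pos + 1:]:
                if calls[j].pos1 - calls[i].pos1 >= tolerance:
                    break
                if sv_equal(calls[i], calls[j], tolerance):
                    uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(uf.find(i), []).append(i)
    return list(groups.values())


def tumor_only_svs(results: list[PairedAnalysisResult],
                   tolerance: int = SV_MATCH_TOLERANCE_BP) -> list[SvCall]:
    """Panel-of-normals SV consensus.

    Keep an SV iff it is labeled somatic in *all* N paired analyses and
    germline in *none*. Identity across analyses via single-linkage grouping.
    """
    if not results:
        raise ConsensusError("at least one paired analysis result is required")
    n = len(results)
    pool: list[SvCall] = []
    labels: list[tuple[str, str]] = []  # (control_id, 'somatic'|'germline')
    for res in results:
        for call in res.somatic:
            pool.append(call)
            labels.append((res.control_id, "somatic"))
        for call in res.germline:
            pool.append(call)
            labels.append((res.control_id, "germline"))
    kept: list[SvCall] = []
    for group in group_svs(pool, tolerance):
        somatic_in = {labels[i][0] for i in group if labels[i][1] == "somatic"}
        germline_any = any(labels[i][1] == "germline" for i in group)
        if len(somatic_in) == n and not germline_any:
            rep = min((i for i in group if labels[i][1] == "somatic"),
                      key=lambda i: (pool[i].pos1, pool[i].pos2))
            kept.append(pool[rep])
    kept.sort(key=lambda c: (c.chrom1, c.pos1, c.chrom2, c.pos2))
    return kept


def consensus_snvs_paired(calls_a: list[SnvCall],
                          calls_b: list[SnvCall]) -> list[SnvCall]:
    """High-confidence SNVs detected by both callers (exact-key intersection,
    caller labels merged; record fields from caller A win elsewhere)."""
    by_key_b = {c.key: c for c in calls_b}
    out = []
    for call in calls_a:
        other = by_key_b.get(call.key)
        if other is not None:
            merged = call.callers | other.callers
            out.append(SnvCall(call.chromosome, call.position, call.ref, call.alt,
                               depth=call.depth, alt_count=call.alt_count,
                               callers=merged, hq_alt_count=call.hq_alt_count,
                               sample_id=call.sample_id))
    return out


def tumor_only_snvs(calls: list[SnvCall],
                    control_sets: list[set[tuple]],
                    vaf_min: float = 0.1) -> list[SnvCall]:
    """Keep SNVs with VAF strictly above ``vaf_min`` that appear in no control."""
    blacklist: set[tuple] = set()
    for cs in control_sets:
        blacklist.update(cs)
    out = []
    for call in calls:
        vaf = call.vaf
        if vaf is None or vaf <= vaf_min:
            continue
        if call.key in blacklist:
            continue
        out.append(call)
    return out


def consensus_indels(caller_a_indels: list[SnvCall],
                     caller_b_indels: list[SnvCall] | None,
                     control_sets: list[set[tuple]],
                     mode: str = "matched") -> list[SnvCall]:
    """Somatic indel consensus.

    matched mode — exact-key intersection of the two callers, minus any indel
    seen in a germline control. tumor-only mode — ``caller_a_indels`` holds
    per-comparison call lists concatenated is not supported; instead pass the
    per-comparison sets via :func:`tumor_only_indels`.
    """
    if mode != "matched":
        raise ConsensusError("use tumor_only_indels for tumor-only mode")
    if caller_b_indels is None:
        raise ConsensusError("matched mode requires both caller call sets")
    keys_b = {c.key for c in caller_b_indels}
    blacklist: set[tuple] = set()
    for cs in control_sets:
        blacklist.update(cs)
    return [c for c in caller_a_indels
            if c.key in keys_b and c.key not in blacklist]


def tumor_only_indels(per_comparison_calls: list[list[SnvCall]]) -> list[SnvCall]:
    """Tumor-only indels: the exact indel key must appear in every one of the
    N tumor-vs-control comparisons."""
    if not per_comparison_calls:
        raise ConsensusError("at least one comparison is required")
    key_sets = [{c.key for c in calls} for calls in per_comparison_calls]
    common = set.intersection(*key_sets)
    first_by_key = {c.key: c for c in per_comparison_calls[0]}
    return [first_by_key[k] for k in sorted(common)]
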
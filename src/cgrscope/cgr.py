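"""Complex genomic rearrangement (CGR) detection.

CGRs are connected components of the interleaving graph over intrachromosomal
SVs with at least 4 members. Two SVs interleave when their [pos1, pos2]
intervals partially overlap without either containing the other. Clusters on
different chromosomes are merged into multi-chromosomal CGRs when joined by a
direct translocation (one breakpoint inside each footprint) or when the
chromosome pair carries significantly more translocations than the tumor's
background rate (one-sided Fisher, BH-adjusted q < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort_stats import bh_adjust, fisher_2x2
from .genomic_io import GenomicInterval, SvCall

__all__ = [
    "CgrCluster", "MultiChromCgr", "LinkEvidence", "interleaved",
    "detect_clusters", "link_multichromosomal", "breakpoint_fraction_in_cgr",
]

MIN_CLUSTER_SIZE = 4


@dataclass
class CgrCluster:
    cluster_id: str
    chromosome: str
    members: list[SvCall]
    footprint: GenomicInterval

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class LinkEvidence:
    chrom_a: str
    chrom_b: str
    rule: str  # 'direct' or 'enrichment'
    n_translocations: int
    p: float | None = None
    q: float | None = None


@dataclass
class MultiChromCgr:
    clusters: list[CgrCluster]
    links: list[LinkEvidence] = field(default_factory=list)

    @property
    def chromosomes(self) -> list[str]:
        return sorted({c.chromosome for c in self.clusters})


def interleaved(a: SvCall, b: SvCall) -> bool:
    """Partial-overlap test: intervals overlap but neither contains the other.

    False (not an error) for translocations or SVs on different chromosomes.
    Shared endpoints count as containment, never interleaving.
    """
    if a.sv_type == "TRA" or b.sv_type == "TRA" or a.chrom1 != b.chrom1:
        return False
    a1, a2 = a.interval
    b1, b2 = b.interval
    if min(a2, b2) - max(a1, b1) <= 0:  # no positive-length overlap
        return False
    a_contains_b = a1 <= b1 and b2 <= a2
    b_contains_a = b1 <= a1 and a2 <= b2
    return not (a_contains_b or b_contains_a)


def detect_clusters(svs: list[SvCall],
                    min_size: int = MIN_CLUSTER_SIZE) -> list[CgrCluster]:
    """Connected components of the interleaving graph with >= min_size members.

    Footprint = leftmost to rightmost member breakpoint on the chromosome.
    """
    intra = [sv for sv in svs if sv.sv_type != "TRA"]
    by_chrom: dict[str, list[SvCall]] = {}
    for sv in intra:
        by_chrom.setdefault(sv.chrom1, []).append(sv)

    clusters: list[CgrCluster] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda s: (s.pos1, s.pos2))
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # sweep: j can only interleave i while j.pos1 < i.pos2
        for i, a in enumerate(members):
            for j in range(i + 1, len(members)):
                if members[j].pos1 >= a.pos2:
                    break
                if interleaved(a, members[j]):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        comps: dict[int, list[SvCall]] = {}
        for i, sv in enumerate(members):
            comps.setdefault(find(i), []).append(sv)
        for comp in comps.values():
            if len(comp) >= min_size:
                left = min(sv.pos1 for sv in comp)
                right = max(sv.pos2 for sv in comp)
                # half-open footprint must include the rightmost breakpoint
                clusters.append(CgrCluster(
                    cluster_id="", chromosome=chrom, members=comp,
                    footprint=GenomicInterval(chrom, left, right + 1)))
    clusters.sort(key=lambda c: (c.chromosome, c.footprint.start))
    for i, cluster in enumerate(clusters):
        cluster.cluster_id = f"cgr{i + 1}"
    return clusters


def _translocation_counts(translocations: list[SvCall]) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for sv in translocations:
        pair = tuple(sorted((sv.chrom1, sv.chrom2)))
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def translocation_enrichment(translocations: list[SvCall],
                             alpha: float = 0.01) -> list[LinkEvidence]:
    """Per chromosome pair, one-sided Fisher test of the pair's translocation
    count against the tumor's background rate; BH across pairs with >= 1 event.

    2x2 table: [[t_ij, t_i. - t_ij], [t_.j - t_ij, T - t_i. - t_.j + t_ij]].
    """
    counts = _translocation_counts(translocations)
    total = sum(counts.values())
    per_chrom: dict[str, int] = {}
    for (a, b), t in counts.items():
        per_chrom[a] = per_chrom.get(a, 0) + t
        per_chrom[b] = per_chrom.get(b, 0) + t
    evidence = []
    for (a, b), t_ij in sorted(counts.items()):
        t_i, t_j = per_chrom[a], per_chrom[b]
        p = fisher_2x2(t_ij, t_i - t_ij, t_j - t_ij,
                       total - t_i - t_j + t_ij, sided="greater")
        evidence.append(LinkEvidence(a, b, "enrichment", t_ij, p=p))
    qs = bh_adjust([e.p for e in evidence])
    for e, q in zip(evidence, qs):
        e.q = float(q)
    return [e for e in evidence if e.q < alpha]


def link_multichromosomal(clusters: list[CgrCluster],
                          translocations: list[SvCall],
                          alpha: float = 0.01) -> list[MultiChromCgr]:
    """Union-find closure of clusters over direct and enrichment links."""
    parent = list(range(len(clusters)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    links: list[LinkEvidence] = []

    # rule 1: a translocation with one breakpoint inside each footprint
    for sv in translocations:
        if sv.sv_type != "TRA":
            continue
        hits = [i for i, cl in enumerate(clusters)
                if cl.footprint.contains(sv.chrom1, sv.pos1)
                or cl.footprint.contains(sv.chrom2, sv.pos2)]
        for i in hits:
            for j in hits:
                if i < j and clusters[i].chromosome != clusters[j].chromosome:
                    union(i, j)
                    links.append(LinkEvidence(
                        *sorted((clusters[i].chromosome, clusters[j].chromosome)),
                        rule="direct", n_translocations=1))

    # rule 2: chromosome-pair translocation enrichment
    chrom_to_clusters: dict[str, list[int]] = {}
    for i, cl in enumerate(clusters):
        chrom_to_clusters.setdefault(cl.chromosome, []).append(i)
    for ev in translocation_enrichment(translocations, alpha=alpha):
        ca = chrom_to_clusters.get(ev.chrom_a, [])
        cb = chrom_to_clusters.get(ev.chrom_b, [])
        if ca and cb:
            links.append(ev)
            for i in ca:
                for j in cb:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(clusters)):
        groups.setdefault(find(i), []).append(i)
    out = []
    for group in groups.values():
        chroms = {clusters[i].chromosome for i in group}
        if len(chroms) < 2:
            continue
        group_links = [l for l in links
                       if l.chrom_a in chroms and l.chrom_b in chroms]
        out.append(MultiChromCgr(clusters=[clusters[i] for i in group],
                                 links=group_links))
    out.sort(key=lambda m: m.chromosomes)
    return out


def breakpoint_fraction_in_cgr(svs: list[SvCall],
                               clusters: list[CgrCluster]) -> float | None:
    """Fraction of all breakpoints (2 per SV) inside any cluster footprint.

    None (missing) when there are no breakpoints at all.
    """
    total = inside = 0
    for sv in svs:
        for chrom, pos in sv.breakpoints():
            total += 1
            if any(cl.footprint.contains(chrom, pos) for cl in clusters):
                inside += 1
    if total == 0:
        return None
    return inside / total
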
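from fractions import Fraction
from math import comb

import numpy as np
import pytest

from cgrscope.cgr import (
    breakpoint_fraction_in_cgr, detect_clusters, interleaved,
    link_multichromosomal, translocation_enrichment,
)
from cgrscope.simdata import CgrSpec, plant_cgr
from cgrscope.genome import default_mouse_genome

from conftest import make_sv, random_sv_instance


# --- independent oracles ----------------------------------------------------

def oracle_interleaved(span_a, span_b):
    """Strict crossing: s_a < s_b < e_a < e_b or s_b < s_a < e_b < e_a."""
    (sa, ea), (sb, eb) = span_a, span_b
    return (sa < sb < ea < eb) or (sb < sa < eb < ea)


def oracle_components(svs, min_size):
    """Brute-force all-pairs interleaving graph + DFS components."""
    n = len(svs)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = svs[i], svs[j]
            if a.sv_type == "TRA" or b.sv_type == "TRA" or a.chrom1 != b.chrom1:
                continue
            if oracle_interleaved(a.interval, b.interval):
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        if len(comp) >= min_size:
            comps.append(frozenset((svs[k].chrom1, svs[k].pos1, svs[k].pos2)
                                   for k in comp))
    return set(comps)


def oracle_fisher_greater(t_ij, t_i, t_j, total):
    """P(X >= t_ij) for X ~ Hypergeom(total, t_i, t_j), exact rationals."""
    p = Fraction(0)
    for k in range(t_ij, min(t_i, t_j) + 1):
        p += Fraction(comb(t_i, k) * comb(total - t_i, t_j - k),
                      comb(total, t_j))
    return float(p)


# --- interleaved ------------------------------------------------------------

class TestInterleaved:
    def test_partial_overlap(self):
        assert interleaved(make_sv("chr1", 0, 100), make_sv("chr1", 50, 150))

    def test_nested_is_not_interleaved(self):
        assert not interleaved(make_sv("chr1", 0, 100), make_sv("chr1", 10, 90))

    def test_disjoint(self):
        assert not interleaved(make_sv("chr1", 0, 100), make_sv("chr1", 200, 300))

    def test_different_chromosomes_false_not_error(self):
        assert not interleaved(make_sv("chr1", 0, 100), make_sv("chr2", 50, 150))

    def test_translocation_false(self):
        tra = make_sv("chr1", 50, 150, chrom2="chr2")
        assert not interleaved(make_sv("chr1", 0, 100), tra)

    def test_shared_endpoint_is_containment(self):
        assert not interleaved(make_sv("chr1", 0, 100), make_sv("chr1", 0, 150))
        assert not interleaved(make_sv("chr1", 0, 100), make_sv("chr1", 50, 100))

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            a1, a2 = sorted(rng.integers(0, 30, size=2))
            b1, b2 = sorted(rng.integers(0, 30, size=2))
            if a1 == a2 or b1 == b2:
                continue
            a = make_sv("chr1", int(a1), int(a2))
            b = make_sv("chr1", int(b1), int(b2))
            assert interleaved(a, b) == oracle_interleaved((a1, a2), (b1, b2))


# --- detect_clusters --------------------------------------------------------

def _cluster_keys(clusters):
    return {frozenset((sv.chrom1, sv.pos1, sv.pos2) for sv in cl.members)
            for cl in clusters}


class TestDetectClusters:
    def test_chain_of_four(self):
        svs = [make_sv("chr1", 0, 100), make_sv("chr1", 50, 150),
               make_sv("chr1", 120, 220), make_sv("chr1", 200, 300)]
        (cluster,) = detect_clusters(svs)
        assert cluster.size == 4
        # right-inclusive: footprint covers the rightmost breakpoint at 300
        assert (cluster.footprint.start, cluster.footprint.end) == (0, 301)

    def test_three_interleaved_is_no_cluster(self):
        svs = [make_sv("chr1", 0, 100), make_sv("chr1", 50, 150),
               make_sv("chr1", 120, 220)]
        assert detect_clusters(svs) == []

    def test_two_independent_components(self):
        comp1 = [make_sv("chr1", i * 50, i * 50 + 80) for i in range(4)]
        comp2 = [make_sv("chr1", 10_000 + i * 50, 10_000 + i * 50 + 80)
                 for i in range(5)]
        clusters = detect_clusters(comp1 + comp2)
        assert sorted(cl.size for cl in clusters) == [4, 5]

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            svs = random_sv_instance(rng, int(rng.integers(0, 51)))
            expected = oracle_components(svs, 4)
            assert _cluster_keys(detect_clusters(svs)) == expected

    def test_adding_disjoint_sv_preserves_membership(self):
        rng = np.random.default_rng(9)
        svs = random_sv_instance(rng, 30, chroms=("chr1",))
        before = _cluster_keys(detect_clusters(svs))
        svs.append(make_sv("chr1", 1_000_000, 1_000_100))  # far away
        after = _cluster_keys(detect_clusters(svs))
        assert before == after

    def test_planted_cgr_recovered_exactly(self):
        rng = np.random.default_rng(3)
        spec = CgrSpec(chromosomes=("chr15",), n_svs=6)
        svs, _, truth = plant_cgr(spec, default_mouse_genome(), rng)
        (cluster,) = detect_clusters(svs)
        assert {sv.sv_id for sv in cluster.members} == set(truth["sv_ids"])


# --- multi-chromosomal linking ---------------------------------------------

def _chain(chrom, lo, n=4, step=50, size=80):
    return [make_sv(chrom, lo + i * step, lo + i * step + size) for i in range(n)]


class TestLinking:
    def test_direct_translocation_joins_clusters(self):
        clusters = detect_clusters(_chain("chr7", 1000) + _chain("chr15", 2000))
        tra = make_sv("chr7", 1100, 2100, chrom2="chr15")
        (multi,) = link_multichromosomal(clusters, [tra])
        assert multi.chromosomes == ["chr15", "chr7"]
        assert any(l.rule == "direct" for l in multi.links)

    def test_zero_translocations_no_joins(self):
        clusters = detect_clusters(_chain("chr7", 1000) + _chain("chr15", 2000))
        assert link_multichromosomal(clusters, []) == []

    def test_enrichment_p_matches_hypergeometric_oracle(self):
        # t_ij=5 between A and B, t_i.=6, t_.j=6, T=30
        tras = []
        for i in range(5):
            tras.append(make_sv("chr1", 10 + 100 * i, 10 + 100 * i, chrom2="chr2"))
        tras.append(make_sv("chr1", 900, 10, chrom2="chr3"))
        tras.append(make_sv("chr2", 900, 10, chrom2="chr4"))
        for i in range(23):  # background among chr5..chr10
            c1, c2 = f"chr{5 + i % 3}", f"chr{8 + i % 3}"
            tras.append(make_sv(c1, 50 + i, 50 + i, chrom2=c2))
        evidence = translocation_enrichment(tras, alpha=0.01)
        hit = [e for e in evidence if {e.chrom_a, e.chrom_b} == {"chr1", "chr2"}]
        assert len(hit) == 1
        expected = oracle_fisher_greater(5, 6, 6, 30)
        assert expected == pytest.approx(2.442002442e-4, rel=1e-6)
        assert hit[0].p == pytest.approx(expected, rel=1e-9)
        assert hit[0].q < 0.01

    def test_enrichment_joins_clusters_without_direct_link(self):
        clusters = detect_clusters(_chain("chr1", 500_000) + _chain("chr2", 500_000))
        # translocations between chr1/chr2 but outside both footprints
        tras = [make_sv("chr1", 10 + i, 10 + i, chrom2="chr2") for i in range(5)]
        tras += [make_sv("chr1", 900, 10, chrom2="chr3"),
                 make_sv("chr2", 900, 10, chrom2="chr4")]
        tras += [make_sv(f"chr{5 + i % 3}", 50 + i, 50 + i, chrom2=f"chr{8 + i % 3}")
                 for i in range(23)]
        (multi,) = link_multichromosomal(clusters, tras)
        assert multi.chromosomes == ["chr1", "chr2"]
        assert all(l.rule == "enrichment" for l in multi.links)


# --- breakpoint fraction ----------------------------------------------------

class TestBreakpointFraction:
    def test_all_inside(self):
        svs = _chain("chr1", 1000)
        clusters = detect_clusters(svs)
        assert breakpoint_fraction_in_cgr(svs, clusters) == 1.0

    def test_four_of_ten(self):
        svs = _chain("chr1", 1000)  # 8 breakpoints inside
        outside = [make_sv("chr1", 50_000, 60_000)]  # 2 outside
        clusters = detect_clusters(svs)
        frac = breakpoint_fraction_in_cgr(svs[:2] + outside, clusters)
        assert frac == pytest.approx(4 / 6)
        assert breakpoint_fraction_in_cgr(svs + outside, clusters) == \
            pytest.approx(8 / 10)

    def test_no_clusters_gives_zero(self):
        assert breakpoint_fraction_in_cgr([make_sv("chr1", 0, 10)], []) == 0.0

    def test_no_breakpoints_is_missing(self):
        assert breakpoint_fraction_in_cgr([], []) is None
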
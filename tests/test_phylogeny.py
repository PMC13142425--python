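import numpy as np
import pandas as pd
import pytest

from cgrscope.phylogeny import (
    PresenceMatrix, assign_branch_lengths, bootstrap_support,
    build_presence_matrix, classify_clonality, enumerate_topologies,
    fitch_score, search_parsimony_tree, to_newick, tree_clades, upgma_sv_tree,
)

from conftest import make_sv


# --- independent oracles ----------------------------------------------------

def oracle_fitch(rows, samples, tree):
    """Set-based Fitch per character, rooted at an all-zero germline leaf."""
    total = 0
    for row in rows:
        state = dict(zip(samples, row))

        def post(node):
            nonlocal changes
            if isinstance(node, str):
                return {state[node]}
            left, right = post(node[0]), post(node[1])
            inter = left & right
            if inter:
                return inter
            changes += 1
            return left | right

        changes = 0
        root_set = post(tree)
        if 0 not in root_set:
            changes += 1
        total += changes
    return total


def oracle_topologies(samples):
    """Enumerate rooted binary topologies by root-split recursion (an
    implementation independent of the package's stepwise-insertion one)."""
    if len(samples) == 1:
        yield samples[0]
        return
    first, rest = samples[0], samples[1:]
    for bits in range(2 ** len(rest)):
        left = [first] + [s for i, s in enumerate(rest) if bits >> i & 1]
        right = [s for i, s in enumerate(rest) if not bits >> i & 1]
        if not right:
            continue
        for lt in oracle_topologies(left):
            for rt in oracle_topologies(right):
                yield (lt, rt)


def matrix_from_rows(rows, samples):
    return PresenceMatrix(
        samples=list(samples),
        sites=[("chr1", i, "A", "T") for i in range(len(rows))],
        data=np.array(rows, dtype=bool) if rows
        else np.zeros((0, len(samples)), bool))


# --- presence matrix --------------------------------------------------------

def _site_table(entries):
    return pd.DataFrame(entries, columns=["chromosome", "position", "ref",
                                          "alt", "depth", "hq_alt_count",
                                          "detected"])


class TestBuildPresenceMatrix:
    def test_low_depth_in_one_sample_excludes_site(self):
        tables = {
            "S1": _site_table([("chr1", 1, "A", "T", 100, 30, True)]),
            "S2": _site_table([("chr1", 1, "A", "T", 39, 30, True)]),
        }
        assert build_presence_matrix(tables).n_sites == 0

    def test_depth_forty_is_enough(self):
        tables = {
            "S1": _site_table([("chr1", 1, "A", "T", 100, 30, True)]),
            "S2": _site_table([("chr1", 1, "A", "T", 40, 0, False)]),
        }
        matrix = build_presence_matrix(tables)
        assert matrix.n_sites == 1
        assert list(matrix.data[0]) == [True, False]

    @pytest.mark.parametrize("hq,expected", [(3, True), (2, False)])
    def test_hq_alt_rescue_rule(self, hq, expected):
        tables = {
            "S1": _site_table([("chr1", 1, "A", "T", 100, 50, True)]),
            "S2": _site_table([("chr1", 1, "A", "T", 100, hq, False)]),
        }
        matrix = build_presence_matrix(tables)
        assert matrix.data[0][1] == expected

    def test_site_missing_from_one_sample_dropped_with_warning(self):
        tables = {
            "S1": _site_table([("chr1", 1, "A", "T", 100, 50, True)]),
            "S2": _site_table([]),
        }
        with pytest.warns(UserWarning, match="dropped"):
            matrix = build_presence_matrix(tables)
        assert matrix.n_sites == 0


class TestClonality:
    def test_labels(self):
        m = matrix_from_rows([[1, 1, 1, 1], [1, 0, 0, 0], [1, 1, 0, 0]],
                             ["S1", "S2", "S3", "S4"])
        assert classify_clonality(m) == ["truncal", "private", "shared"]

    def test_all_absent_is_error(self):
        m = matrix_from_rows([[0, 0]], ["S1", "S2"])
        with pytest.raises(ValueError):
            classify_clonality(m)

    def test_single_sample_is_error(self):
        m = matrix_from_rows([[1]], ["S1"])
        with pytest.raises(ValueError):
            classify_clonality(m)


# --- Fitch ------------------------------------------------------------------

SAMPLES3 = ["S1", "S2", "S3"]
ROWS3 = [[1, 1, 1], [1, 0, 0], [1, 1, 0]]  # {all}, {S1}, {S1,S2}


class TestFitchScore:
    def test_truncal_only_any_topology(self):
        m = matrix_from_rows([[1, 1, 1]] * 5, SAMPLES3)
        for tree in enumerate_topologies(SAMPLES3):
            assert fitch_score(m, tree) == 5

    def test_hand_worked_three_samples(self):
        m = matrix_from_rows(ROWS3, SAMPLES3)
        assert fitch_score(m, (("S1", "S2"), "S3")) == 3
        assert fitch_score(m, (("S1", "S3"), "S2")) == 4

    def test_empty_matrix(self):
        m = matrix_from_rows([], SAMPLES3)
        assert fitch_score(m, (("S1", "S2"), "S3")) == 0

    def test_leaf_mismatch_is_error(self):
        m = matrix_from_rows(ROWS3, SAMPLES3)
        with pytest.raises(ValueError):
            fitch_score(m, (("S1", "S2"), "S4"))

    def test_matches_set_based_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            samples = [f"S{i}" for i in range(n)]
            rows = (rng.random((int(rng.integers(1, 15)), n)) < 0.5).astype(int)
            rows = [r for r in rows.tolist() if any(r)]
            if not rows:
                continue
            m = matrix_from_rows(rows, samples)
            for tree in list(enumerate_topologies(samples))[:10]:
                assert fitch_score(m, tree) == oracle_fitch(rows, samples, tree)

    def test_lower_bound_is_mutation_count(self):
        rng = np.random.default_rng(6)
        samples = [f"S{i}" for i in range(5)]
        rows = [[1, 1, 0, 0, 1], [0, 1, 1, 0, 0], [1, 0, 1, 1, 1]]
        m = matrix_from_rows(rows, samples)
        for tree in enumerate_topologies(samples):
            assert fitch_score(m, tree) >= len(rows)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_rooted_topology_counts(self, n, count):
        samples = [f"S{i}" for i in range(n)]
        trees = list(enumerate_topologies(samples))
        assert len(trees) == count
        assert len({to_newick(t) for t in trees}) == count

    def test_matches_independent_enumerator(self):
        samples = ["a", "b", "c", "d", "e"]
        ours = {to_newick(t) for t in enumerate_topologies(samples)}
        oracle = {to_newick(t) for t in oracle_topologies(samples)}
        assert ours == oracle


class TestSearch:
    def test_hand_worked_minimum(self):
        m = matrix_from_rows(ROWS3, SAMPLES3)
        assert to_newick(search_parsimony_tree(m)) == to_newick((("S1", "S2"), "S3"))

    def test_perfect_phylogeny_zero_homoplasy(self):
        samples = [f"S{i}" for i in range(5)]
        rows = [[1] * 5, [1, 1, 1, 0, 0], [1, 1, 0, 0, 0], [0, 0, 0, 1, 1]]
        m = matrix_from_rows(rows, samples)
        tree = search_parsimony_tree(m)
        assert fitch_score(m, tree) == len(rows)

    def test_duplicated_columns_weight_invariance(self):
        m1 = matrix_from_rows(ROWS3, SAMPLES3)
        m10 = matrix_from_rows(ROWS3 * 10, SAMPLES3)
        assert to_newick(search_parsimony_tree(m1)) == \
            to_newick(search_parsimony_tree(m10))

    def test_matches_exhaustive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            samples = [f"S{i}" for i in range(n)]
            rows = (rng.random((10, n)) < 0.5).astype(int)
            rows = [r for r in rows.tolist() if any(r)]
            m = matrix_from_rows(rows, samples)
            best = min(oracle_fitch(rows, samples, t)
                       for t in oracle_topologies(samples))
            tree = search_parsimony_tree(m)
            assert fitch_score(m, tree) == best

    def test_ratchet_reaches_exhaustive_optimum_on_small_instance(self):
        rng = np.random.default_rng(13)
        samples = [f"S{i}" for i in range(6)]
        rows = (rng.random((15, 6)) < 0.5).astype(int)
        rows = [r for r in rows.tolist() if any(r)]
        m = matrix_from_rows(rows, samples)
        exhaustive = search_parsimony_tree(m, mode="exhaustive")
        ratchet = search_parsimony_tree(m, mode="ratchet", seed=4)
        assert fitch_score(m, ratchet) == fitch_score(m, exhaustive)

    def test_fewer_than_three_samples_degenerate(self):
        m = matrix_from_rows([[1, 1]], ["S1", "S2"])
        assert search_parsimony_tree(m) == ("S1", "S2")


class TestBranchLengths:
    def test_hand_worked_example(self):
        m = matrix_from_rows(ROWS3, SAMPLES3)
        tree = assign_branch_lengths((("S1", "S2"), "S3"), m)
        bl = tree.branch_lengths
        assert bl[frozenset(SAMPLES3)] == 1  # truncal on root edge
        assert bl[frozenset({"S1", "S2"})] == 1
        assert bl[frozenset({"S1"})] == 1
        assert bl[frozenset({"S2"})] == 0
        assert bl[frozenset({"S3"})] == 0
        assert tree.unassigned == 0
        assert tree.total_assigned() + tree.unassigned == m.n_sites

    def test_all_truncal_on_root_edge(self):
        m = matrix_from_rows([[1, 1, 1]] * 4, SAMPLES3)
        tree = assign_branch_lengths((("S1", "S2"), "S3"), m)
        assert tree.branch_lengths[frozenset(SAMPLES3)] == 4
        assert sum(v for k, v in tree.branch_lengths.items()
                   if k != frozenset(SAMPLES3)) == 0

    def test_non_clade_presence_set_is_unassigned(self):
        m = matrix_from_rows([[1, 0, 1]], SAMPLES3)  # {S1,S3} not a clade
        tree = assign_branch_lengths((("S1", "S2"), "S3"), m)
        assert tree.unassigned == 1
        assert tree.total_assigned() == 0


class TestUpgma:
    def _sets(self, profiles, samples):
        # build per-sample SV lists realizing the given binary profiles
        sv_sets = {s: [] for s in samples}
        for k, profile in enumerate(profiles):
            for j, present in enumerate(profile):
                if present:
                    sv_sets[samples[j]].append(
                        make_sv("chr1", 1000 * (k + 1), 1000 * (k + 1) + 500,
                                vaf=0.4, alt_reads=40, depth=100, sv_id=f"v{k}"))
        return sv_sets

    def test_hand_worked_example(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=4
        profiles = [(1, 0, 0), (0, 1, 0),  # A vs B differ in 2
                    (1, 1, 0), (1, 1, 0),  # shared by A,B, absent in C
                    (0, 0, 1)]  # d(A,C) = d(B,C) = 3 + 1 = 4
        tree = upgma_sv_tree(self._sets(profiles, ["A", "B", "C"]))
        assert tree.heights[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert tree.heights[frozenset({"A", "B", "C"})] == pytest.approx(2.0)
        assert tree.newick == "((A:1,B:1):1,C:2);"

    def test_identical_sets_zero_height_star(self):
        profiles = [(1, 1, 1), (1, 1, 1)]
        tree = upgma_sv_tree(self._sets(profiles, ["A", "B", "C"]))
        assert all(h == 0 for h in tree.heights.values())

    def test_af_threshold_strict(self):
        samples = ["A", "B"]
        sv_sets = {s: [make_sv("chr1", 1000, 2000, vaf=0.1, alt_reads=10,
                               depth=100, sv_id="v0")] for s in samples}
        sv_sets["A"].append(make_sv("chr1", 5000, 9000, vaf=0.11,
                                    alt_reads=11, depth=100, sv_id="v1"))
        tree = upgma_sv_tree(sv_sets)
        # v0 excluded (AF 0.1 nowhere > 0.1); only v1 separates A from B
        assert tree.heights[frozenset({"A", "B"})] == pytest.approx(0.5)

    def test_ultrametric(self):
        rng = np.random.default_rng(21)
        samples = [f"S{i}" for i in range(5)]
        profiles = (rng.random((12, 5)) < 0.5).astype(int).tolist()
        tree = upgma_sv_tree(self._sets(profiles, samples))
        # every merge height must be >= the heights of its children
        for clade, h in tree.heights.items():
            for other, oh in tree.heights.items():
                if other < clade:
                    assert oh <= h + 1e-9

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError):
            upgma_sv_tree({"A": []})


class TestBootstrap:
    def _perfect_matrix(self):
        samples = [f"S{i}" for i in range(4)]
        rows = ([[1, 1, 1, 1]] * 20 + [[1, 1, 0, 0]] * 20
                + [[1, 0, 0, 0]] * 20 + [[0, 0, 1, 1]] * 20)
        return matrix_from_rows(rows, samples)

    def test_saturated_signal_gives_high_support(self):
        support = bootstrap_support(self._perfect_matrix(), n_replicates=50,
                                    seed=3)
        assert support
        assert all(v >= 0.95 for v in support.values())

    def test_same_seed_is_reproducible(self):
        m = self._perfect_matrix()
        a = bootstrap_support(m, n_replicates=20, seed=9)
        b = bootstrap_support(m, n_replicates=20, seed=9)
        assert a == b

    def test_single_mutation_matrix_warns(self):
        m = matrix_from_rows([[1, 1, 0]], SAMPLES3)
        with pytest.warns(UserWarning, match="degenerate"):
            bootstrap_support(m, n_replicates=5, seed=0)


class TestRecoveryFromSimdata:
    def test_noise_free_cohort_recovers_truth(self, acceptance_cohort):
        cohort = acceptance_cohort
        matrix = build_presence_matrix(cohort.site_tables)
        # clonality labels match the planted branch structure exactly
        truth_labels = {}
        for clade, keys in cohort.branch_snvs.items():
            label = ("truncal" if len(clade) == len(cohort.samples)
                     else "private" if len(clade) == 1 else "shared")
            for key in keys:
                truth_labels[key] = label
        labels = classify_clonality(matrix)
        assert {site: lab for site, lab in zip(matrix.sites, labels)} == truth_labels
        # topology matches the planted caterpillar
        tree = search_parsimony_tree(matrix)
        assert tree_clades(tree) == tree_clades(cohort.topology)
        # branch lengths equal planted counts
        clone_tree = assign_branch_lengths(tree, matrix)
        for clade, keys in cohort.branch_snvs.items():
            assert clone_tree.branch_lengths[clade] == len(keys)
        assert clone_tree.unassigned == 0
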
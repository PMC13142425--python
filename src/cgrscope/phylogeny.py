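"""Multi-region clonal phylogenetics.

Presence/absence matrices are built under depth >= 40 in every sample with a
>= 3 high-quality-alt-read rescue rule; clonality is truncal (all samples),
shared (>= 2, < all) or private (exactly one). Trees are rooted by an
implicit all-absent germline outgroup. Maximum parsimony uses Fitch small
parsimony; topologies are represented as nested tuples of sample names.

Fitch is evaluated with per-node Python bigints acting as bitmasks over
characters, which makes exhaustive enumeration practical up to 8 samples
(135,135 rooted topologies); larger instances use a seeded parsimony ratchet
(random 25% column upweighting + nearest-neighbor-interchange hill climbing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genomic_io import SvCall
from .somatic_consensus import group_svs

__all__ = [
    "PresenceMatrix", "CloneTree", "build_presence_matrix", "classify_clonality",
    "fitch_score", "enumerate_topologies", "search_parsimony_tree",
    "assign_branch_lengths", "upgma_sv_tree", "bootstrap_support",
    "tree_clades", "to_newick",
]

MIN_DEPTH_ALL_SAMPLES = 40
MIN_HQ_ALT_READS = 3

Topology = tuple | str  # nested tuples of sample-name leaves


# ---------------------------------------------------------------------------
# presence matrix


@dataclass
class PresenceMatrix:
    samples: list[str]
    sites: list[tuple]  # (chromosome, position, ref, alt)
    data: np.ndarray  # sites x samples, bool

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.sites), len(self.samples)):
            raise ValueError("matrix shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def clonality(self) -> list[str]:
        return classify_clonality(self)

    def presence_set(self, row: int) -> frozenset[str]:
        return frozenset(s for s, present in zip(self.samples, self.data[row])
                         if present)


def build_presence_matrix(site_tables: dict[str, pd.DataFrame],
                          min_depth: int = MIN_DEPTH_ALL_SAMPLES,
                          min_hq_alt: int = MIN_HQ_ALT_READS) -> PresenceMatrix:
    """Presence/absence matrix from per-sample site tables.

    Each table needs columns chromosome, position, ref, alt, depth,
    hq_alt_count, detected. A site is retained iff it appears in every
    sample's table (sites missing depth data anywhere are dropped with a
    warning) and has depth >= ``min_depth`` in every sample. Presence in a
    sample = caller-detected there OR hq_alt_count >= ``min_hq_alt``.
    """
    samples = sorted(site_tables)
    indexed = {}
    for sample, df in site_tables.items():
        indexed[sample] = df.set_index(["chromosome", "position", "ref", "alt"])
    all_sites = sorted(set().union(*(set(ix.index) for ix in indexed.values())))
    sites, rows, dropped = [], [], 0
    for site in all_sites:
        if not all(site in indexed[s].index for s in samples):
            dropped += 1
            continue
        recs = [indexed[s].loc[site] for s in samples]
        if any(pd.isna(r["depth"]) for r in recs):
            dropped += 1
            continue
        if any(int(r["depth"]) < min_depth for r in recs):
            continue
        row = [bool(r["detected"]) or int(r["hq_alt_count"]) >= min_hq_alt
               for r in recs]
        if not any(row):
            continue
        sites.append(site)
        rows.append(row)
    if dropped:
        warnings.warn(f"{dropped} sites dropped for missing depth data", stacklevel=2)
    data = np.array(rows, dtype=bool) if rows else np.zeros((0, len(samples)), bool)
    return PresenceMatrix(samples=samples, sites=sites, data=data)


def classify_clonality(matrix: PresenceMatrix) -> list[str]:
    """truncal = all samples, private = exactly one, shared = in between."""
    if len(matrix.samples) < 2:
        raise ValueError("clonality requires at least 2 samples")
    labels = []
    n = len(matrix.samples)
    for row in matrix.data:
        count = int(row.sum())
        if count == 0:
            raise ValueError("mutation absent from every sample")
        labels.append("truncal" if count == n
                      else "private" if count == 1 else "shared")
    return labels


# ---------------------------------------------------------------------------
# Fitch parsimony on bitmask columns


def _column_masks(matrix: PresenceMatrix) -> dict[str, int]:
    """Per-sample bigint with bit k set iff mutation k present in the sample."""
    masks = {}
    for j, sample in enumerate(matrix.samples):
        mask = 0
        for k in range(matrix.n_sites):
            if matrix.data[k, j]:
                mask |= 1 << k
        masks[sample] = mask
    return masks


def _fitch_node(tree, masks: dict[str, int], full: int) -> tuple[int, int, int]:
    """Postorder Fitch. Returns (zero_set_mask, one_set_mask, n_changes)."""
    if isinstance(tree, str):
        one = masks[tree]
        return (~one) & full, one, 0
    left, right = tree
    a0, a1, ca = _fitch_node(left, masks, full)
    b0, b1, cb = _fitch_node(right, masks, full)
    i0, i1 = a0 & b0, a1 & b1
    union_events = full & ~(i0 | i1)
    changes = ca + cb + union_events.bit_count()
    z0 = i0 | (union_events & (a0 | b0))
    z1 = i1 | (union_events & (a1 | b1))
    return z0, z1, changes


def _fitch_score_masks(tree, masks: dict[str, int], full: int,
                       n_sites: int) -> int:
    if n_sites == 0:
        return 0
    if isinstance(tree, str) or len(_leaves(tree)) == 1:
        # single sample: germline root 0, each present mutation = 1 change
        one = masks[tree] if isinstance(tree, str) else masks[_leaves(tree)[0]]
        return one.bit_count()
    z0, _, changes = _fitch_node(tree, masks, full)
    # root against the all-zero germline outgroup
    changes += (full & ~z0).bit_count()
    return changes


def fitch_score(matrix: PresenceMatrix, topology: Topology) -> int:
    """Fitch small-parsimony change count, rooted at an all-absent germline."""
    leaves = _leaves(topology)
    if sorted(leaves) != sorted(matrix.samples):
        raise ValueError("topology leaf set does not match matrix samples")
    full = (1 << matrix.n_sites) - 1
    return _fitch_score_masks(topology, _column_masks(matrix), full, matrix.n_sites)


# ---------------------------------------------------------------------------
# topology utilities


def _leaves(tree: Topology) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    return _leaves(tree[0]) + _leaves(tree[1])


def tree_clades(tree: Topology, include_trivial: bool = False) -> set[frozenset[str]]:
    """Leaf sets of every internal node (plus leaves/root if requested)."""
    clades: set[frozenset[str]] = set()

    def walk(node) -> frozenset[str]:
        if isinstance(node, str):
            leaf = frozenset([node])
            if include_trivial:
                clades.add(leaf)
            return leaf
        below = walk(node[0]) | walk(node[1])
        clades.add(below)
        return below

    walk(tree)
    if not include_trivial:
        clades.discard(frozenset(_leaves(tree)))
    return clades


def to_newick(tree: Topology, branch_lengths: dict[frozenset[str], float] | None = None,
              canonical: bool = True) -> str:
    """Newick string; children sorted for a canonical form."""

    def fmt(node) -> tuple[str, frozenset[str]]:
        if isinstance(node, str):
            label, clade = node, frozenset([node])
        else:
            parts = [fmt(child) for child in node]
            if canonical:
                parts.sort(key=lambda p: p[0])
            label = "(" + ",".join(p[0] for p in parts) + ")"
            clade = frozenset().union(*(p[1] for p in parts))
        if branch_lengths is not None:
            label += f":{branch_lengths.get(clade, 0):g}"
        return label, clade

    return fmt(tree)[0] + ";"


def enumerate_topologies(samples: list[str]):
    """Yield every rooted binary topology over ``samples`` ((2n-3)!! trees)."""
    if not samples:
        return
    if len(samples) == 1:
        yield samples[0]
        return

    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if not isinstance(tree, str):
            left, right = tree
            for t in insert_everywhere(left, leaf):
                yield (t, right)
            for t in insert_everywhere(right, leaf):
                yield (left, t)

    def build(trees, remaining):
        if not remaining:
            yield from trees
            return
        leaf, rest = remaining[0], remaining[1:]
        yield from build((t2 for t in trees for t2 in insert_everywhere(t, leaf)),
                         rest)

    yield from build([samples[0]], samples[1:])


def nni_neighbors(tree: Topology):
    """All topologies one nearest-neighbor interchange away."""
    if isinstance(tree, str):
        return
    left, right = tree
    if not isinstance(left, str):
        l1, l2 = left
        yield ((l1, right), l2)
        yield ((l2, right), l1)
    if not isinstance(right, str):
        r1, r2 = right
        yield (r1, (r2, left))
        yield (r2, (r1, left))
    for t in nni_neighbors(left):
        yield (t, right)
    for t in nni_neighbors(right):
        yield (left, t)


EXHAUSTIVE_MAX_SAMPLES = 8
RATCHET_ITERATIONS = 50
RATCHET_UPWEIGHT_FRACTION = 0.25


def search_parsimony_tree(matrix: PresenceMatrix, mode: str = "auto",
                          seed: int = 0) -> Topology:
    """Maximum-parsimony topology.

    <= 8 samples (or mode='exhaustive'): exhaustive scan, globally optimal,
    ties broken by lexicographically smallest canonical newick. Larger
    instances: seeded parsimony ratchet (25% column upweighting, NNI hill
    climbing, 50 iterations).
    """
    samples = matrix.samples
    if len(samples) < 3:
        return tuple(samples) if len(samples) == 2 else (
            samples[0] if samples else ())
    if mode == "auto":
        mode = ("exhaustive" if len(samples) <= EXHAUSTIVE_MAX_SAMPLES else "ratchet")
    masks = _column_masks(matrix)
    full = (1 << matrix.n_sites) - 1
    if mode == "exhaustive":
        best_score, best_key, best_tree = None, None, None
        for tree in enumerate_topologies(samples):
            score = _fitch_score_masks(tree, masks, full, matrix.n_sites)
            if best_score is None or score < best_score:
                best_score, best_key, best_tree = score, to_newick(tree), tree
            elif score == best_score:
                key = to_newick(tree)
                if key < best_key:
                    best_key, best_tree = key, tree
        return best_tree
    if mode != "ratchet":
        raise ValueError(f"unknown search mode {mode!r}")
    return _ratchet(matrix, masks, full, seed)


def _remove_leaf(tree, leaf):
    if isinstance(tree, str):
        return None if tree == leaf else tree
    left = _remove_leaf(tree[0], leaf)
    right = _remove_leaf(tree[1], leaf)
    if left is None:
        return right
    if right is None:
        return left
    return (left, right)


def _neighbors(tree):
    """NNI rearrangements plus single-leaf reinsertions (richer than NNI
    alone, which stalls easily on greedy starts)."""
    yield from nni_neighbors(tree)
    leaves = _leaves(tree)
    if len(leaves) < 4:
        return
    for leaf in leaves:
        pruned = _remove_leaf(tree, leaf)
        for cand in _insertions(pruned, leaf):
            yield cand


def _hill_climb(tree, masks, full, n_sites):
    score = _fitch_score_masks(tree, masks, full, n_sites)
    improved = True
    while improved:
        improved = False
        for cand in _neighbors(tree):
            s = _fitch_score_masks(cand, masks, full, n_sites)
            if s < score:
                tree, score, improved = cand, s, True
                break
    return tree, score


RATCHET_RESTARTS = 3


def _ratchet(matrix: PresenceMatrix, masks, full, seed: int) -> Topology:
    rng = np.random.default_rng(seed)
    best, best_score = None, None
    for restart in range(RATCHET_RESTARTS):
        tree, score = _ratchet_walk(matrix, masks, full, rng,
                                    RATCHET_ITERATIONS // RATCHET_RESTARTS)
        if best_score is None or score < best_score or \
                (score == best_score and to_newick(tree) < to_newick(best)):
            best, best_score = tree, score
    return best


def _ratchet_walk(matrix, masks, full, rng, n_iterations):
    samples = list(matrix.samples)
    n_sites = matrix.n_sites
    order = list(rng.permutation(samples))

    # greedy stepwise-addition start tree
    tree: Topology = (order[0], order[1])
    for leaf in order[2:]:
        best = None
        for cand in _insertions(tree, leaf):
            s = _fitch_score_masks(cand, masks, full, n_sites)
            if best is None or s < best[0]:
                best = (s, cand)
        tree = best[1]
    current, score = _hill_climb(tree, masks, full, n_sites)
    best, best_score = current, score

    for _ in range(n_iterations):
        # upweight a random 25% of columns by duplicating their bits
        n_up = max(1, int(round(RATCHET_UPWEIGHT_FRACTION * n_sites)))
        up = rng.choice(n_sites, size=n_up, replace=False) if n_sites else []
        w_masks = {}
        for sample, mask in masks.items():
            extra = 0
            for b, k in enumerate(up):
                if mask >> int(k) & 1:
                    extra |= 1 << (n_sites + b)
            w_masks[sample] = mask | extra
        w_full = (1 << (n_sites + len(up))) - 1
        perturbed, _ = _hill_climb(current, w_masks, w_full, n_sites + len(up))
        # the unweighted re-optimization continues from the perturbed tree,
        # whether or not it beats the incumbent (classic ratchet walk)
        current, cur_score = _hill_climb(perturbed, masks, full, n_sites)
        if cur_score < best_score or (cur_score == best_score
                                      and to_newick(current) < to_newick(best)):
            best, best_score = current, cur_score
    return best, best_score


def _insertions(tree, leaf):
    yield (tree, leaf)
    if not isinstance(tree, str):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


# ---------------------------------------------------------------------------
# branch lengths


@dataclass
class CloneTree:
    topology: Topology
    samples: list[str]
    branch_lengths: dict[frozenset[str], int]  # clade -> mutation count
    unassigned: int = 0  # homoplasic presence sets

    def newick(self) -> str:
        inner = to_newick(self.topology, {k: float(v)
                                          for k, v in self.branch_lengths.items()})
        return inner

    def total_assigned(self) -> int:
        return sum(self.branch_lengths.values())


def assign_branch_lengths(topology: Topology, matrix: PresenceMatrix) -> CloneTree:
    """Branch length = number of mutations whose presence set equals the clade
    below that branch; the root edge carries truncal mutations; non-clade
    presence sets are counted as unassigned, never forced onto a branch."""
    clades = tree_clades(topology, include_trivial=True)
    clades.add(frozenset(matrix.samples))  # root edge
    lengths = {clade: 0 for clade in clades}
    unassigned = 0
    for row in range(matrix.n_sites):
        pset = matrix.presence_set(row)
        if pset in lengths:
            lengths[pset] += 1
        else:
            unassigned += 1
    return CloneTree(topology=topology, samples=list(matrix.samples),
                     branch_lengths=lengths, unassigned=unassigned)


# ---------------------------------------------------------------------------
# UPGMA on SV profiles


@dataclass
class UpgmaTree:
    samples: list[str]
    linkage: np.ndarray  # scipy linkage matrix (average method)
    newick: str
    heights: dict[frozenset[str], float] = field(default_factory=dict)


def upgma_sv_tree(sv_sets: dict[str, list[SvCall]], af_min: float = 0.1) -> UpgmaTree:
    """UPGMA dendrogram from binary SV presence profiles.

    SVs are matched across samples by single-linkage fuzzy grouping; a group
    enters the profile only if some member has allele fraction strictly above
    ``af_min``. Distance = Hamming count; node height = merge distance / 2
    (ultrametric).
    """
    samples = sorted(sv_sets)
    if len(samples) < 2:
        raise ValueError("UPGMA requires at least 2 samples")
    pool, owners = [], []
    for sample in samples:
        for sv in sv_sets[sample]:
            pool.append(sv)
            owners.append(sample)
    profiles = []
    for group in group_svs(pool):
        if not any(pool[i].vaf is not None and pool[i].vaf > af_min for i in group):
            continue
        present = {owners[i] for i in group}
        profiles.append([s in present for s in samples])
    prof = np.array(profiles, dtype=bool) if profiles \
        else np.zeros((0, len(samples)), bool)
    n = len(samples)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = int(np.sum(prof[:, i] != prof[:, j]))
            dist[i, j] = dist[j, i] = d
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")

    heights: dict[frozenset[str], float] = {}
    clusters: dict[int, frozenset[str]] = {i: frozenset([s])
                                           for i, s in enumerate(samples)}
    labels: dict[int, str] = dict(enumerate(samples))
    for step, (a, b, d, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + step
        clusters[node] = clusters[a] | clusters[b]
        heights[clusters[node]] = d / 2.0

        def with_len(idx: int) -> str:
            top = d / 2.0
            own = heights.get(clusters[idx], 0.0)
            return f"{labels[idx]}:{top - own:g}"

        labels[node] = "(" + ",".join(sorted([with_len(a), with_len(b)])) + ")"
    return UpgmaTree(samples=samples, linkage=Z,
                     newick=labels[2 * n - 2] + ";", heights=heights)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(matrix: PresenceMatrix, n_replicates: int = 100,
                      seed: int = 0) -> dict[frozenset[str], float]:
    """Clade support by resampling mutation columns with replacement.

    Supports are reported for the clades of the tree inferred from the full
    matrix; reproducible under ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if matrix.n_sites < 2:
        warnings.warn("bootstrap on <2 mutations is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    reference = search_parsimony_tree(matrix, seed=seed)
    ref_clades = tree_clades(reference)
    hits = {clade: 0 for clade in ref_clades}
    for _ in range(n_replicates):
        idx = rng.integers(0, max(matrix.n_sites, 1), size=max(matrix.n_sites, 1))
        resampled = PresenceMatrix(
            samples=list(matrix.samples),
            sites=[matrix.sites[i] if matrix.n_sites else ("", 0, "", "")
                   for i in idx],
            data=matrix.data[idx] if matrix.n_sites
            else np.zeros((len(idx), len(matrix.samples)), bool))
        tree = search_parsimony_tree(resampled, seed=seed)
        found = tree_clades(tree)
        for clade in ref_clades:
            if clade in found:
                hits[clade] += 1
    return {clade: count / n_replicates for clade, count in hits.items()}
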
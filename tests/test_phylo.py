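"""Window haplotypes, pairwise distances, and neighbour joining (checked
against closed forms, brute-force topology enumeration, random additive
trees, and dendropy's independent NJ)."""

import io as stdio
import itertools

import dendropy
import numpy as np
import pytest

from ricechip import phylo as ph
from ricechip.models import AA, AB, BB, NOCALL, GenotypeMatrix
from ricechip.simulate import simulate_genotype_matrix


def _matrix(calls, chrom=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        [f"m{j}" for j in range(m)],
        chrom or ["1"] * m,
        list(range(1, m + 1)),
        calls,
    )


# ---------------------------------------------------------------------------
# windows

def test_twelve_markers_make_two_windows_of_five():
    m = _matrix(np.zeros((2, 12), dtype=np.int8))
    haps = ph.window_haplotypes(m, w=5)
    assert [(c, a, b) for c, a, b in haps.windows] == [
        ("1", 0, 4), ("1", 5, 9)
    ]


def test_nocall_voids_only_its_window():
    calls = np.zeros((1, 10), dtype=np.int8)
    calls[0, 2] = NOCALL
    haps = ph.window_haplotypes(_matrix(calls), w=5)
    assert haps.hap[0][0] is None
    assert haps.hap[0][1] == "AA" * 5


def test_identical_samples_share_haplotype_rows():
    calls = np.tile(np.array([AA, AB, BB, AA, AB] * 2, dtype=np.int8), (2, 1))
    haps = ph.window_haplotypes(_matrix(calls), w=5)
    assert haps.hap[0] == haps.hap[1]


def test_windows_never_span_chromosomes():
    chrom = ["1"] * 7 + ["2"] * 6
    m = _matrix(np.zeros((1, 13), dtype=np.int8), chrom=chrom)
    haps = ph.window_haplotypes(m, w=5)
    assert [c for c, _, _ in haps.windows] == ["1", "2"]


def test_invalid_window_width_rejected():
    with pytest.raises(ValueError):
        ph.window_haplotypes(_matrix(np.zeros((1, 5), dtype=np.int8)), w=0)


# ---------------------------------------------------------------------------
# distances

def test_haplotype_distance_identity_extremes_and_fraction():
    assert ph.haplotype_distance(["x", "y"], ["x", "y"]) == 0.0
    assert ph.haplotype_distance(["x", "y"], ["a", "b"]) == 1.0
    assert ph.haplotype_distance(
        ["a", "b", "c", "d", "e"], ["a", "B", "c", "D", "e"]
    ) == pytest.approx(0.4)


def test_missing_windows_use_pairwise_deletion():
    assert ph.haplotype_distance(["a", None, "c"], ["a", "b", "x"]) == 0.5


def test_zero_comparable_windows_rejected():
    with pytest.raises(ValueError, match="comparable"):
        ph.haplotype_distance([None, "a"], ["b", None])


def test_distance_matrix_symmetry_and_identity(rng):
    m, _ = simulate_genotype_matrix(8, 50, missing_rate=0.05, seed=2)
    d = ph.distance_matrix(ph.window_haplotypes(m))
    assert np.allclose(d.d, d.d.T)
    assert np.all(np.diag(d.d) == 0)
    assert np.all((d.d >= 0) & (d.d <= 1))


# ---------------------------------------------------------------------------
# neighbour joining

def test_three_taxon_closed_form():
    d = ph.DistanceMatrix(
        ["A", "B", "C"], np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    )
    assert ph.write_newick(ph.neighbor_joining(d)) == (
        "(A:2.000000,B:3.000000,C:7.000000);"
    )


def _tree_from_additive_4taxon():
    # tree ((A:2,B:3):1,(C:4,D:5)) -> pairwise path lengths
    d = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        float,
    )
    return ph.DistanceMatrix(["A", "B", "C", "D"], d)


def test_four_taxon_additive_matrix_recovers_generating_tree():
    dist = _tree_from_additive_4taxon()
    tree = ph.neighbor_joining(dist)
    # exact additive fit: the tree's path metric reproduces the input
    back = ph.tree_path_distances(tree)
    assert back.sample_ids == dist.sample_ids
    assert np.allclose(back.d, dist.d)


def test_four_taxon_topology_beats_brute_force_alternatives():
    """Of the 3 unrooted 4-taxon topologies only AB|CD admits an exact
    additive fit; check NJ picks it by splitting A,B from C,D."""
    dist = _tree_from_additive_4taxon()
    # four-point condition identifies the valid split
    d = dist.d
    sums = {
        "AB|CD": d[0, 1] + d[2, 3],
        "AC|BD": d[0, 2] + d[1, 3],
        "AD|BC": d[0, 3] + d[1, 2],
    }
    assert min(sums, key=sums.get) == "AB|CD"
    newick = ph.write_newick(ph.neighbor_joining(dist))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    splits = {
        frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        for node in tree.preorder_node_iter()
    }
    assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits


def test_duplicate_taxa_become_zero_length_siblings():
    d = np.array(
        [
            [0, 0, 4, 5, 6],
            [0, 0, 4, 5, 6],
            [4, 4, 0, 3, 4],
            [5, 5, 3, 0, 3],
            [6, 6, 4, 3, 0],
        ],
        float,
    )
    newick = ph.write_newick(
        ph.neighbor_joining(ph.DistanceMatrix(["X", "Y", "C", "D", "E"], d))
    )
    assert "(X:0.000000,Y:0.000000)" in newick


def _random_additive(rng, n_leaves):
    """Random binary tree with positive lengths and its path metric."""
    names = [f"t{i:02d}" for i in range(n_leaves)]
    nodes = [ph.TreeNode(name=x) for x in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = ph.TreeNode(
            children=[
                (a, float(rng.uniform(0.5, 3.0))),
                (b, float(rng.uniform(0.5, 3.0))),
            ]
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = ph.TreeNode(
        children=[(x, float(rng.uniform(0.5, 3.0))) for x in nodes]
    )
    return root


def test_nj_consistency_on_random_additive_trees(rng):
    """NJ reconstructs random additive trees (up to 12 leaves) exactly."""
    for n_leaves in (4, 5, 6, 8, 10, 12):
        for _ in range(5):
            true_tree = _random_additive(rng, n_leaves)
            dist = ph.tree_path_distances(true_tree)
            recovered = ph.neighbor_joining(dist)
            back = ph.tree_path_distances(recovered)
            assert back.sample_ids == dist.sample_ids
            assert np.allclose(back.d, dist.d, atol=1e-9)


def test_nj_matches_dendropy_topology(rng):
    true_tree = _random_additive(rng, 9)
    dist = ph.tree_path_distances(true_tree)
    mine = ph.write_newick(ph.neighbor_joining(dist))

    csv = "," + ",".join(dist.sample_ids) + "\n"
    for i, s in enumerate(dist.sample_ids):
        csv += s + "," + ",".join(str(x) for x in dist.d[i]) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        stdio.StringIO(csv), delimiter=","
    )
    theirs = pdm.nj_tree()
    taxa = theirs.taxon_namespace
    mine_tree = dendropy.Tree.get(
        data=mine, schema="newick", taxon_namespace=taxa
    )
    mine_tree.encode_bipartitions()
    theirs.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(
        mine_tree, theirs
    )
    assert rf == 0


def test_taxon_input_order_does_not_change_the_tree(rng):
    true_tree = _random_additive(rng, 7)
    dist = ph.tree_path_distances(true_tree)
    newick_a = ph.write_newick(ph.neighbor_joining(dist))
    perm = rng.permutation(len(dist.sample_ids))
    shuffled = ph.DistanceMatrix(
        [dist.sample_ids[i] for i in perm], dist.d[np.ix_(perm, perm)]
    )
    newick_b = ph.write_newick(ph.neighbor_joining(shuffled))
    assert newick_a == newick_b


def test_invalid_distance_matrices_rejected():
    with pytest.raises(ValueError):
        ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))
    with pytest.raises(ValueError):
        ph.DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]], float))
    with pytest.raises(ValueError, match="at least 3"):
        ph.neighbor_joining(
            ph.DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        )


def test_newick_roundtrip_preserves_topology():
    d = _tree_from_additive_4taxon()
    newick = ph.write_newick(ph.neighbor_joining(d))
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == [
        "A", "B", "C", "D"
    ]


# ---------------------------------------------------------------------------
# hypothesis properties

from hypothesis import given, settings
from hypothesis import strategies as st

_hap_cell = st.sampled_from([None, "AAABB", "ABBBA"])


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.tuples(_hap_cell, _hap_cell), min_size=1, max_size=20))
def test_haplotype_distance_identity_and_symmetry(pairs):
    hi = [a for a, _ in pairs]
    hj = [b for _, b in pairs]
    comparable = any(a is not None and b is not None for a, b in pairs)
    if not comparable:
        with pytest.raises(ValueError):
            ph.haplotype_distance(hi, hj)
        return
    d_ij = ph.haplotype_distance(hi, hj)
    d_ji = ph.haplotype_distance(hj, hi)
    assert d_ij == d_ji
    assert 0.0 <= d_ij <= 1.0
    assert ph.haplotype_distance(hi, hi if any(
        a is not None for a in hi) else hj) >= 0.0 if comparable else True
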
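import collections
import itertools
import math

import numpy as np
import pytest

from oryzapop.phylo import (
    DistanceMatrix,
    detect_segregating_haplotypes,
    distance_matrix,
    extract_gene_haplotypes,
    genome_distance,
    major_clade_leaves,
    nj_tree,
    p_distance,
    p_distance_tree,
    read_newick,
    tree_distance_table,
    write_newick,
)
from oryzapop.variantio import MISSING


# -- genome distance ---------------------------------------------------------

def test_genome_distance_trivial_cases():
    g = np.array([0, 1, 2, 1], dtype=np.int8)
    assert genome_distance(g, g)[0] == 0.0
    a = np.zeros(4, dtype=np.int8)
    b = np.full(4, 2, dtype=np.int8)
    assert genome_distance(a, b)[0] == 1.0


def test_genome_distance_het_half():
    d, L = genome_distance(np.array([0], dtype=np.int8),
                           np.array([1], dtype=np.int8))
    assert d == 0.5 and L == 1


def test_distance_matrix_matches_pair_loop(matrix_factory):
    rng = np.random.default_rng(8)
    g = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
    m = matrix_factory(g)
    D = distance_matrix(m)
    for i, j in itertools.combinations(range(6), 2):
        want = np.abs(g[i].astype(int) - g[j].astype(int)).sum() / (2 * 50)
        assert D.values[i, j] == pytest.approx(want, abs=1e-15)


def test_distance_matrix_symmetric_under_missingness(matrix_factory):
    rng = np.random.default_rng(9)
    g = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
    g[rng.random(g.shape) < 0.2] = MISSING
    m = matrix_factory(g)
    D = distance_matrix(m)
    np.testing.assert_allclose(D.values, D.values.T)
    assert (D.n_sites < 40).any()
    assert (np.diag(D.values) == 0).all()


# -- neighbour joining -------------------------------------------------------

def test_nj_recovers_four_taxon_tree():
    # unrooted tree: A and B join u (1, 2); C and D join v (3, 4); u-v = 1
    ids = ["A", "B", "C", "D"]
    D = np.array(
        [[0, 3, 5, 6],
         [3, 0, 6, 7],
         [5, 6, 0, 7],
         [6, 7, 7, 0]], dtype=float
    )
    tree, clamped = nj_tree(D, ids=ids)
    assert clamped == 0
    tab = tree_distance_table(tree)
    for (a, b), v in tab.items():
        i, j = ids.index(a), ids.index(b)
        assert v == pytest.approx(D[i, j], abs=1e-12)
    splits = {
        frozenset(l.taxon.label for l in e.head_node.leaf_iter())
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    }
    assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree, _ = nj_tree(D, ids=["A", "B", "C"])
    tab = tree_distance_table(tree)
    # branch lengths solve the three-point formulas exactly
    for (a, b), v in tab.items():
        i, j = "ABC".index(a), "ABC".index(b)
        assert v == pytest.approx(D[i, j], abs=1e-12)


def test_nj_star_tree_zero_internal_branches():
    D = np.full((4, 4), 2.0)
    np.fill_diagonal(D, 0.0)
    tree, _ = nj_tree(D, ids=list("ABCD"))
    for (a, b), v in tree_distance_table(tree).items():
        assert v == pytest.approx(2.0, abs=1e-12)


# -- Newick I/O --------------------------------------------------------------

def test_newick_round_trip_simple(tmp_path):
    D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree, _ = nj_tree(D, ids=["A", "B", "C"])
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert tree_distance_table(back) == tree_distance_table(tree)


def test_newick_quotes_labels_with_spaces(tmp_path):
    ids = ["taxon one", "taxon two", "t3"]
    D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree, _ = nj_tree(D, ids=ids)
    path = tmp_path / "q.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    labels = {l.taxon.label for l in back.leaf_node_iter()}
    assert labels == set(ids)


def random_additive(ntax, rng):
    nodes = list(range(ntax))
    adj = {i: [] for i in range(ntax)}
    nxt = ntax
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[i], nodes[j]
        c = nxt
        nxt += 1
        adj[c] = []
        for x in (a, b):
            w = float(rng.uniform(0.05, 2.0))
            adj[c].append((x, w))
            adj[x].append((c, w))
        nodes = [n for n in nodes if n not in (a, b)] + [c]
    D = np.zeros((ntax, ntax))
    for s in range(ntax):
        dist = {s: 0.0}
        q = collections.deque([s])
        while q:
            u = q.popleft()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    q.append(v)
        for t in range(ntax):
            D[s, t] = dist[t]
    return D


def test_fifty_leaf_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    D = random_additive(50, rng)
    ids = [f"leaf_{i}" for i in range(50)]
    tree, _ = nj_tree(D, ids=ids)
    path = tmp_path / "big.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    t1, t2 = tree_distance_table(tree), tree_distance_table(back)
    assert set(t1) == set(t2)
    for k in t1:
        assert t1[k] == pytest.approx(t2[k], abs=1e-9)


# -- gene haplotypes ---------------------------------------------------------

def gene_feature(nv):
    return {"chrom": "chr1", "start": 1, "end": nv * 100 + 1, "gene_id": "g1"}


def test_homozygous_samples_have_identical_haplotype_pairs(matrix_factory):
    g = np.array([[0, 2, 0], [2, 0, 2]], dtype=np.int8)
    m = matrix_factory(g)
    groups, seqs = extract_gene_haplotypes(m, gene_feature(3))
    assert seqs["s0|1"] == seqs["s0|2"]
    assert all(g.count % 2 == 0 for g in groups)


def test_identical_samples_share_group(matrix_factory):
    g = np.array([[0, 2, 1], [0, 2, 1], [2, 0, 0]], dtype=np.int8)
    m = matrix_factory(g)
    groups, seqs = extract_gene_haplotypes(m, gene_feature(3))
    by_seq = {}
    for gid, s in seqs.items():
        by_seq.setdefault(s, []).append(gid)
    assert sorted(by_seq[seqs["s0|1"]]) >= ["s0|1", "s1|1"]


def test_planted_haplotype_frequencies_rank(matrix_factory):
    # 10 homozygous samples: 6 of hap A, 3 of hap B, 1 of hap C
    hapA = [0, 0, 0, 0]
    hapB = [2, 2, 0, 0]
    hapC = [2, 2, 2, 2]
    g = np.array([hapA] * 6 + [hapB] * 3 + [hapC], dtype=np.int8)
    m = matrix_factory(g)
    groups, _ = extract_gene_haplotypes(m, gene_feature(4))
    assert [grp.count for grp in groups[:3]] == [12, 6, 2]
    assert [grp.rank for grp in groups[:3]] == [1, 2, 3]


# -- p-distance --------------------------------------------------------------

def test_p_distance_cases():
    assert p_distance("ACGT", "ACGT") == 0.0
    assert p_distance("AAAA", "AAAT") == 0.25
    assert p_distance("AA?A", "ATAA") == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        p_distance("????", "AAAA")


# -- segregating haplotype rules --------------------------------------------

def detection_fixture(matrix_factory):
    # doms d1,d2 (D1) share the background haplotype; d3 (D2) and d4 (D3)
    # share a divergent haplotype that sits with wild w3
    background = [0] * 10
    divergent = [2] * 8 + [0, 0]
    w1 = [0] * 8 + [2, 0]
    w2 = [0] * 9 + [2]
    w3 = [2] * 8 + [2, 2]
    g = np.array([background, background, divergent, divergent, w1, w2, w3],
                 dtype=np.int8)
    ids = ["d1", "d2", "d3", "d4", "w1", "w2", "w3"]
    m = matrix_factory(g, samples=ids)
    subpop_of = {"d1": "D1", "d2": "D1", "d3": "D2", "d4": "D3",
                 "w1": "W1", "w2": "W2", "w3": "W3"}
    species_of = {k: ("dom" if k.startswith("d") else "wild") for k in ids}
    genome_tree, _ = nj_tree(distance_matrix(m))
    groups, seqs = extract_gene_haplotypes(m, gene_feature(10),
                                           subpop_of=subpop_of)
    gene_tree, _ = p_distance_tree(seqs)
    return gene_tree, genome_tree, groups, subpop_of, species_of


def test_mixed_subpop_divergent_clade_not_flagged(matrix_factory):
    gene_tree, genome_tree, groups, subpop_of, species_of = detection_fixture(
        matrix_factory
    )
    det = detect_segregating_haplotypes(gene_tree, genome_tree, groups,
                                        subpop_of, species_of)
    assert not det["flagged"].any()
    divergent_rows = det[(det["single_subpop"] == False)  # noqa: E712
                         & (det["count"] == 4)]
    assert len(divergent_rows) >= 1


def test_single_dom_clade_no_flags(matrix_factory):
    # all domesticates identical -> one clade, nothing outside it
    g = np.array([[0] * 6] * 4 + [[2] * 6, [0, 2] * 3], dtype=np.int8)
    ids = ["d1", "d2", "d3", "d4", "w1", "w2"]
    m = matrix_factory(g, samples=ids)
    subpop_of = {"d1": "D1", "d2": "D1", "d3": "D2", "d4": "D2",
                 "w1": "W1", "w2": "W2"}
    species_of = {k: ("dom" if k.startswith("d") else "wild") for k in ids}
    genome_tree, _ = nj_tree(distance_matrix(m))
    groups, seqs = extract_gene_haplotypes(m, gene_feature(6),
                                           subpop_of=subpop_of)
    gene_tree, _ = p_distance_tree(seqs)
    det = detect_segregating_haplotypes(gene_tree, genome_tree, groups,
                                        subpop_of, species_of)
    assert not det["flagged"].any()
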
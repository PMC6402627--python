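"""Genome distances, neighbour-joining trees and gene haplotypes.

The whole-genome divergence between two diploid samples is the average,
over sites called in both, of one minus half the best pairing of allele
identities between the two genotypes -- equivalently |g_x - g_y| / 2 on
0/1/2 codes. Neighbour joining (Saitou & Nei, with the Studier-Keppler
update) is authored here so that additive matrices are inverted exactly;
trees are returned as dendropy objects, which also provide Newick I/O.

Gene haplotypes are extracted over a feature interval plus flanks with a
declared naive phasing rule: homozygous sites feed both haplotypes, and at
heterozygous sites the reference allele goes to haplotype 1. With the low
heterozygosity of predominant selfers the distortion this introduces is
small, and it is measured against simulation truth in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .variantio import MISSING, GenotypeMatrix

Tree = dendropy.Tree


@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray  # symmetric, zero diagonal
    n_sites: np.ndarray | None = None  # per-pair compared-site count L

    def validate(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("nonzero diagonal")


def genome_distance(g_x: np.ndarray, g_y: np.ndarray) -> tuple[float, int]:
    """Pairwise genomic divergence between two diploid genotype vectors.

    Per shared called site the contribution is 1 - max-matching/2 of the
    two allele pairs, which reduces to |g_x - g_y| / 2 for codes 0/1/2.
    Returns (distance, L) with L the number of compared sites.
    """
    g_x, g_y = np.asarray(g_x), np.asarray(g_y)
    ok = (g_x != MISSING) & (g_y != MISSING)
    L = int(ok.sum())
    if L == 0:
        raise ValueError("no sites called in both samples")
    d = float(np.abs(g_x[ok].astype(np.int16) - g_y[ok]).sum() / (2.0 * L))
    return d, L


def distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs genome distances (vectorized over sample pairs)."""
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    g = matrix.genotypes.astype(np.int16)
    called = g != MISSING
    n = matrix.n_samples
    d = np.zeros((n, n))
    L = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        shared = called[i] & called[i + 1 :]
        diff = np.abs(g[i] - g[i + 1 :]) * shared
        Li = shared.sum(axis=1)
        if np.any(Li == 0):
            raise ValueError("a sample pair shares no called sites")
        row = diff.sum(axis=1) / (2.0 * Li)
        d[i, i + 1 :] = d[i + 1 :, i] = row
        L[i, i + 1 :] = L[i + 1 :, i] = Li
    out = DistanceMatrix(list(matrix.samples), d, L)
    out.validate()
    return out


@dataclass
class _Node:
    label: str | None
    children: list = field(default_factory=list)  # (child, branch length)


def nj_tree(D: DistanceMatrix | np.ndarray, ids=None,
            clamp_negative: bool = True) -> tuple[Tree, int]:
    """Saitou-Nei neighbour joining.

    Returns an unrooted dendropy tree (trifurcating seed node) and the
    number of negative branch-length estimates clamped to zero. Additive
    distance matrices are recovered exactly (topology and lengths).
    """
    if isinstance(D, DistanceMatrix):
        ids, d = list(D.ids), D.values.astype(float).copy()
    else:
        d = np.asarray(D, float).copy()
        ids = [f"t{i}" for i in range(d.shape[0])] if ids is None else list(ids)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [_Node(label) for label in ids]
    active = list(range(n))
    lengths: list[float] = []

    def join(i, j):  # i, j are positions in `active`
        a, b = active[i], active[j]
        m = len(active)
        r = d[np.ix_(active, active)].sum(axis=1)
        li = 0.5 * d[a, b] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[a, b] - li
        parent = _Node(None, [(nodes[a], li), (nodes[b], lj)])
        lengths.extend([li, lj])
        # Studier-Keppler distance update
        new_col = 0.5 * (d[a, active] + d[b, active] - d[a, b])
        nodes.append(parent)
        d_new = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0]
        d_new[k, active] = d_new[active, k] = new_col
        d_new[k, k] = 0.0
        return parent, k, d_new

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        _, k, d = join(i, j)
        active = [x for idx, x in enumerate(active) if idx not in (i, j)] + [k]

    a, b, c = active
    # three-point formulas for the final unrooted join
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = _Node(None, [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    lengths.extend([la, lb, lc])

    n_clamped = sum(1 for x in lengths if x < -1e-12)
    newick = _to_newick(root, clamp_negative) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree, (n_clamped if clamp_negative else 0)


def _to_newick(node: _Node, clamp: bool) -> str:
    if not node.children:
        label = node.label or ""
        return f"'{label}'" if any(ch in label for ch in " ()[]:;,") else label
    parts = []
    for child, length in node.children:
        if clamp and length < 0:
            length = 0.0
        parts.append(f"{_to_newick(child, clamp)}:{length:.12g}")
    return "(" + ",".join(parts) + ")"


def write_newick(tree: Tree, path) -> None:
    # preserve_spaces keeps space-holding labels quoted instead of
    # rewriting the spaces as underscores
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               preserve_spaces=True)


def read_newick(path) -> Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def tree_distance_table(tree: Tree) -> dict:
    """Patristic distances between all leaf pairs, keyed by label pair."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            v = pdm.patristic_distance(ta, tb)
            out[(ta.label, tb.label)] = v
            out[(tb.label, ta.label)] = v
    return out


@dataclass
class HaplotypeGroup:
    gene_id: str
    haplotype: str
    members: list  # haplotype sequence ids, two per sample
    count: int
    rank: int
    subpop_composition: dict


def extract_gene_haplotypes(
    matrix: GenotypeMatrix,
    feature,
    flank_bp: int = 5000,
    subpop_of: dict | None = None,
) -> tuple[list, dict]:
    """Per-sample haplotype strings over a gene interval with flanks.

    Returns (groups ranked by descending count, sequences dict id->string).
    Sequence ids are '<sample>|1' and '<sample>|2'; missing genotypes
    appear as '?'. Group counts sum to twice the sample count.
    """
    chrom, start, end = feature["chrom"], int(feature["start"]), int(feature["end"])
    sel = (
        (matrix.chrom == chrom)
        & (matrix.pos >= start - flank_bp)
        & (matrix.pos <= end + flank_bp)
    )
    idx = np.flatnonzero(sel)
    sequences = {}
    for s, sample in enumerate(matrix.samples):
        h1, h2 = [], []
        for j in idx:
            g = matrix.genotypes[s, j]
            if g == MISSING:
                h1.append("?")
                h2.append("?")
            elif g == 0:
                h1.append(matrix.ref[j])
                h2.append(matrix.ref[j])
            elif g == 2:
                h1.append(matrix.alt[j])
                h2.append(matrix.alt[j])
            else:  # naive phasing: ref allele to haplotype 1
                h1.append(matrix.ref[j])
                h2.append(matrix.alt[j])
        sequences[f"{sample}|1"] = "".join(h1)
        sequences[f"{sample}|2"] = "".join(h2)
    gene_id = feature.get("gene_id", f"{chrom}:{start}-{end}") if hasattr(feature, "get") else (
        f"{chrom}:{start}-{end}"
    )
    groups: dict[str, list] = {}
    for sid, seq in sequences.items():
        groups.setdefault(seq, []).append(sid)
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    out = []
    for rank, (seq, members) in enumerate(ranked, start=1):
        comp: dict[str, int] = {}
        if subpop_of:
            for sid in members:
                sp = subpop_of.get(sid.rsplit("|", 1)[0], "?")
                comp[sp] = comp.get(sp, 0) + 1
        out.append(HaplotypeGroup(gene_id, seq, sorted(members), len(members), rank, comp))
    return out, sequences


def p_distance(seq_a: str, seq_b: str, ambiguous="?N-") -> float:
    """Proportion of differing sites with pairwise deletion of positions
    ambiguous in either sequence."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    bad = np.isin(a, [c.encode() for c in ambiguous]) | np.isin(
        b, [c.encode() for c in ambiguous]
    )
    ok = ~bad
    if not ok.any():
        raise ValueError("no comparable sites for a sequence pair")
    return float((a[ok] != b[ok]).mean())


def p_distance_matrix(sequences: dict) -> DistanceMatrix:
    ids = list(sequences)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(sequences[ids[i]], sequences[ids[j]])
    out = DistanceMatrix(ids, d)
    out.validate()
    return out


def p_distance_tree(sequences: dict) -> tuple[Tree, int]:
    """NJ tree on pairwise p-distances of aligned haplotype sequences."""
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    return nj_tree(p_distance_matrix(sequences))


def _bipartitions(tree: Tree):
    """Yield (edge, leaf-label frozenset on the child side) for internal edges."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        labels = frozenset(
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        )
        yield edge, labels


def major_clade_leaves(tree: Tree, is_target: dict) -> frozenset:
    """Leaf set of the clade best separating target from non-target leaves.

    Scans all bipartitions of the unrooted tree and maximizes the Youden
    index (target recall minus non-target contamination), requiring the
    chosen side to hold at least half the target leaves; deterministic
    tie-break by first encounter in preorder.
    """
    all_leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    targets = {x for x in all_leaves if is_target.get(x)}
    others = set(all_leaves) - targets
    if not targets:
        raise ValueError("no target leaves")
    best, best_j = frozenset(all_leaves), -math.inf
    for _, side in _bipartitions(tree):
        for labels in (side, frozenset(all_leaves) - side):
            tpr = len(labels & targets) / len(targets)
            fpr = len(labels & others) / len(others) if others else 0.0
            j = tpr - fpr
            if tpr >= 0.5 and j > best_j:
                best, best_j = labels, j
    return best


def wild_sister_subpop(genome_tree: Tree, species_of: dict, subpop_of: dict) -> str:
    """Subpopulation of the wild accession closest (mean patristic distance)
    to the domesticated samples on the genome tree."""
    pdm = genome_tree.phylogenetic_distance_matrix()
    taxa = list(genome_tree.taxon_namespace)
    dom = [t for t in taxa if species_of.get(t.label) == "dom"]
    wild = [t for t in taxa if species_of.get(t.label) == "wild"]
    if not dom or not wild:
        raise ValueError("need both domesticated and wild leaves")
    means = {
        w: np.mean([pdm.patristic_distance(w, t) for t in dom]) for w in wild
    }
    closest = min(wild, key=lambda w: (means[w], w.label))
    return subpop_of[closest.label]


def detect_segregating_haplotypes(
    gene_tree: Tree,
    genome_tree: Tree,
    groups: list,
    subpop_of: dict,
    species_of: dict,
    top_n: int = 5,
) -> pd.DataFrame:
    """Flag top haplotype groups consistent with a divergent, geographically
    restricted gene history.

    A group among the ``top_n`` most common is flagged iff (i) all its
    domesticated members come from a single subpopulation, (ii) none of its
    member leaves lie inside the gene tree's major domesticated clade, and
    (iii) its nearest wild neighbour on the gene tree belongs to a
    different wild subpopulation than the genome tree's wild sister group
    of the domesticates.
    """
    sample_of = lambda sid: sid.rsplit("|", 1)[0]
    leaf_labels = {leaf.taxon.label for leaf in gene_tree.leaf_node_iter()}
    for g in groups[:top_n]:
        for m in g.members:
            if m not in leaf_labels:
                raise ValueError(f"leaf {m!r} missing from gene tree")
    for sid in leaf_labels:
        if sample_of(sid) not in subpop_of or sample_of(sid) not in species_of:
            raise ValueError(f"unlabeled leaf {sid!r}")
    is_dom = {lab: species_of[sample_of(lab)] == "dom" for lab in leaf_labels}
    major = major_clade_leaves(gene_tree, is_dom)
    sister = wild_sister_subpop(genome_tree, species_of, subpop_of)
    pdm = gene_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in gene_tree.taxon_namespace}
    wild_leaves = [lab for lab in leaf_labels if not is_dom[lab]]
    rows = []
    for g in groups[:top_n]:
        dom_members = [m for m in g.members if is_dom[m]]
        dom_subpops = {subpop_of[sample_of(m)] for m in dom_members}
        single_subpop = len(dom_subpops) == 1
        outside_major = all(m not in major for m in g.members)
        nearest_wild, nearest_subpop = None, None
        if dom_members:
            best = (math.inf, None)
            for w in wild_leaves:
                dmin = min(pdm.patristic_distance(taxa[w], taxa[m]) for m in dom_members)
                if (dmin, w) < best:
                    best = (dmin, w)
            nearest_wild = best[1]
            nearest_subpop = subpop_of[sample_of(nearest_wild)] if nearest_wild else None
        flagged = bool(
            dom_members
            and single_subpop
            and outside_major
            and nearest_subpop is not None
            and nearest_subpop != sister
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "rank": g.rank,
                "count": g.count,
                "dom_subpop": next(iter(dom_subpops)) if single_subpop and dom_subpops else "",
                "single_subpop": single_subpop,
                "outside_major_clade": outside_major,
                "nearest_wild_subpop": nearest_subpop or "",
                "genome_sister_subpop": sister,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
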
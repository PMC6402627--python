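#!/usr/bin/env python
"""Genome tree and gene-haplotype trees with segregating-haplotype flags.

Writes the whole-genome neighbour-joining tree (Newick), a table of the
five most common haplotypes per candidate gene with their subpopulation
composition, and the per-gene detection table flagging haplotypes whose
history is divergent and geographically restricted.
"""
import pandas as pd

from _common import DATA, RESULTS, ROOT, load_matrix, load_samples, save
from oryzapop.phylo import (
    detect_segregating_haplotypes,
    distance_matrix,
    extract_gene_haplotypes,
    nj_tree,
    p_distance_tree,
    write_newick,
)
from oryzapop.simdata import read_gff3
from oryzapop.variantio import MISSING


def main():
    matrix, _ = load_matrix()
    samples = load_samples()
    subpop_of = dict(zip(samples["id"], samples["subpop"]))
    species_of = dict(zip(samples["id"], samples["species"]))

    genome_tree, clamped = nj_tree(distance_matrix(matrix))
    RESULTS.mkdir(parents=True, exist_ok=True)
    tree_path = RESULTS / "genome_tree.nwk"
    write_newick(genome_tree, tree_path)
    print(f"wrote {tree_path.relative_to(ROOT)} ({clamped} branches clamped)")

    # naive phasing groups haplotypes by exact string identity, so restrict
    # the gene analysis to fully called sites ('?' would split every group)
    complete = matrix.take_variants(
        (matrix.genotypes != MISSING).all(axis=0)
    )
    print(f"gene haplotypes use {complete.n_variants} fully called sites")

    features = read_gff3(DATA / "features.gff3")
    hap_rows, det_rows = [], []
    for _, feat in features.iterrows():
        groups, seqs = extract_gene_haplotypes(complete, feat,
                                               subpop_of=subpop_of)
        for g in groups[:5]:
            hap_rows.append(
                {"gene_id": g.gene_id, "rank": g.rank, "count": g.count,
                 "composition": ";".join(
                     f"{k}:{v}" for k, v in sorted(g.subpop_composition.items())
                 )}
            )
        gene_tree, _ = p_distance_tree(seqs)
        det = detect_segregating_haplotypes(gene_tree, genome_tree, groups,
                                            subpop_of, species_of)
        det_rows.append(det)
    save(pd.DataFrame(hap_rows), "phylo_gene_haplotypes.csv")
    det_all = pd.concat(det_rows, ignore_index=True)
    save(det_all, "phylo_segregating_haplotypes.csv")
    flagged = det_all[det_all["flagged"]]
    if len(flagged):
        print(flagged.to_string(index=False))
    else:
        print("no segregating haplotypes flagged")


if __name__ == "__main__":
    main()
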
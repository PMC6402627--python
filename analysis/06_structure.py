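#!/usr/bin/env python
"""Population structure, geographic differentiation and kinship.

Writes PCA scores on the LD-pruned call set, PC-geography correlations,
ancestry-based subpopulation assignments, F_ST contrasts (species and
geographic clines on balanced subsamples), and the kinship-distance
regression per species group.
"""
import pandas as pd

from _common import DATA, load_matrix, load_samples, save
from oryzapop.structure import (
    assign_subpops,
    cline_and_balance,
    fst,
    ibd_regression,
    kinship_pairs,
    ld_prune,
    pc_geo_correlation,
    pca,
)


def main():
    matrix, _ = load_matrix()
    samples = load_samples().set_index("id").loc[list(matrix.samples)].reset_index()

    kept = ld_prune(matrix, r2_threshold=0.25, window_snps=500, step_snps=50)
    print(f"LD pruning kept {len(kept)} of {matrix.n_variants} SNPs")
    pruned = matrix.take_variants(kept)

    res = pca(pruned, k=20)
    scores = pd.DataFrame(
        res.scores, columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])]
    )
    scores.insert(0, "sample", matrix.samples)
    save(scores, "structure_pca_scores.csv")

    geo = pc_geo_correlation(res.scores,
                             samples["lat"].to_numpy(),
                             samples["lon"].to_numpy())
    save(geo, "structure_pc_geography.csv")

    qmatrix = pd.read_csv(DATA / "qmatrix.tsv", sep="\t")
    labels = assign_subpops(qmatrix)
    assigned = labels.rename("assigned").reset_index()
    assigned = assigned.merge(samples[["id", "subpop"]],
                              left_on="sample", right_on="id").drop(columns="id")
    save(assigned, "structure_assignments.csv")
    agree = (assigned["assigned"] == assigned["subpop"]).mean()
    print(f"ancestry assignment agrees with simulated subpop for {agree:.0%}")

    rows = []
    dom_ids = list(samples[samples["species"] == "dom"]["id"])
    wild_ids = list(samples[samples["species"] == "wild"]["id"])
    r = fst(matrix, dom_ids, wild_ids, labels=("cultivated", "wild"))
    rows.append({"contrast": "cultivated_vs_wild", "fst": r.weighted,
                 "classification": r.classification})
    clined, subsets = cline_and_balance(samples, n_per_group=15)
    for col, names in (("ns_group", ("north", "south")),
                       ("ew_group", ("east", "west"))):
        balanced = [i for ids in subsets.values() for i in ids]
        sub = clined[clined["id"].isin(balanced)]
        a = list(sub[sub[col] == names[0]]["id"])
        b = list(sub[sub[col] == names[1]]["id"])
        if a and b:
            r = fst(matrix, a, b, labels=names)
            rows.append({"contrast": f"{names[0]}_vs_{names[1]}",
                         "fst": r.weighted,
                         "classification": r.classification})
    save(pd.DataFrame(rows), "structure_fst.csv")
    print(pd.DataFrame(rows).to_string(index=False))

    fits = []
    for sp, ids in (("wild", wild_ids), ("dom", dom_ids)):
        pairs = kinship_pairs(matrix, samples, sample_ids=ids, group=sp)
        fit = ibd_regression(pairs)
        fits.append({"species": sp, "slope_per_km": fit.slope,
                     "intercept": fit.intercept, "r": fit.r,
                     "n_pairs": fit.n_used, "n_excluded": fit.n_excluded})
    save(pd.DataFrame(fits), "structure_ibd.csv")
    print(pd.DataFrame(fits).to_string(index=False))


if __name__ == "__main__":
    main()
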
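#!/usr/bin/env python
"""Outgroup polarization and the unfolded site frequency spectrum.

Writes the polarization discard tally, the observed derived-allele
spectrum of synonymous + noncoding sites per species group, the neutral
expectation, the ECDF comparison with its KS test, and the percent
excess of high-frequency derived variants in (0.7, 1.0].
"""
import numpy as np
import pandas as pd

from _common import DATA, load_matrix, load_samples, save
from oryzapop.sfs import (
    daf_spectrum,
    ecdf_ks_compare,
    excess_above_expectation,
    expected_neutral_sfs,
    polarize,
    read_outgroup_map,
)


def main():
    matrix, _ = load_matrix()
    samples = load_samples()
    outgroup = read_outgroup_map(DATA / "outgroup_map.tsv")
    # align the map to the filtered call set by position
    key = pd.MultiIndex.from_arrays([matrix.chrom, matrix.pos])
    outgroup = (
        outgroup.set_index(["chrom", "pos"]).loc[key].reset_index()
    )
    polarized, tally = polarize(matrix, outgroup)
    save(
        pd.DataFrame(sorted(tally.items()), columns=["reason", "count"]),
        "sfs_polarization_tally.csv",
    )
    print(f"polarized {tally['none']} of {matrix.n_variants} variants")

    sample_pos = {s: i for i, s in enumerate(matrix.samples)}
    specs, curves, summaries = [], [], []
    for sp in ("wild", "dom"):
        idx = np.array(
            [sample_pos[i] for i in samples[samples["species"] == sp]["id"]]
        )
        spec = daf_spectrum(matrix, polarized, sample_index=idx)
        expected = expected_neutral_sfs(int(spec["count"].sum()), 2 * len(idx))
        curve, ks, p = ecdf_ks_compare(spec, expected)
        excess = excess_above_expectation(spec, expected)
        for tag, table in (("observed", spec), ("expected", expected)):
            t = table.copy()
            t.insert(0, "species", sp)
            t.insert(1, "kind", tag)
            specs.append(t)
        curve.insert(0, "species", sp)
        curves.append(curve)
        summaries.append(
            {"species": sp, "n_sites": spec.attrs["total"],
             "ks_statistic": ks, "ks_p": p,
             "frac_in_0.7_1.0": spec.attrs["frac_in_0.7_1.0"],
             "frac_gt_0.95": spec.attrs["frac_gt_0.95"],
             "frac_gt_0.99": spec.attrs["frac_gt_0.99"],
             "excess_pct_0.7_1.0": excess}
        )
        print(f"{sp}: KS={ks:.4f} p={p:.3g} excess={excess:.2f}%")
    save(pd.concat(specs, ignore_index=True), "sfs_spectra.csv")
    save(pd.concat(curves, ignore_index=True), "sfs_ecdf.csv")
    save(pd.DataFrame(summaries), "sfs_summary.csv")


if __name__ == "__main__":
    main()
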
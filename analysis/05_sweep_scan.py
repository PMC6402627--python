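#!/usr/bin/env python
"""LD-based selective sweep scan on the cultivated samples.

Writes the omega scan grid with top-0.5% outlier flags, nearby candidate
genes (< 25 kb from a flagged point, containing moderate/high impact
variants), and the cross-check of omega against overlapping 25 kb
windows of pi and Tajima's D.
"""
import numpy as np

from _common import DATA, load_matrix, load_samples, save
from oryzapop.diversity import windowed_scan
from oryzapop.simdata import read_gff3
from oryzapop.sweep import (
    call_outliers,
    feature_proximity,
    neutrality_cross_check,
    omega_scan,
    variant_impacts,
)


def main():
    matrix, _ = load_matrix()
    samples = load_samples()
    sample_pos = {s: i for i, s in enumerate(matrix.samples)}
    dom = np.array(
        [sample_pos[i] for i in samples[samples["species"] == "dom"]["id"]]
    )

    scan = omega_scan(matrix, grid_spacing=5_000, max_window_bp=100_000,
                      max_sites=150, sample_index=dom)
    scan = call_outliers(scan, quantile=0.005)
    n_out = int(scan["outlier"].sum())
    print(f"{n_out} of {len(scan)} grid points flagged")

    features = read_gff3(DATA / "features.gff3")
    near = feature_proximity(scan, features, variants=variant_impacts(matrix))
    save(near, "sweep_candidate_genes.csv")

    pi_w = windowed_scan(matrix, "pi", window_bp=25_000, step_bp=12_500,
                         sample_index=dom)
    d_w = windowed_scan(matrix, "tajima_d", window_bp=25_000, step_bp=12_500,
                        sample_index=dom)
    checked = neutrality_cross_check(scan, pi_w, d_w)
    save(checked, "sweep_scan.csv")

    top = checked[checked["outlier"]].nlargest(10, "omega")
    cols = ["chrom", "pos", "omega", "log10_omega", "pi", "tajima_d"]
    print(top[cols].to_string(index=False))


if __name__ == "__main__":
    main()
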
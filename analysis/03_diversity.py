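#!/usr/bin/env python
"""Windowed diversity statistics and wild/cultivated contrasts.

Writes 100 kb windows of pi, Watterson's theta, Tajima's D and SNP
density for each species group, the per-window and genome-wide
pi_wild / pi_cultivated ratios with a Kruskal-Wallis comparison, and the
minor-allele-frequency spectrum per group.
"""
import numpy as np
import pandas as pd

from _common import load_matrix, load_samples, save
from oryzapop.diversity import kruskal_compare, maf_spectrum, pi_ratio, windowed_scan


def main():
    matrix, _ = load_matrix()
    samples = load_samples()
    sample_pos = {s: i for i, s in enumerate(matrix.samples)}
    groups = {
        sp: np.array([sample_pos[i] for i in samples[samples["species"] == sp]["id"]])
        for sp in ("wild", "dom")
    }

    windows = {}
    rows = []
    for sp, idx in groups.items():
        for stat in ("pi", "theta_w", "tajima_d", "snp_density"):
            w = windowed_scan(matrix, stat, window_bp=100_000, sample_index=idx)
            w.insert(0, "species", sp)
            w.insert(1, "statistic", stat)
            rows.append(w)
            windows[sp, stat] = w
    save(pd.concat(rows, ignore_index=True), "diversity_windows.csv")

    per_window, genome_wide = pi_ratio(windows["wild", "pi"],
                                       windows["dom", "pi"])
    save(per_window, "diversity_pi_ratio_windows.csv")

    h, p = kruskal_compare(windows["wild", "pi"]["value"],
                           windows["dom", "pi"]["value"])
    save(
        pd.DataFrame(
            [{"genome_wide_pi_ratio_wild_over_cultivated": genome_wide,
              "kruskal_H": h, "kruskal_p": p}]
        ),
        "diversity_summary.csv",
    )
    print(f"pi_wild/pi_cultivated = {genome_wide:.3f}  (H={h:.2f}, p={p:.3g})")

    mafs = []
    for sp, idx in groups.items():
        spec = maf_spectrum(matrix.genotypes[idx])
        spec.insert(0, "species", sp)
        mafs.append(spec)
    save(pd.concat(mafs, ignore_index=True), "diversity_maf_spectrum.csv")


if __name__ == "__main__":
    main()
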
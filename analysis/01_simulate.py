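#!/usr/bin/env python
"""Simulate the study dataset and write the text bundle to data/.

Scenario: 40 wild samples in 4 demes, 45 cultivated samples in 5 demes,
2 x 500 kb chromosomes, domestication bottleneck with recovery, selfing
rate 0.9, one planted sweep in the cultivated group on chromosome 1 and
one introgressed gene haplotype on chromosome 2 (donated to OG-2 from
the distant wild deme OB-D).
"""
from pathlib import Path

from oryzapop.simdata import (
    Introgression,
    SimConfig,
    Sweep,
    default_features,
    make_outgroup_map,
    simulate_history,
    truth_qmatrix,
    write_bundle,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 11


def main():
    cfg = SimConfig(
        seed=SEED,
        sweeps=[Sweep(chrom=0, position=250_000, target="dom")],
        introgressions=[Introgression(chrom=1, start=200_000, end=212_000)],
    )
    matrix, samples, truth = simulate_history(cfg)
    outgroup_map = make_outgroup_map(
        matrix, truth, unaligned_frac=0.45, gap_frac=0.10, multimap_frac=0.05,
        seed=SEED,
    )
    features = default_features(matrix, n_per_chrom=4, width=4_000)
    # add one candidate gene inside the introgressed interval on chr2
    features.loc[len(features)] = {
        "chrom": "chr2", "start": 202_000, "end": 208_000,
        "gene_id": f"gene{len(features):02d}",
    }
    qmatrix = truth_qmatrix(samples, seed=SEED)
    paths = write_bundle(matrix, samples, truth, ROOT / "data",
                         outgroup_map=outgroup_map, features=features,
                         qmatrix=qmatrix)
    print(f"{matrix.n_variants} variants x {matrix.n_samples} samples")
    for k, p in paths.items():
        print(f"  {k}: {p.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
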
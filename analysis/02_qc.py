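#!/usr/bin/env python
"""Variant and sample quality control.

Writes the Ts:Tv profile along each INFO annotation (used to choose hard
filter thresholds), the removal tally for both filter presets, and
per-sample depth/call-rate/heterozygosity.
"""
import pandas as pd

from _common import load_matrix, save
from oryzapop.variantio import (
    ANNOTATION_NAMES,
    FILTER_PRESETS,
    apply_filters,
    sample_stats,
    tstv_profile,
)


def main():
    matrix, warnings = load_matrix(filtered=False)
    print(f"parsed {matrix.n_variants} biallelic SNPs; skipped: {warnings}")

    profiles = []
    for name in ANNOTATION_NAMES:
        if name in matrix.annotations:
            prof = tstv_profile(matrix, name, n_bins=10)
            prof.insert(0, "annotation", name)
            profiles.append(prof)
    save(pd.concat(profiles, ignore_index=True), "qc_tstv_profile.csv")

    rows = []
    for preset, spec in FILTER_PRESETS.items():
        kept, removed_by = apply_filters(matrix, spec)
        for filt, n in removed_by.items():
            rows.append({"preset": preset, "filter": filt, "removed": n})
        rows.append({"preset": preset, "filter": "(retained)",
                     "removed": kept.n_variants})
    save(pd.DataFrame(rows), "qc_filter_tally.csv")

    # site DP is panel-wide, so no per-sample depths are available here
    save(sample_stats(matrix), "qc_sample_stats.csv")


if __name__ == "__main__":
    main()
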
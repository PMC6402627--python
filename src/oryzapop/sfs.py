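"""Outgroup polarization and derived-allele-frequency spectra.

SNPs are polarized against a per-variant outgroup alignment map: a variant
is usable only when it aligned uniquely to the outgroup, has no gap within
5 bp, and the outgroup base matches one of the two segregating alleles
(the outgroup base is then taken as ancestral). The observed unfolded
spectrum of synonymous and noncoding variants is compared with the neutral
expectation E[count at derived copy i] = theta_W / i, via per-class excess
and a two-sample Kolmogorov-Smirnov test on the binned spectra.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.special

from .diversity import allele_counts, harmonic
from .variantio import GenotypeMatrix

DISCARD_REASONS = ("none", "unaligned", "gap5", "multimap", "outgroup_mismatch")


def polarize(matrix: GenotypeMatrix, outgroup_map: pd.DataFrame
             ) -> tuple[pd.DataFrame, dict]:
    """Assign ancestral/derived states from the outgroup map.

    Returns a per-variant table (chrom, pos, ancestral, derived,
    discard_reason) aligned to the matrix, and a tally that partitions all
    input variants by discard reason.
    """
    key = pd.MultiIndex.from_arrays([matrix.chrom, matrix.pos])
    om = outgroup_map.set_index(["chrom", "pos"]).reindex(key)
    if om["unaligned"].isna().any():
        raise ValueError("outgroup map does not cover all matrix variants")
    allele = om["outgroup_allele"].fillna("").to_numpy(dtype=object)
    reason = np.full(matrix.n_variants, "none", dtype=object)
    reason[(allele != matrix.ref) & (allele != matrix.alt)] = "outgroup_mismatch"
    reason[om["multimap"].to_numpy(bool)] = "multimap"
    reason[om["gap5"].to_numpy(bool)] = "gap5"
    reason[om["unaligned"].to_numpy(bool)] = "unaligned"
    ok = reason == "none"
    ancestral = np.where(ok, allele, "").astype(object)
    derived = np.where(
        ok, np.where(allele == matrix.ref, matrix.alt, matrix.ref), ""
    ).astype(object)
    table = pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "pos": matrix.pos,
            "ancestral": ancestral,
            "derived": derived,
            "discard_reason": reason,
        }
    )
    tally = {r: int((reason == r).sum()) for r in DISCARD_REASONS}
    return table, tally


def derived_frequency(matrix: GenotypeMatrix, polarized: pd.DataFrame,
                      sample_index=None) -> np.ndarray:
    """Derived allele frequency per variant in the given sample subset;
    NaN for discarded variants or variants with no called haplotypes."""
    g = matrix.genotypes if sample_index is None else matrix.genotypes[sample_index]
    alt, m = allele_counts(g)
    derived_is_alt = polarized["derived"].to_numpy(object) == matrix.alt
    # Divide the integer derived count directly: deriving the REF-derived
    # frequency as 1 - alt_freq would put e.g. 1 - 0.95 a few ulp above
    # 0.05 and shift counts across exact bin edges.
    der = np.where(derived_is_alt, alt, m - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(m > 0, der / np.maximum(m, 1), np.nan)
    freq[polarized["discard_reason"].to_numpy(object) != "none"] = np.nan
    return freq


DEFAULT_DAF_EDGES = tuple(np.round(np.linspace(0.0, 1.0, 21), 3))


def daf_spectrum(
    matrix: GenotypeMatrix,
    polarized: pd.DataFrame,
    sample_index=None,
    functional_filter=("synonymous", "noncoding"),
    bin_edges=DEFAULT_DAF_EDGES,
) -> pd.DataFrame:
    """Unfolded spectrum of derived allele frequencies.

    Restricted by default to synonymous + noncoding variants. Bins are
    (low, high] except the first ([0, high]); fixed derived variants
    (frequency 1.0) are retained in the last bin. The result carries the
    report-class counts of interest -- interval (0.7, 1.0], and the
    thresholds > 0.95 and > 0.99 -- as DataFrame attrs (these classes
    overlap; they are not a partition).
    """
    freq = derived_frequency(matrix, polarized, sample_index)
    keep = ~np.isnan(freq)
    keep &= freq > 0  # sites with no derived copies in this subset carry no signal
    if functional_filter is not None and matrix.functional_class is not None:
        keep &= np.isin(matrix.functional_class, list(functional_filter))
    f = freq[keep]
    edges = np.asarray(bin_edges, dtype=float)
    which = np.clip(np.searchsorted(edges, f, side="left") - 1, 0, len(edges) - 2)
    counts = np.bincount(which, minlength=len(edges) - 1)
    out = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
    out.attrs["total"] = int(len(f))
    out.attrs["frac_in_0.7_1.0"] = float((f > 0.7).mean()) if len(f) else math.nan
    out.attrs["frac_gt_0.95"] = float((f > 0.95).mean()) if len(f) else math.nan
    out.attrs["frac_gt_0.99"] = float((f > 0.99).mean()) if len(f) else math.nan
    return out


def expected_neutral_sfs(S_total: int, n_haplotypes: int,
                         bin_edges=DEFAULT_DAF_EDGES) -> pd.DataFrame:
    """Neutral expectation of the unfolded spectrum.

    theta_W = S_total / a1; the expected count at derived copy number i is
    theta_W / i for i = 1..n-1, binned by frequency i/n. Expected counts
    sum to S_total by the harmonic normalization.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    theta = S_total / harmonic(n_haplotypes)
    i = np.arange(1, n_haplotypes)
    expected = theta / i
    f = i / n_haplotypes
    edges = np.asarray(bin_edges, dtype=float)
    which = np.clip(np.searchsorted(edges, f, side="left") - 1, 0, len(edges) - 2)
    counts = np.zeros(len(edges) - 1)
    np.add.at(counts, which, expected)
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})


def ecdf_ks_compare(observed: pd.DataFrame, expected: pd.DataFrame
                    ) -> tuple[pd.DataFrame, float, float]:
    """Two-sample KS comparison of binned spectra.

    ECDFs are evaluated at the bin upper edges; KS is the maximum absolute
    ECDF difference, and the p-value uses the asymptotic two-sample formula
    with effective size n1*n2/(n1+n2) (total counts as sample sizes).
    """
    if not np.allclose(observed["bin_high"], expected["bin_high"]):
        raise ValueError("spectra must share bin edges")
    n1, n2 = observed["count"].sum(), expected["count"].sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("empty spectrum")
    e1 = np.cumsum(observed["count"].to_numpy(float)) / n1
    e2 = np.cumsum(expected["count"].to_numpy(float)) / n2
    diff = e1 - e2
    ks = float(np.abs(diff).max())
    n_eff = n1 * n2 / (n1 + n2)
    p = float(scipy.special.kolmogorov(ks * math.sqrt(n_eff)))
    curve = pd.DataFrame(
        {"bin_high": observed["bin_high"], "ecdf_obs": e1, "ecdf_exp": e2, "diff": diff}
    )
    return curve, ks, min(p, 1.0)


def excess_above_expectation(observed: pd.DataFrame, expected: pd.DataFrame,
                             freq_range=(0.7, 1.0)) -> float:
    """Percent of total observed SNPs lying above the neutral expectation
    within a frequency range: sum of positive per-bin (obs - exp)
    differences over bins inside the range, divided by total observed,
    times 100."""
    lo, hi = freq_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("range must lie within [0, 1]")
    in_range = (observed["bin_low"] >= lo - 1e-12) & (observed["bin_high"] <= hi + 1e-12)
    diff = observed.loc[in_range, "count"].to_numpy(float) - expected.loc[
        in_range, "count"
    ].to_numpy(float)
    total = observed["count"].sum()
    return float(np.clip(diff, 0, None).sum() / total * 100.0) if total else math.nan


def read_outgroup_map(path) -> pd.DataFrame:
    om = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    om["outgroup_allele"] = om["outgroup_allele"].fillna("")
    for col in ("unaligned", "gap5", "multimap"):
        om[col] = om[col].astype(bool)
    return om
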
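"""Diversity and neutrality statistics.

Per-site and windowed nucleotide diversity (pi), Watterson's theta,
Tajima's D, SNP density, the minor-allele-frequency spectrum, and a
rank-based comparison of windowed statistics between groups.

Haplotype counts come from diploid genotypes without phasing: each called
sample contributes two allele copies, a heterozygote one copy of each.
Per-site pi uses the unbiased pairwise form 2*x*(1-x)*m/(m-1), which equals
the mean pairwise difference over all m*(m-1)/2 haplotype pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .variantio import MISSING, GenotypeMatrix


def allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (alt allele copies, called haplotypes) from a samples x
    variants diploid code matrix."""
    called = genotypes != MISSING
    alt = np.where(called, genotypes, 0).sum(axis=0)
    return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)


def per_site_pi(genotypes: np.ndarray) -> np.ndarray:
    """Unbiased per-site pi for each variant column; NaN where fewer than
    two haplotypes are called."""
    alt, m = allele_counts(np.atleast_2d(genotypes))
    with np.errstate(invalid="ignore", divide="ignore"):
        x = alt / m
        pi = 2.0 * x * (1.0 - x) * m / (m - 1.0)
    return np.where(m >= 2, pi, np.nan)


def harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


@dataclass(frozen=True)
class TajimaConstants:
    """Normalizing constants of Tajima's D for n sequences."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("need at least 2 sequences")
        a1 = harmonic(n)
        a2 = harmonic(n, 2)
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        return cls(n, a1, a2, b1, b2, c1, c2, c1 / a1, c2 / (a1**2 + a2))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S / a1 for n haplotypes (total, not per site)."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    return S / harmonic(n)


def tajimas_d(genotypes: np.ndarray, n_haplotypes: int | None = None) -> float:
    """Tajima's D over a window of genotype columns.

    n defaults to twice the sample count; segregating sites are variants
    polymorphic among the called haplotypes. Returns NaN when S = 0.
    """
    g = np.atleast_2d(genotypes)
    n = 2 * g.shape[0] if n_haplotypes is None else n_haplotypes
    alt, m = allele_counts(g)
    seg = (alt > 0) & (alt < m)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    pi_total = float(np.nansum(per_site_pi(g)[seg]))
    k = TajimaConstants.for_n(n)
    theta = S / k.a1
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (pi_total - theta) / math.sqrt(var)


_STATS = ("pi", "theta_w", "tajima_d", "snp_density")


def windowed_scan(
    matrix: GenotypeMatrix,
    statistic: str,
    window_bp: int = 100_000,
    step_bp: int | None = None,
    sample_index: np.ndarray | None = None,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Tile each chromosome from position 1 with (possibly overlapping)
    windows and evaluate one statistic per window.

    pi and theta_w are reported per site using the window width (not the
    covered-site count); snp_density is segregating sites per kb. Partial
    terminal windows are kept.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_STATS}")
    step_bp = window_bp if step_bp is None else step_bp
    if not 1 <= step_bp <= window_bp:
        raise ValueError("require window_bp >= step_bp >= 1")
    g = matrix.genotypes if sample_index is None else matrix.genotypes[sample_index]
    n_hap = 2 * g.shape[0]
    alt, m = allele_counts(g)
    seg = (alt > 0) & (alt < m)
    pi_site = per_site_pi(g)
    rows = []
    for c in dict.fromkeys(matrix.chrom):
        on_c = matrix.chrom == c
        pos = matrix.pos[on_c]
        length = (chrom_lengths or {}).get(c, int(pos.max()) if len(pos) else window_bp)
        start = 1
        while start <= length:
            end = min(start + window_bp - 1, length)
            width = end - start + 1
            sel = on_c & (matrix.pos >= start) & (matrix.pos <= end) & seg
            S = int(sel.sum())
            if statistic == "pi":
                value = float(np.nansum(pi_site[sel])) / width
            elif statistic == "theta_w":
                value = (S / harmonic(n_hap)) / width if n_hap >= 2 else math.nan
            elif statistic == "tajima_d":
                value = tajimas_d(g[:, sel], n_haplotypes=n_hap) if S else math.nan
            else:
                value = S / (width / 1000.0)
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": end,
                    "n_sites": S,
                    "value": value,
                    "partial": width < window_bp,
                }
            )
            if end >= length:
                break
            start += step_bp
    return pd.DataFrame(rows)


def maf_spectrum(
    matrix_or_genotypes, bin_edges=(0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
) -> pd.DataFrame:
    """Minor-allele-frequency spectrum over polymorphic sites.

    Bins are (low, high] except the first, which is [0, high]; MAF 0.5
    falls in the last bin. Monomorphic sites are excluded.
    """
    g = matrix_or_genotypes.genotypes if isinstance(matrix_or_genotypes, GenotypeMatrix) \
        else np.atleast_2d(matrix_or_genotypes)
    alt, m = allele_counts(g)
    ok = (m >= 2) & (alt > 0) & (alt < m)
    x = alt[ok] / m[ok]
    maf = np.minimum(x, 1.0 - x)
    edges = np.asarray(bin_edges, dtype=float)
    which = np.clip(np.searchsorted(edges, maf, side="left") - 1, 0, len(edges) - 2)
    counts = np.bincount(which, minlength=len(edges) - 1)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


def kruskal_compare(values_a, values_b) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value (1 df)."""
    a = np.asarray([v for v in values_a if not math.isnan(v)], dtype=float)
    b = np.asarray([v for v in values_b if not math.isnan(v)], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(a, b)
    return float(h), float(p)


def pi_ratio(wild_windows: pd.DataFrame, cult_windows: pd.DataFrame
             ) -> tuple[pd.DataFrame, float]:
    """Per-window and genome-wide relative diversity pi_wild / pi_cultivated.

    Windows are aligned on (chrom, start, end). The genome-wide ratio is
    the ratio of summed window values; per-window ratios where the
    cultivated value is 0 are reported as NaN rather than infinity.
    """
    keys = ["chrom", "start", "end"]
    merged = wild_windows[keys + ["value"]].merge(
        cult_windows[keys + ["value"]], on=keys, suffixes=("_w", "_c")
    )
    if not len(merged):
        raise ValueError("no aligned windows")
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["ratio"] = np.where(
            merged["value_c"] > 0, merged["value_w"] / merged["value_c"], np.nan
        )
    total_c = merged["value_c"].sum()
    if total_c == 0:
        raise ZeroDivisionError("cultivated diversity is zero genome-wide")
    return merged, float(merged["value_w"].sum() / total_c)
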
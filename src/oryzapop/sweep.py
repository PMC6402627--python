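"""LD-based selective sweep scan.

Pairwise r-squared, the omega statistic (within-flank versus cross-flank
LD contrast, maximized over the split point), a grid scan along each
chromosome, empirical top-quantile outlier calling, and joins of outlier
positions against nearby annotated features and against windowed
diversity statistics.

r-squared follows the Hill & Robertson definition D^2 / (p1 p2 q1 q2) on
phased haplotypes; on unphased diploid genotypes the squared genotype
correlation is used as the standard surrogate, and the mode is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variantio import MISSING, GenotypeMatrix

#: omega is undefined when cross-flank LD sums to zero; it is reported
#: capped at this ceiling with the ``capped`` flag set.
OMEGA_CAP = 1e6


@dataclass(frozen=True)
class LDPair:
    i: int
    j: int
    p1: float
    p2: float
    q1: float
    q2: float
    D: float
    r2: float
    mode: str  # "haplotype" or "genotype"


def r_squared_haplotypes(h_i: np.ndarray, h_j: np.ndarray, i: int = 0, j: int = 1) -> LDPair:
    """Exact r^2 from phased 0/1 haplotype vectors at two sites."""
    h_i, h_j = np.asarray(h_i), np.asarray(h_j)
    ok = (h_i != MISSING) & (h_j != MISSING)
    n = ok.sum()
    if n < 2:
        raise ValueError("need at least 2 shared haplotypes")
    a, b = h_i[ok], h_j[ok]
    p1 = float(a.mean())
    q1 = float(b.mean())
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise ValueError("monomorphic site in the shared sample")
    d = float((a & b).mean() - p1 * q1)
    r2 = d * d / (p1 * (1 - p1) * q1 * (1 - q1))
    return LDPair(i, j, p1, 1 - p1, q1, 1 - q1, d, r2, "haplotype")


def r_squared_genotypes(g_i: np.ndarray, g_j: np.ndarray, i: int = 0, j: int = 1) -> LDPair:
    """Squared genotype correlation surrogate for unphased diploid codes."""
    g_i, g_j = np.asarray(g_i, float), np.asarray(g_j, float)
    ok = (g_i != MISSING) & (g_j != MISSING)
    if ok.sum() < 2:
        raise ValueError("need at least 2 shared called samples")
    a, b = g_i[ok], g_j[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic site in the shared sample")
    r = float(np.corrcoef(a, b)[0, 1])
    p1 = float(a.mean() / 2.0)
    q1 = float(b.mean() / 2.0)
    d = r * math.sqrt(p1 * (1 - p1) * q1 * (1 - q1))  # implied haplotype-scale D
    return LDPair(i, j, p1, 1 - p1, q1, 1 - q1, d, r * r, "genotype")


def r2_matrix(genotypes: np.ndarray, phased: bool = False) -> np.ndarray:
    """All-pairs r^2 for a (samples x sites) genotype block (or a
    haplotypes x sites block when ``phased``). Missing entries are imputed
    to the site mean before correlation; monomorphic sites yield NaN."""
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean, g)
    centered = g - g.mean(axis=0)
    sd = centered.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = centered / sd
        r = normed.T @ normed / g.shape[0]
    r2 = r * r
    r2[sd == 0, :] = np.nan
    r2[:, sd == 0] = np.nan
    np.fill_diagonal(r2, 1.0)
    return r2


def omega_at_split(r2: np.ndarray, l: int) -> tuple[float, bool]:
    """Evaluate omega for the split L = sites[:l], R = sites[l:].

    Returns (omega, capped). omega is the mean within-flank r^2 over the
    mean cross-flank r^2; a zero cross term yields the capped ceiling.
    """
    w = r2.shape[0]
    if w < 3:
        raise ValueError("need at least 3 sites")
    if not 1 <= l < w:
        raise ValueError("split index out of range")
    left_pairs = l * (l - 1) // 2
    right_pairs = (w - l) * (w - l - 1) // 2
    sum_left = float(np.nansum(r2[np.triu_indices(l, k=1)]))
    rblock = r2[l:, l:]
    sum_right = float(np.nansum(rblock[np.triu_indices(w - l, k=1)]))
    sum_cross = float(np.nansum(r2[:l, l:]))
    n_within = left_pairs + right_pairs
    numerator = (sum_left + sum_right) / n_within if n_within else 0.0
    denominator = sum_cross / (l * (w - l))
    if denominator <= 0:
        return OMEGA_CAP, True
    return min(numerator / denominator, OMEGA_CAP), numerator / denominator >= OMEGA_CAP


def max_omega(r2: np.ndarray) -> tuple[float, int, bool]:
    """Maximize omega over all admissible splits; returns (omega, l, capped).

    Uses prefix sums over the r^2 matrix for O(W^2) total work.
    """
    w = r2.shape[0]
    if w < 3:
        raise ValueError("need at least 3 sites")
    m = np.nan_to_num(r2, nan=0.0)
    np.fill_diagonal(m, 0.0)
    best = (-math.inf, 1, False)
    # tri[k] = sum of all pairs (a,b) with a < b <= k
    tri = np.cumsum([m[:k, k].sum() for k in range(w)])
    total_pairs_sum = tri[-1]
    col_prefix = np.cumsum(m, axis=0)  # col_prefix[l-1, b] = sum_{a < l} m[a, b]
    for l in range(1, w):
        sum_left = tri[l - 1]
        cross = float(col_prefix[l - 1, l:].sum())
        sum_right = total_pairs_sum - sum_left - cross
        left_pairs = l * (l - 1) // 2
        right_pairs = (w - l) * (w - l - 1) // 2
        n_within = left_pairs + right_pairs
        if n_within == 0:
            continue
        numerator = (sum_left + sum_right) / n_within
        denom = cross / (l * (w - l))
        if denom <= 0:
            value, capped = OMEGA_CAP, True
        else:
            value, capped = min(numerator / denom, OMEGA_CAP), numerator / denom >= OMEGA_CAP
        if value > best[0]:
            best = (value, l, capped)
    return best


def omega_scan(
    matrix: GenotypeMatrix,
    grid_spacing: int = 10_000,
    max_window_bp: int = 100_000,
    max_sites: int = 200,
    sample_index=None,
    phased_haplotypes: np.ndarray | None = None,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Scan each chromosome on a regular grid.

    At each grid position, the assessment window holds the (at most
    ``max_sites``) segregating sites nearest the position within
    +/- ``max_window_bp``; omega is maximized over the split point.
    Grid points with fewer than 3 usable sites are skipped. Values are
    also reported log10-transformed.
    """
    data = phased_haplotypes if phased_haplotypes is not None else (
        matrix.genotypes if sample_index is None else matrix.genotypes[sample_index]
    )
    mode = "haplotype" if phased_haplotypes is not None else "genotype"
    # keep sites polymorphic among the analysed samples
    arr = np.asarray(data)
    called = arr != MISSING
    mx = np.where(called, arr, -2).max(axis=0)
    mn = np.where(called, arr, 127).min(axis=0)
    poly = (called.sum(axis=0) >= 2) & (mx != mn)
    rows = []
    for c in dict.fromkeys(matrix.chrom):
        on_c = (matrix.chrom == c) & poly
        pos = matrix.pos[on_c]
        block = np.asarray(data)[:, on_c]
        length = (chrom_lengths or {}).get(c, int(matrix.pos[matrix.chrom == c].max())
                                           if (matrix.chrom == c).any() else 0)
        grid_points = list(range(grid_spacing, length + 1, grid_spacing))
        if not grid_points and length > 0:
            # spacing wider than the chromosome: evaluate once at the midpoint
            grid_points = [max(1, length // 2)]
        for grid in grid_points:
            near = np.flatnonzero(np.abs(pos - grid) <= max_window_bp)
            if len(near) > max_sites:
                near = near[np.argsort(np.abs(pos[near] - grid), kind="stable")[:max_sites]]
                near = np.sort(near)
            if len(near) < 3:
                continue
            r2 = r2_matrix(block[:, near], phased=(mode == "haplotype"))
            value, l, capped = max_omega(r2)
            rows.append(
                {
                    "chrom": c,
                    "pos": grid,
                    "W": len(near),
                    "l": l,
                    "omega": value,
                    "log10_omega": math.log10(value) if value > 0 else -math.inf,
                    "capped": capped,
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)


def call_outliers(results: pd.DataFrame, quantile: float = 0.005,
                  column: str = "omega") -> pd.DataFrame:
    """Flag the top ``quantile`` fraction of grid points (ties at the
    threshold all flagged)."""
    if not len(results):
        raise ValueError("no scan results")
    values = results[column].to_numpy(float)
    k = max(int(math.ceil(quantile * len(values))), 1)
    threshold = np.sort(values)[::-1][k - 1]
    out = results.copy()
    out["outlier"] = values >= threshold
    return out


def feature_proximity(
    outliers: pd.DataFrame,
    features: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    impact_classes=("moderate", "high"),
    max_distance: int = 25_000,
) -> pd.DataFrame:
    """Join outlier positions against features within strict < max_distance.

    A feature is reported iff its interval lies closer than ``max_distance``
    bp to some flagged position (distance measured from the interval edge;
    0 when overlapping) and -- when a per-variant impact table (chrom, pos,
    impact) is supplied -- it contains at least one variant of a requested
    impact class.
    """
    flagged = outliers[outliers["outlier"]] if "outlier" in outliers else outliers
    rows = []
    for _, feat in features.iterrows():
        if variants is not None:
            inside = (
                (variants["chrom"] == feat["chrom"])
                & (variants["pos"] >= feat["start"])
                & (variants["pos"] <= feat["end"])
                & variants["impact"].isin(impact_classes)
            )
            if not inside.any():
                continue
        near = flagged[flagged["chrom"] == feat["chrom"]]
        for _, o in near.iterrows():
            if feat["start"] <= o["pos"] <= feat["end"]:
                dist = 0
            else:
                dist = int(min(abs(o["pos"] - feat["start"]), abs(o["pos"] - feat["end"])))
            if dist < max_distance:
                rows.append(
                    {
                        "gene_id": feat["gene_id"],
                        "chrom": feat["chrom"],
                        "start": feat["start"],
                        "end": feat["end"],
                        "outlier_pos": o["pos"],
                        "distance": dist,
                        "omega": o.get("omega", math.nan),
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "outlier_pos", "distance", "omega"]
    )


IMPACT_OF_CLASS = {"nonsynonymous": "moderate", "synonymous": "low", "noncoding": "modifier"}


def variant_impacts(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Map functional classes onto coarse impact categories."""
    if matrix.functional_class is None:
        raise ValueError("matrix carries no functional classes")
    return pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "pos": matrix.pos,
            "impact": [IMPACT_OF_CLASS.get(c, "modifier") for c in matrix.functional_class],
        }
    )


def neutrality_cross_check(
    omega_results: pd.DataFrame, pi_windows: pd.DataFrame, d_windows: pd.DataFrame
) -> pd.DataFrame:
    """Match each omega grid point to every covering window of pi and
    Tajima's D (overlapping windows all match; boundary points match all
    covering windows); missing windows yield NaN."""
    out = omega_results.copy()
    for name, table in (("pi", pi_windows), ("tajima_d", d_windows)):
        vals, n_cov = [], []
        for _, row in out.iterrows():
            cover = table[
                (table["chrom"] == row["chrom"])
                & (table["start"] <= row["pos"])
                & (table["end"] >= row["pos"])
            ]
            vals.append(cover["value"].mean() if len(cover) else math.nan)
            n_cov.append(len(cover))
        out[name] = vals
        out[f"n_{name}_windows"] = n_cov
    return out
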
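"""Population structure and geography.

LD pruning, principal component analysis with geographic correlation,
subpopulation assignment from ancestry fractions, the Wright variance form
of F_ST (with an optional Weir-Cockerham mode), latitude/longitude cline
splits with balanced subsampling, KING-robust pairwise kinship, Haversine
great-circle distances and isolation-by-distance regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .sweep import r2_matrix
from .variantio import MISSING, GenotypeMatrix


def ld_prune(
    matrix_or_genotypes,
    r2_threshold: float = 0.25,
    window_snps: int = 500,
    step_snps: int = 50,
    chrom: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained variant indices.

    Within each window (advanced by ``step_snps`` and never spanning
    chromosomes) the later member of any retained pair with r^2 above the
    threshold is removed. Re-application leaves the retained set unchanged.
    """
    if window_snps < step_snps:
        raise ValueError("window_snps must be >= step_snps")
    if isinstance(matrix_or_genotypes, GenotypeMatrix):
        g = matrix_or_genotypes.genotypes
        chrom = matrix_or_genotypes.chrom
    else:
        g = np.asarray(matrix_or_genotypes)
        chrom = np.zeros(g.shape[1]) if chrom is None else np.asarray(chrom)
    retained = np.arange(g.shape[1])
    # removing SNPs shifts later windows, so sweep until a fixpoint: the
    # returned set is then stable under re-application
    while True:
        kept = _prune_pass(g, chrom, retained, r2_threshold, window_snps, step_snps)
        if len(kept) == len(retained):
            return retained
        retained = kept


def _prune_pass(g, chrom, idx, r2_threshold, window_snps, step_snps) -> np.ndarray:
    keep = np.ones(len(idx), dtype=bool)
    for c in dict.fromkeys(chrom[idx]):
        where = np.flatnonzero(chrom[idx] == c)
        start = 0
        while start < len(where):
            window = where[start : start + window_snps]
            live = window[keep[window]]
            if len(live) > 1:
                r2 = np.nan_to_num(r2_matrix(g[:, idx[live]]), nan=0.0)
                for b in range(1, len(live)):
                    if not keep[live[b]]:
                        continue
                    earlier_rows = np.flatnonzero(keep[live[:b]])
                    if len(earlier_rows) and np.any(r2[earlier_rows, b] > r2_threshold):
                        keep[live[b]] = False
            if start + window_snps >= len(where):
                break
            start += step_snps
    return idx[keep]


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, k)
    components: np.ndarray  # (k, n_variants)
    explained_variance_ratio: np.ndarray


def pca(matrix_or_genotypes, k: int = 20) -> PCAResult:
    """PCA of the genotype matrix: per-variant mean imputation of missing
    calls, per-variant centering, then a singular value decomposition.
    Returns at most min(n_samples, n_variants) components."""
    g = (
        matrix_or_genotypes.genotypes
        if isinstance(matrix_or_genotypes, GenotypeMatrix)
        else np.asarray(matrix_or_genotypes)
    ).astype(float)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variants")
    g = np.where(g == MISSING, np.nan, g)
    mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mean, g) - mean
    u, s, vt = np.linalg.svd(g, full_matrices=False)
    k = min(k, len(s))
    var = s**2
    return PCAResult(
        scores=u[:, :k] * s[:k],
        components=vt[:k],
        explained_variance_ratio=var[:k] / var.sum() if var.sum() else var[:k],
    )


def pc_geo_correlation(scores: np.ndarray, lat, lon) -> pd.DataFrame:
    """Pearson correlation of each PC with latitude and longitude, with the
    two-sided t-test t = r sqrt((n-2)/(1-r^2)) on n-2 df. Samples with
    missing coordinates are excluded."""
    lat, lon = np.asarray(lat, float), np.asarray(lon, float)
    ok = ~(np.isnan(lat) | np.isnan(lon))
    if ok.sum() < 3:
        raise ValueError("need at least 3 geo-referenced samples")
    rows = []
    for pc in range(scores.shape[1]):
        row = {"pc": pc + 1}
        for name, coord in (("lat", lat[ok]), ("lon", lon[ok])):
            r = _pearson(scores[ok, pc], coord)
            n = ok.sum()
            if abs(r) >= 1.0:
                t, p = math.inf * np.sign(r), 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
            row.update({f"r_{name}": r, f"t_{name}": t, f"p_{name}": p})
        rows.append(row)
    return pd.DataFrame(rows)


def _pearson(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom else 0.0


def assign_subpops(qmatrix: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Per-sample label = argmax ancestry component iff its fraction is
    strictly above the threshold, else 'unassigned'."""
    q = qmatrix.drop(columns=["sample"]) if "sample" in qmatrix else qmatrix
    sums = q.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("ancestry fractions must sum to 1 per sample")
    if (q.to_numpy() < 0).any():
        raise ValueError("ancestry fractions must be nonnegative")
    best = q.idxmax(axis=1)
    label = best.where(q.max(axis=1) > threshold, "unassigned")
    if "sample" in qmatrix:
        label.index = qmatrix["sample"]
    return label


FST_CLASSES = ((0.05, "little"), (0.15, "moderate"), (0.25, "great"), (math.inf, "very great"))


def classify_fst(value: float) -> str:
    for bound, label in FST_CLASSES:
        if value < bound:
            return label
    return "very great"


@dataclass
class FstResult:
    group_a: str
    group_b: str
    per_site: np.ndarray
    weighted: float
    classification: str


def fst(
    matrix: GenotypeMatrix,
    group_a_ids,
    group_b_ids,
    labels=("A", "B"),
    method: str = "variance",
) -> FstResult:
    """F_ST between two groups.

    The primary 'variance' mode is the Wright variance decomposition
    F_ST = sigma^2_S / (p (1-p)): per site, sigma^2_S is the sample-size
    weighted between-group variance of allele frequencies and p the pooled
    frequency; the weighted genome-wide value is the ratio of sums over
    sites. The 'weir_cockerham' mode is the 1984 two-level theta estimator
    provided for comparison. Sites where either group has no called
    haplotypes, or with zero total variance, are skipped.
    """
    if not len(group_a_ids) or not len(group_b_ids):
        raise ValueError("empty group")
    ia, ib = matrix.sample_index(group_a_ids), matrix.sample_index(group_b_ids)
    ga, gb = matrix.genotypes[ia], matrix.genotypes[ib]
    na = 2 * (ga != MISSING).sum(axis=0).astype(float)
    nb = 2 * (gb != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(ga != MISSING, ga, 0).sum(axis=0) / na
        pb = np.where(gb != MISSING, gb, 0).sum(axis=0) / nb
        usable = (na >= 2) & (nb >= 2)
        p = (na * pa + nb * pb) / (na + nb)
        sigma_t = p * (1.0 - p)
        usable &= sigma_t > 0
        if method == "variance":
            sigma_s = (na * (pa - p) ** 2 + nb * (pb - p) ** 2) / (na + nb)
            per_site = np.where(usable, sigma_s / sigma_t, np.nan)
            weighted = float(np.nansum(sigma_s[usable]) / np.nansum(sigma_t[usable]))
        elif method == "weir_cockerham":
            a_comp, b_comp, c_comp = _wc_components(pa, pb, na / 2, nb / 2, ga, gb)
            denom = a_comp + b_comp + c_comp
            per_site = np.where(usable & (denom > 0), a_comp / np.where(denom > 0, denom, 1),
                                np.nan)
            weighted = float(np.nansum(a_comp[usable]) / np.nansum(denom[usable]))
        else:
            raise ValueError(f"unknown method {method!r}")
    return FstResult(labels[0], labels[1], per_site, weighted, classify_fst(weighted))


def _wc_components(pa, pb, na, nb, ga, gb):
    """Weir & Cockerham (1984) a/b/c variance components for two demes,
    using observed heterozygote fractions."""
    r = 2.0
    n_bar = (na + nb) / r
    n_c = (r * n_bar - (na**2 + nb**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (na * pa + nb * pb) / (r * n_bar)
    s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1.0) * n_bar)
    ha = (ga == 1).sum(axis=0) / np.maximum((ga != MISSING).sum(axis=0), 1)
    hb = (gb == 1).sum(axis=0) / np.maximum((gb != MISSING).sum(axis=0), 1)
    h_bar = (na * ha + nb * hb) / (r * n_bar)
    pq = p_bar * (1.0 - p_bar)
    a = n_bar / n_c * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0))
    b = n_bar / (n_bar - 1.0) * (pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    return a, b, c


def cline_and_balance(
    samples: pd.DataFrame,
    lat_cline: float = 11.0,
    lon_cline: float = -6.0,
    n_per_group: int = 15,
    seed: int = 0,
    group_by: str = "subpop",
    prefer_high_coverage: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Split samples by latitude/longitude clines and draw balanced
    subsamples per group.

    Latitude >= the cline is 'north', longitude >= the cline is 'east'
    (boundary points go north/east). Balanced subsets take the n highest
    coverage samples when coverage is available and preferred, otherwise a
    seeded uniform draw without replacement; groups smaller than n are used
    whole with a warning.
    """
    out = samples.copy()
    out["ns_group"] = np.where(out["lat"] >= lat_cline, "north", "south")
    out["ew_group"] = np.where(out["lon"] >= lon_cline, "east", "west")
    rng = np.random.default_rng(seed)
    subsets = {}
    for group, members in out.groupby(group_by):
        if len(members) < n_per_group:
            warnings.warn(
                f"group {group!r} has only {len(members)} samples (< {n_per_group}); using all"
            )
            subsets[group] = list(members["id"])
        elif prefer_high_coverage and "coverage" in members:
            ranked = members.sort_values(["coverage", "id"], ascending=[False, True])
            subsets[group] = list(ranked["id"].head(n_per_group))
        else:
            pick = rng.choice(len(members), size=n_per_group, replace=False)
            subsets[group] = list(members["id"].iloc[np.sort(pick)])
    return out, subsets


def king_kinship(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """KING-robust within-pair kinship estimate.

    phi = (N_{het,het} - 2 N_{opposing hom}) / (N_het(i) + N_het(j)) over
    the sites called in both samples; NaN when neither sample is
    heterozygous at any shared site. A self comparison yields exactly 0.5.
    """
    g_i, g_j = np.asarray(g_i), np.asarray(g_j)
    ok = (g_i != MISSING) & (g_j != MISSING)
    a, b = g_i[ok], g_j[ok]
    n_het_i = int((a == 1).sum())
    n_het_j = int((b == 1).sum())
    if n_het_i + n_het_j == 0:
        return math.nan
    n_hh = int(((a == 1) & (b == 1)).sum())
    n_opp = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    return (n_hh - 2.0 * n_opp) / (n_het_i + n_het_j)


def kinship_pairs(matrix: GenotypeMatrix, samples: pd.DataFrame,
                  sample_ids=None, group: str | None = None) -> pd.DataFrame:
    """All unordered pairs with KING kinship and Haversine distance (km)."""
    meta = samples.set_index("id")
    ids = list(sample_ids) if sample_ids is not None else list(matrix.samples)
    idx = matrix.sample_index(ids)
    rows = []
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            i, j = ids[x], ids[y]
            phi = king_kinship(matrix.genotypes[idx[x]], matrix.genotypes[idx[y]])
            km = haversine_km(
                (meta.at[i, "lat"], meta.at[i, "lon"]), (meta.at[j, "lat"], meta.at[j, "lon"])
            )
            rows.append({"i": i, "j": j, "phi": phi, "km": km, "group": group or ""})
    return pd.DataFrame(rows)


EARTH_RADIUS_KM = 6378.0


def haversine_km(p1, p2, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between (lat, lon) points in degrees."""
    for lat, lon in (p1, p2):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*p1, *p2))
    a = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(a)))


@dataclass
class IbdFit:
    slope: float
    intercept: float
    r: float
    n_used: int
    n_excluded: int


def ibd_regression(pairs: pd.DataFrame, iqr_multiplier: float = 1.5,
                   one_sided: bool = False) -> IbdFit:
    """Ordinary least squares of kinship on geographic distance after
    excluding distance outliers by the Tukey fence rule.

    Fences are Q1 - k*IQR and Q3 + k*IQR on the distances (kinship never
    enters the fences); ``one_sided`` drops only the upper fence's
    exceeders. Requires >= 3 pairs after exclusion.
    """
    data = pairs.dropna(subset=["phi", "km"])
    km = data["km"].to_numpy(float)
    q1, q3 = np.percentile(km, [25, 75])
    iqr = q3 - q1
    hi = km <= q3 + iqr_multiplier * iqr
    lo = np.ones_like(hi) if one_sided else km >= q1 - iqr_multiplier * iqr
    keep = hi & lo.astype(bool)
    used = data[keep]
    if len(used) < 3:
        raise ValueError("fewer than 3 pairs after outlier exclusion")
    x, y = used["km"].to_numpy(float), used["phi"].to_numpy(float)
    if np.all(x == x[0]):
        raise ValueError("degenerate distances: slope undefined")
    res = scipy.stats.linregress(x, y)
    return IbdFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n_used=int(len(used)),
        n_excluded=int(len(data) - len(used)),
    )
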
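import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oryzapop.sweep import (
    OMEGA_CAP,
    call_outliers,
    feature_proximity,
    max_omega,
    neutrality_cross_check,
    omega_at_split,
    omega_scan,
    r2_matrix,
    r_squared_genotypes,
    r_squared_haplotypes,
)


# -- r^2 ---------------------------------------------------------------------

def test_duplicated_site_r2_one():
    g = np.array([0, 1, 2, 1, 0, 2])
    assert r_squared_genotypes(g, g).r2 == pytest.approx(1.0)


def test_independent_sites_zero_ld():
    # all four gametes equally frequent
    h1 = np.array([1, 1, 0, 0])
    h2 = np.array([1, 0, 1, 0])
    pair = r_squared_haplotypes(h1, h2)
    assert pair.D == pytest.approx(0.0, abs=1e-15)
    assert pair.r2 == pytest.approx(0.0, abs=1e-15)


def test_hand_enumerated_haplotype_ld():
    # AB x4, ab x2, Ab x1, aB x1
    h1 = np.array([1, 1, 1, 1, 0, 0, 1, 0])
    h2 = np.array([1, 1, 1, 1, 0, 0, 0, 1])
    pair = r_squared_haplotypes(h1, h2)
    assert pair.D == pytest.approx(4 / 8 - (5 / 8) * (5 / 8), abs=1e-15)
    assert pair.D == pytest.approx(0.109375)
    expected_r2 = pair.D**2 / ((5 / 8) * (3 / 8) * (5 / 8) * (3 / 8))
    assert pair.r2 == pytest.approx(expected_r2, abs=1e-15)


# -- omega -------------------------------------------------------------------

def test_uniform_ld_gives_omega_one():
    r2 = np.ones((6, 6))
    for l in range(1, 6):
        val, capped = omega_at_split(r2, l)
        assert val == pytest.approx(1.0)
        assert not capped


def test_block_ld_with_zero_cross_is_capped():
    r2 = np.zeros((4, 4))
    r2[:2, :2] = 1.0
    r2[2:, 2:] = 1.0
    val, capped = omega_at_split(r2, 2)
    assert val == OMEGA_CAP
    assert capped


def test_block_ld_with_tiny_cross_hits_cap():
    eps = 1e-7
    r2 = np.full((4, 4), eps)
    r2[:2, :2] = 1.0
    r2[2:, 2:] = 1.0
    val, capped = omega_at_split(r2, 2)
    assert val == OMEGA_CAP  # 1/eps beyond the ceiling
    assert capped


def brute_omega(r2, l):
    w = r2.shape[0]
    left = [(i, j) for i in range(l) for j in range(i + 1, l)]
    right = [(i, j) for i in range(l, w) for j in range(i + 1, w)]
    cross = [(i, j) for i in range(l) for j in range(l, w)]
    num = sum(r2[i, j] for i, j in left + right) / (len(left) + len(right))
    den = sum(r2[i, j] for i, j in cross) / len(cross)
    return num / den


def test_omega_matches_term_by_term_evaluation():
    rng = np.random.default_rng(5)
    for w in (4, 5, 8):
        a = rng.uniform(0.01, 1.0, size=(w, w))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        for l in range(2, w - 1):
            val, capped = omega_at_split(r2, l)
            assert not capped
            assert val == pytest.approx(brute_omega(r2, l), abs=1e-12)
        best, lbest, _ = max_omega(r2)
        brute_best = max(
            (brute_omega(r2, l), l) for l in range(1, w)
            if l * (l - 1) / 2 + (w - l) * (w - l - 1) / 2 > 0
        )
        assert best == pytest.approx(brute_best[0], abs=1e-12)


def test_grid_spacing_beyond_chromosome_single_point(matrix_factory):
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
    m = matrix_factory(g, pos=np.linspace(100, 40_000, 30).astype(int))
    scan = omega_scan(m, grid_spacing=1_000_000, max_window_bp=1_000_000)
    assert len(scan) == 1


# -- outlier calling ---------------------------------------------------------

def test_top_half_percent_of_thousand_is_five():
    df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1000),
                       "omega": np.arange(1000, dtype=float)})
    out = call_outliers(df, 0.005)
    assert out["outlier"].sum() == 5
    assert set(out[out["outlier"]]["pos"]) == {995, 996, 997, 998, 999}


def test_all_equal_values_all_flagged():
    df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(100),
                       "omega": np.ones(100)})
    out = call_outliers(df, 0.005)
    assert out["outlier"].all()


def test_outliers_match_sort_oracle():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0, 10, 400)
    df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(400), "omega": vals})
    out = call_outliers(df, 0.01)
    k = math.ceil(0.01 * 400)
    threshold = np.sort(vals)[::-1][k - 1]
    np.testing.assert_array_equal(out["outlier"].to_numpy(), vals >= threshold)


# -- feature proximity -------------------------------------------------------

def features_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def outliers_df(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "omega": [10.0] * len(positions),
                         "outlier": [True] * len(positions)})


def test_overlapping_feature_distance_zero():
    feats = features_df([("chr1", 900, 1100, "gA")])
    prox = feature_proximity(outliers_df([1000]), feats)
    assert len(prox) == 1
    assert prox["distance"].iloc[0] == 0


def test_exactly_25kb_excluded_strict():
    feats = features_df([("chr1", 26_000, 27_000, "gA")])
    prox = feature_proximity(outliers_df([1000]), feats)
    assert len(prox) == 0  # distance exactly 25,000 -> strict <
    near = features_df([("chr1", 25_999, 27_000, "gA")])
    prox2 = feature_proximity(outliers_df([1000]), near)
    assert len(prox2) == 1
    assert prox2["distance"].iloc[0] == 24_999


def test_proximity_matches_brute_force_join():
    feats = features_df(
        [("chr1", 1000, 2000, "g1"), ("chr1", 40_000, 41_000, "g2"),
         ("chr1", 70_000, 71_000, "g3"), ("chr2", 500, 900, "g4"),
         ("chr1", 90_000, 95_000, "g5")]
    )
    outs = pd.concat([outliers_df([1500, 60_000]),], ignore_index=True)
    prox = feature_proximity(outs, feats)
    expected = set()
    for _, o in outs.iterrows():
        for _, f in feats.iterrows():
            if f["chrom"] != o["chrom"]:
                continue
            if f["start"] <= o["pos"] <= f["end"]:
                d = 0
            else:
                d = min(abs(o["pos"] - f["start"]), abs(o["pos"] - f["end"]))
            if d < 25_000:
                expected.add((f["gene_id"], o["pos"], d))
    got = set(zip(prox["gene_id"], prox["outlier_pos"], prox["distance"]))
    assert got == expected


# -- cross-check against diversity windows ----------------------------------

def window_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def test_cross_check_single_window_covers_all():
    omega = outliers_df([100, 5000, 9000])
    pi = window_df([("chr1", 1, 10_000, 0.001)])
    d = window_df([("chr1", 1, 10_000, -0.5)])
    merged = neutrality_cross_check(omega, pi, d)
    assert (merged["n_pi_windows"] == 1).all()
    assert np.allclose(merged["pi"], 0.001)
    assert np.allclose(merged["tajima_d"], -0.5)


def test_cross_check_boundary_point_in_both_windows():
    omega = outliers_df([5000])
    pi = window_df([("chr1", 1, 5000, 0.001), ("chr1", 4000, 9000, 0.003)])
    d = window_df([("chr1", 1, 5000, 0.1), ("chr1", 4000, 9000, 0.3)])
    merged = neutrality_cross_check(omega, pi, d)
    assert merged["n_pi_windows"].iloc[0] == 2
    assert merged["pi"].iloc[0] == pytest.approx(0.002)  # mean of both
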
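import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oryzapop.structure import (
    assign_subpops,
    classify_fst,
    cline_and_balance,
    fst,
    haversine_km,
    ibd_regression,
    king_kinship,
    ld_prune,
    pc_geo_correlation,
    pca,
)
from oryzapop.sweep import r2_matrix
from oryzapop.variantio import MISSING


# -- LD pruning --------------------------------------------------------------

def test_duplicated_columns_keep_one():
    rng = np.random.default_rng(1)
    col = rng.integers(0, 3, 30)
    g = np.column_stack([col, col]).astype(np.int8)
    kept = ld_prune(g, window_snps=10, step_snps=5)
    assert len(kept) == 1


def test_uncorrelated_columns_all_kept():
    # orthogonal two-level patterns over 8 samples: pairwise r = 0
    base = np.array(
        [[0, 0, 0, 0, 2, 2, 2, 2],
         [0, 0, 2, 2, 0, 0, 2, 2],
         [0, 2, 0, 2, 0, 2, 0, 2]]
    ).T.astype(np.int8)
    kept = ld_prune(base, window_snps=10, step_snps=5)
    assert len(kept) == 3


def test_pruned_set_passes_exhaustive_check():
    rng = np.random.default_rng(7)
    g = rng.integers(0, 3, size=(40, 20)).astype(np.int8)
    g[:, 5:9] = g[:, [4]]  # plant a perfect LD block
    kept = ld_prune(g, r2_threshold=0.25, window_snps=10, step_snps=5)
    r2 = r2_matrix(g[:, kept])
    for a, b in itertools.combinations(range(len(kept)), 2):
        if kept[b] - kept[a] < 10:  # same window reachable
            assert not (r2[a, b] > 0.25)
    # idempotence
    again = ld_prune(g[:, kept], r2_threshold=0.25, window_snps=10, step_snps=5)
    assert len(again) == len(kept)


# -- PCA ---------------------------------------------------------------------

def test_pca_separates_duplicated_clusters():
    a = np.tile([0, 2, 0, 2, 2], (5, 1))
    b = np.tile([2, 0, 2, 0, 0], (5, 1))
    res = pca(np.vstack([a, b]).astype(np.int8), k=2)
    pc1 = res.scores[:, 0]
    assert np.std(pc1[:5]) == pytest.approx(0.0, abs=1e-9)
    assert np.std(pc1[5:]) == pytest.approx(0.0, abs=1e-9)
    assert abs(pc1[:5].mean() - pc1[5:].mean()) > 1.0


def test_pca_scores_uncorrelated():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, size=(30, 80)).astype(np.int8)
    res = pca(g, k=5)
    cov = np.cov(res.scores.T)
    off = cov - np.diag(np.diag(cov))
    assert np.abs(off).max() < 1e-8


def test_pca_variance_ratio_matches_eigendecomposition():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
    res = pca(g, k=5)
    x = g.astype(float)
    x -= x.mean(axis=0)
    eig = np.linalg.eigvalsh(x @ x.T)[::-1]
    expected = eig[:5] / eig.sum()
    np.testing.assert_allclose(res.explained_variance_ratio, expected, atol=1e-10)


# -- PC vs geography ---------------------------------------------------------

def test_pc_equal_to_latitude_perfect_correlation():
    lat = np.linspace(5, 15, 12)
    lon = np.zeros(12)
    scores = lat[:, None].copy()
    out = pc_geo_correlation(scores, lat, lon)
    assert out["r_lat"].iloc[0] == pytest.approx(1.0)
    assert out["p_lat"].iloc[0] == 0.0


def test_pc_orthogonal_to_geography():
    lat = np.array([0, 0, 1, 1, 2, 2], float)
    scores = np.array([1, -1, 1, -1, 1, -1], float)[:, None]
    out = pc_geo_correlation(scores, lat, np.zeros(6))
    assert out["r_lat"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert out["p_lat"].iloc[0] == pytest.approx(1.0)


def test_pc_geo_t_statistic_closed_form():
    rng = np.random.default_rng(4)
    lat = rng.normal(10, 2, 10)
    lon = rng.normal(-5, 2, 10)
    scores = (0.6 * lat + rng.normal(0, 1, 10))[:, None]
    out = pc_geo_correlation(scores, lat, lon)
    r = np.corrcoef(scores[:, 0], lat)[0, 1]
    t = r * math.sqrt(8 / (1 - r * r))
    assert out["r_lat"].iloc[0] == pytest.approx(r, abs=1e-12)
    assert out["t_lat"].iloc[0] == pytest.approx(t, abs=1e-10)


# -- ancestry assignment -----------------------------------------------------

def test_assignment_majority_and_boundary():
    q = pd.DataFrame({"sample": ["a", "b"], "K1": [0.9, 0.5], "K2": [0.1, 0.5]})
    labels = assign_subpops(q)
    assert labels.loc["a"] == "K1"
    assert labels.loc["b"] == "unassigned"  # strict >


def test_assignment_matches_truth(small_sim):
    from oryzapop.simdata import truth_qmatrix

    _, _, samples, truth = small_sim
    q = truth_qmatrix(samples, seed=1)
    labels = assign_subpops(q)
    frac = q.drop(columns=["sample"]).max(axis=1).to_numpy()
    want = np.asarray([truth.subpop_of[s] for s in q["sample"]], dtype=object)
    got = labels.to_numpy(object)
    confident = frac > 0.5
    assert (got[confident] == want[confident]).all()


# -- F_ST --------------------------------------------------------------------

def two_pop_matrix(matrix_factory, pa_geno, pb_geno):
    g = np.vstack([pa_geno, pb_geno]).astype(np.int8)
    ids = [f"s{i}" for i in range(g.shape[0])]
    m = matrix_factory(g, samples=ids)
    na = len(pa_geno)
    return m, ids[:na], ids[na:]


def test_fst_identical_groups_zero(matrix_factory):
    block = np.array([[0, 1], [1, 2], [2, 0], [1, 1]])
    m, a, b = two_pop_matrix(matrix_factory, block, block)
    assert fst(m, a, b).weighted == pytest.approx(0.0, abs=1e-12)


def test_fst_fixed_difference_one(matrix_factory):
    m, a, b = two_pop_matrix(
        matrix_factory, np.zeros((4, 3)), np.full((4, 3), 2)
    )
    res = fst(m, a, b)
    assert res.weighted == pytest.approx(1.0)
    res_wc = fst(m, a, b, method="weir_cockerham")
    assert res_wc.weighted == pytest.approx(1.0)


def test_fst_hand_arithmetic_point_two_point_eight(matrix_factory):
    # frequencies 0.2 and 0.8 with equal sizes: sigma2_S = 0.09,
    # sigma2_T = 0.5*0.5 = 0.25, F_ST = 0.36
    pa = np.array([[2], [1], [1], [0], [0], [0], [0], [0], [0], [0]])
    pb = np.array([[2], [2], [2], [2], [2], [2], [1], [1], [1], [1]])
    assert pa.sum() / 20 == 0.2 and pb.sum() / 20 == 0.8
    m, a, b = two_pop_matrix(matrix_factory, pa, pb)
    res = fst(m, a, b)
    assert res.weighted == pytest.approx(0.36, abs=1e-12)
    assert res.classification == "very great"


def test_fst_classification_bands():
    assert classify_fst(0.03) == "little"
    assert classify_fst(0.10) == "moderate"
    assert classify_fst(0.18) == "great"
    assert classify_fst(0.30) == "very great"


# -- clines and balanced subsampling ----------------------------------------

def cline_samples():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "id": [f"x{i}" for i in range(40)],
            "subpop": ["P1"] * 20 + ["P2"] * 20,
            "lat": rng.uniform(5, 15, 40),
            "lon": rng.uniform(-16, 2, 40),
            "coverage": rng.uniform(5, 30, 40).round(2),
        }
    )


def test_cline_boundary_conventions():
    df = pd.DataFrame({"id": ["a", "b"], "subpop": ["P", "P"],
                       "lat": [12.0, 11.0], "lon": [-5.0, -6.0],
                       "coverage": [10.0, 10.0]})
    out, _ = cline_and_balance(df, n_per_group=1)
    assert out.loc[0, "ns_group"] == "north" and out.loc[0, "ew_group"] == "east"
    assert out.loc[1, "ns_group"] == "north" and out.loc[1, "ew_group"] == "east"


def test_balanced_subsample_deterministic():
    df = cline_samples()
    _, s1 = cline_and_balance(df, n_per_group=15, seed=42)
    _, s2 = cline_and_balance(df, n_per_group=15, seed=42)
    assert s1 == s2
    assert all(len(v) == 15 for v in s1.values())


def test_high_coverage_preferred():
    df = cline_samples()
    _, subs = cline_and_balance(df, n_per_group=15)
    for group, chosen in subs.items():
        grp = df[df["subpop"] == group]
        cutoff = grp["coverage"].sort_values(ascending=False).iloc[14]
        assert (grp.set_index("id").loc[chosen, "coverage"] >= cutoff).all()


# -- kinship -----------------------------------------------------------------

def test_king_self_is_half():
    g = np.array([0, 1, 2, 1, 0, 1], dtype=np.int8)
    assert king_kinship(g, g) == 0.5


def test_king_opposing_homozygotes_negative():
    gi = np.array([0, 0, 0, 1], dtype=np.int8)
    gj = np.array([2, 2, 2, 1], dtype=np.int8)
    assert king_kinship(gi, gj) < 0


def test_king_ignores_missing_sites():
    gi = np.array([0, 1, MISSING, 2], dtype=np.int8)
    gj = np.array([MISSING, 1, 1, 2], dtype=np.int8)
    # shared called sites: positions 1 and 3 -> one het-het pair
    assert king_kinship(gi, gj) == pytest.approx((1 - 0) / (1 + 1))


# -- Haversine ---------------------------------------------------------------

def test_haversine_closed_forms():
    assert haversine_km((12.0, -5.0), (12.0, -5.0)) == 0.0
    assert haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
        math.pi * 6378.0, rel=1e-12
    )
    assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
        math.pi / 180.0 * 6378.0, rel=1e-12
    )


# -- IBD regression ----------------------------------------------------------

def test_ibd_recovers_linear_relation():
    km = np.linspace(10, 500, 30)
    phi = 0.3 - 0.0004 * km
    pairs = pd.DataFrame({"phi": phi, "km": km})
    fit = ibd_regression(pairs)
    assert fit.r == pytest.approx(-1.0)
    assert fit.slope == pytest.approx(-0.0004, abs=1e-12)
    assert fit.n_excluded == 0


def test_ibd_fence_excludes_extreme_distance():
    km = np.concatenate([np.linspace(10, 100, 20), [5000.0]])
    phi = 0.3 - 0.0004 * km
    pairs = pd.DataFrame({"phi": phi, "km": km})
    fit = ibd_regression(pairs)
    assert fit.n_excluded == 1
    assert fit.n_used == 20
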
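"""Clustering: z-scores, imputing k-means, validity votes, cluster tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from mameta.cluster import (
    centroid_distances,
    cluster_axis_anova,
    cluster_phenotype_association,
    cluster_t2d_effects,
    compute_zscores,
    disparity_pca,
    impute_kmeans,
    plain_kmeans,
    select_k,
)
from mameta.simulate import SimulationConfig, ZScoreMatrix, simulate_phenotype_zscores

from conftest import SIGN_CENTROIDS


def _zmatrix(values):
    values = np.asarray(values, float)
    return ZScoreMatrix(values, np.isnan(values),
                        [f"s{i}" for i in range(values.shape[0])],
                        [f"t{j}" for j in range(values.shape[1])])


# ---------------------------------------------------------------------------
# z-score construction


def test_zscore_arithmetic_and_sign_alignment():
    trait = pd.DataFrame({
        "SNV": ["v1", "v1", "v2"],
        "PHENOTYPE": ["bmi", "hdl", "bmi"],
        "EA": ["A", "G", "C"],
        "NEA": ["G", "A", "T"],
        "BETA": [0.1, 0.1, 0.0],
        "SE": [0.01, 0.01, 0.02],
    })
    risk = pd.DataFrame({"SNV": ["v1", "v2"], "RISK": ["A", "T"],
                         "OTHER": ["G", "C"]})
    Z = compute_zscores(trait, risk, {"bmi": 100.0, "hdl": 100.0})
    frame = Z.to_frame()
    assert frame.loc["v1", "bmi"] == pytest.approx(1.0)   # 0.1/(10*0.01)
    assert frame.loc["v1", "hdl"] == pytest.approx(-1.0)  # non-risk allele
    assert frame.loc["v2", "bmi"] == 0.0                  # beta 0 -> z 0
    assert np.isnan(frame.loc["v2", "hdl"])               # unreported pair


def test_zscore_mismatched_alleles_set_missing(caplog):
    trait = pd.DataFrame({
        "SNV": ["v1"], "PHENOTYPE": ["bmi"], "EA": ["C"], "NEA": ["T"],
        "BETA": [0.2], "SE": [0.01],
    })
    risk = pd.DataFrame({"SNV": ["v1"], "RISK": ["A"], "OTHER": ["G"]})
    Z = compute_zscores(trait, risk, {"bmi": 50.0})
    assert Z.mask.all()


# ---------------------------------------------------------------------------
# k-means with imputation


def test_no_missingness_identical_to_plain_kmeans():
    cfg = SimulationConfig(n_snvs=120, n_clusters_true=3,
                           cluster_centroids=SIGN_CENTROIDS,
                           missing_rate=0.0, seed=3)
    Z, _ = simulate_phenotype_zscores(cfg)
    model = impute_kmeans(Z, 3, seed=7)
    labels, centroids, inertia = plain_kmeans(Z.values, 3, seed=7)
    np.testing.assert_array_equal(model.labels, labels)
    np.testing.assert_array_equal(model.centroids, centroids)
    # independent oracle: sklearn's Lloyd finds the same partition
    sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(Z.values)
    assert adjusted_rand_score(sk.labels_, model.labels) == 1.0


def test_planted_cluster_recovery_without_missingness():
    cfg = SimulationConfig(n_snvs=200, n_clusters_true=3,
                           cluster_centroids=SIGN_CENTROIDS,
                           missing_rate=0.0, seed=1)
    Z, truth = simulate_phenotype_zscores(cfg)
    model = impute_kmeans(Z, 3, seed=1)
    assert adjusted_rand_score(truth, model.labels) == 1.0


def test_recovery_with_missingness_short():
    """Reduced-replicate version of the 30% MCAR recovery check."""
    aris = []
    for seed in range(5):
        cfg = SimulationConfig(n_snvs=200, n_clusters_true=3,
                               cluster_centroids=SIGN_CENTROIDS,
                               missing_rate=0.3, seed=seed)
        Z, truth = simulate_phenotype_zscores(cfg)
        model = impute_kmeans(Z, 3, seed=seed)
        aris.append(adjusted_rand_score(truth, model.labels))
    assert min(aris) >= 0.9


def test_impute_kmeans_validation_and_partition():
    Z = _zmatrix(np.random.default_rng(0).standard_normal((10, 4)))
    with pytest.raises(ValueError):
        impute_kmeans(Z, 11, seed=0)
    with pytest.raises(ValueError):
        impute_kmeans(Z, 2, n_iter=3, n_end=5, seed=0)
    model = impute_kmeans(Z, 3, seed=0)
    C = model.assignment_matrix()
    np.testing.assert_array_equal(C.sum(axis=1), np.ones(10))  # hard partition
    # centroid identity: mean of imputed member profiles
    for c in range(3):
        if (model.labels == c).any():
            np.testing.assert_allclose(
                model.centroids[c], model.imputed[model.labels == c].mean(axis=0),
                atol=1e-12)


def test_imputed_matrix_preserves_observed_entries():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((50, 6))
    X[rng.random((50, 6)) < 0.3] = np.nan
    Z = _zmatrix(X)
    model = impute_kmeans(Z, 2, seed=2)
    obs = ~Z.mask
    np.testing.assert_array_equal(model.imputed[obs], X[obs])
    assert np.isfinite(model.imputed).all()


# ---------------------------------------------------------------------------
# optimal-k selection


def test_select_k_finds_planted_four_clusters():
    cents = np.zeros((4, 8))
    for c in range(4):
        cents[c, 2 * c] = 5.0
        cents[c, 2 * c + 1] = -5.0
    cfg = SimulationConfig(n_snvs=160, n_clusters_true=4,
                           cluster_centroids=cents, missing_rate=0.0, seed=2)
    Z, _ = simulate_phenotype_zscores(cfg)
    k, votes = select_k(Z, range(2, 7), seed=2)
    assert k == 4


def test_select_k_degenerate_and_deterministic():
    Z = _zmatrix(np.random.default_rng(1).standard_normal((60, 5)))
    k, votes = select_k(Z, [3], seed=0)
    assert k == 3 and all(v == 3 for v in votes.values())
    k1, v1 = select_k(Z, range(2, 5), seed=4)
    k2, v2 = select_k(Z, range(2, 5), seed=4)
    assert k1 == k2 and v1 == v2
    with pytest.raises(ValueError):
        select_k(Z, [], seed=0)


# ---------------------------------------------------------------------------
# profiles, distances, PCA


def test_profile_gamma_is_cluster_mean_and_matches_ols():
    cfg = SimulationConfig(n_snvs=90, n_clusters_true=3,
                           cluster_centroids=SIGN_CENTROIDS,
                           missing_rate=0.0, seed=6)
    Z, _ = simulate_phenotype_zscores(cfg)
    model = impute_kmeans(Z, 3, seed=6)
    prof = cluster_phenotype_association(model)
    X = model.imputed
    C = model.assignment_matrix()
    import statsmodels.api as sm

    for j in [0, 4, 9]:
        fit = sm.OLS(X[:, j], C).fit()
        np.testing.assert_allclose(prof.gamma[:, j], fit.params, atol=1e-10)
        np.testing.assert_allclose(prof.se[:, j], fit.bse, atol=1e-10)
        np.testing.assert_allclose(prof.p[:, j], fit.pvalues, atol=1e-10)
    for c in range(3):
        np.testing.assert_allclose(prof.gamma[c],
                                   X[model.labels == c].mean(axis=0), atol=1e-12)
    # planted centroids recovered within 2 SE
    order = np.argsort([np.linalg.norm(model.centroids[c] - SIGN_CENTROIDS[c])
                        for c in range(3)])
    assert np.isfinite(prof.temperature).all()


def test_profile_k1_and_zero_matrix():
    Z = _zmatrix(np.zeros((20, 4)))
    model = impute_kmeans(Z, 1, seed=0)
    prof = cluster_phenotype_association(model)
    np.testing.assert_array_equal(prof.gamma, np.zeros((1, 4)))
    np.testing.assert_array_equal(prof.temperature, np.zeros((1, 4)))

    rng = np.random.default_rng(2)
    X = rng.standard_normal((20, 4))
    Zr = _zmatrix(X)
    m1 = impute_kmeans(Zr, 1, seed=0)
    p1 = cluster_phenotype_association(m1)
    np.testing.assert_allclose(p1.gamma[0], X.mean(axis=0), atol=1e-12)


def test_centroid_distances_closed_form_and_oracle():
    X = np.array([[3.0], [1.0]])
    Z = _zmatrix(X)
    model = impute_kmeans(Z, 2, seed=0)
    d = centroid_distances(model)
    # SNV equal to its centroid -> 0; one phenotype z=3 vs centroid 1 -> 2
    assert d[0, model.labels[0]] == pytest.approx(0.0)
    other = 1 - model.labels[0]
    assert d[0, other] == pytest.approx(2.0)

    rng = np.random.default_rng(3)
    Xr = rng.standard_normal((40, 6))
    m = impute_kmeans(_zmatrix(Xr), 3, seed=1)
    dr = centroid_distances(m)
    for j in range(40):
        for c in range(3):
            assert dr[j, c] == pytest.approx(
                np.sqrt(((Xr[j] - m.centroids[c]) ** 2).sum()), rel=1e-12)


def test_disparity_pca_rank1_and_conservation():
    u = np.linspace(-1, 1, 30)[:, None]
    v = np.array([[1.0, 2.0, -1.0]])
    model = impute_kmeans(_zmatrix(u @ v), 2, seed=0)
    scores, frac = disparity_pca(model)
    assert frac[0] == pytest.approx(1.0, abs=1e-8)

    rng = np.random.default_rng(4)
    X = rng.standard_normal((25, 5))
    m = impute_kmeans(_zmatrix(X), 2, seed=0)
    scores, frac = disparity_pca(m)
    assert frac.sum() == pytest.approx(1.0, rel=1e-10)
    # oracle: eigendecomposition of the covariance, up to sign
    Xc = X - X.mean(axis=0)
    w, V = np.linalg.eigh(Xc.T @ Xc)
    order = np.argsort(w)[::-1]
    oracle = Xc @ V[:, order]
    for j in range(3):
        assert (np.allclose(scores[:, j], oracle[:, j], atol=1e-8)
                or np.allclose(scores[:, j], -oracle[:, j], atol=1e-8))


# ---------------------------------------------------------------------------
# cluster-level T2D and axis tests


def test_t2d_effects_homogeneous_and_oracle():
    rng = np.random.default_rng(5)
    X = np.vstack([SIGN_CENTROIDS[c] + rng.standard_normal(10) * 0.1
                   for c in [0, 0, 1, 1, 2, 2] * 5])
    model = impute_kmeans(_zmatrix(X), 3, seed=0)
    n = X.shape[0]
    betas = np.full(n, 0.03)
    variances = np.full(n, 0.004**2)
    out = cluster_t2d_effects(betas, variances, model)
    assert out["het_stat"] == pytest.approx(0.0, abs=1e-10)
    assert out["het_p"] == pytest.approx(1.0)

    # weighted-least-squares oracle on random effects
    betas = rng.normal(0.03, 0.01, n)
    variances = rng.uniform(0.003, 0.006, n) ** 2
    out = cluster_t2d_effects(betas, variances, model)
    w = 1 / variances
    C = model.assignment_matrix()
    Xw = C * w[:, None]
    gamma_oracle = np.linalg.solve(Xw.T @ C, Xw.T @ betas)
    np.testing.assert_allclose(out["gamma"], gamma_oracle, atol=1e-10)


def test_t2d_effect_contrast_recovers_planted_or_difference():
    """Two groups of signals with mean ORs 1.033 and 1.028 at SE 0.004."""
    rng = np.random.default_rng(11)
    n_per = 650
    b_rep = rng.normal(np.log(1.033), 0.004, n_per)
    b_nov = rng.normal(np.log(1.028), 0.004, n_per)
    betas = np.r_[b_rep, b_nov]
    variances = np.full(2 * n_per, 0.004**2)
    X = np.vstack([SIGN_CENTROIDS[0] + 0.1 * rng.standard_normal(10)
                   for _ in range(n_per)] +
                  [SIGN_CENTROIDS[1] + 0.1 * rng.standard_normal(10)
                   for _ in range(n_per)])
    model = impute_kmeans(_zmatrix(X), 2, seed=0)
    flags = np.r_[np.ones(n_per, bool), np.zeros(n_per, bool)]
    out = cluster_t2d_effects(betas, variances, model, reported_flags=flags)
    planted = np.log(1.033) - np.log(1.028)
    c = out["contrast"]
    assert abs(c["difference"] - planted) < 2 * c["se"]
    assert c["p"] < 0.05


def test_axis_anova_errors_and_power():
    X = np.vstack([SIGN_CENTROIDS[c] for c in [0] * 50 + [1] * 50])
    X = X + 0.2 * np.random.default_rng(0).standard_normal(X.shape)
    model = impute_kmeans(_zmatrix(X), 2, seed=0)
    rng = np.random.default_rng(1)
    z_null = rng.standard_normal(100)
    res = cluster_axis_anova(z_null, model)
    assert res.loc[0, "P"] > 0.001  # no planted difference

    z_shift = z_null + (model.labels == 0) * 1.0
    res2 = cluster_axis_anova(z_shift, model)
    assert res2.loc[0, "P"] < 1e-4

    m1 = impute_kmeans(_zmatrix(X), 1, seed=0)
    with pytest.raises(ValueError):
        cluster_axis_anova(z_null, m1)


def test_axis_anova_null_calibration():
    X = np.vstack([SIGN_CENTROIDS[c] for c in [0, 1, 2] * 30])
    X = X + 0.3 * np.random.default_rng(3).standard_normal(X.shape)
    model = impute_kmeans(_zmatrix(X), 3, seed=0)
    rng = np.random.default_rng(4)
    n_rep = 400
    rej = 0
    for _ in range(n_rep):
        z = rng.standard_normal(90)
        p = cluster_axis_anova(z, model).loc[0, "P"]
        rej += p < 0.05
    rate = rej / n_rep
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)
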
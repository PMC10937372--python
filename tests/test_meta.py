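"""Meta-regression engine: axes, heterogeneity partition, follow-up stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mameta.meta import (
    AxisCoordinates,
    DegenerateAxesError,
    axis_association_zscores,
    binomial_enrichment_test,
    bmi_adjusted_meta,
    bonferroni_threshold,
    classical_mds,
    compute_axes,
    fixed_effects_meta,
    genomic_control_lambda,
    meta_regress_snv,
    run_meta_scan,
    study_distance_matrix,
)

from conftest import make_studies


def wls_oracle(X, y, w):
    """Brute-force weighted normal equations via sqrt-weight rescaling."""
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    rss = float(w @ resid**2)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, np.sqrt(np.diag(cov)), rss


# ---------------------------------------------------------------------------
# axes of genetic variation


def _uniform_study(sid, eaf_vec):
    n = len(eaf_vec)
    return {
        "SNV": [f"s{i}" for i in range(n)],
        "EA": ["A"] * n,
        "NEA": ["G"] * n,
        "EAF": list(eaf_vec),
        "BETA": [0.0] * n,
        "SE": [0.01] * n,
    }


def test_axes_two_group_offset_separates_on_first_axis():
    """Two EAF-shifted study groups land at two points; higher axes vanish."""
    lo = [0.2, 0.3, 0.4, 0.5]
    hi = [0.4, 0.5, 0.6, 0.7]
    studies = make_studies(
        {f"a{i}": _uniform_study(f"a{i}", lo) for i in range(3)}
        | {f"b{i}": _uniform_study(f"b{i}", hi) for i in range(3)}
    )
    axes = compute_axes(studies, n_axes=2)
    c1 = axes.coords[:, 0]
    assert np.ptp(np.sign(c1[:3])) == 0 and np.ptp(np.sign(c1[3:])) == 0
    assert np.sign(c1[0]) != np.sign(c1[3])
    assert axes.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)


def test_axes_degenerate_when_all_studies_identical():
    studies = make_studies(
        {f"s{i}": _uniform_study(f"s{i}", [0.25, 0.5, 0.75]) for i in range(5)}
    )
    with pytest.raises(DegenerateAxesError):
        compute_axes(studies, n_axes=2)


def test_axes_requires_enough_studies():
    studies = make_studies(
        {f"s{i}": _uniform_study(f"s{i}", [0.2, 0.5]) for i in range(4)}
    )
    with pytest.raises(ValueError, match="studies"):
        compute_axes(studies, n_axes=3)


def test_mds_embedding_matches_rank_k_oracle():
    """Scaled coordinates reconstruct distances as well as the best rank-2
    eigendecomposition of the double-centred matrix."""
    rng = np.random.default_rng(4)
    pts = rng.standard_normal((8, 5))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    coords, evals = classical_mds(D, 2)
    emb = coords * np.sqrt(np.maximum(evals, 0))
    # oracle: full eigendecomposition, top-2 reconstruction
    n = 8
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ D**2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    Y = V[:, order[:2]] * np.sqrt(w[order[:2]])
    D_emb = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
    D_oracle = np.sqrt(((Y[:, None] - Y[None]) ** 2).sum(-1))
    err_emb = np.linalg.norm(D - D_emb) / np.linalg.norm(D)
    err_oracle = np.linalg.norm(D - D_oracle) / np.linalg.norm(D)
    assert err_emb == pytest.approx(err_oracle, abs=1e-10)


def test_distance_matrix_excludes_ambiguous_and_aligns_alleles():
    """A/T SNVs are dropped; allele flips change neither distances."""
    base = {
        "SNV": ["s0", "s1", "s2"],
        "EA": ["A", "A", "A"],
        "NEA": ["G", "T", "G"],  # s1 is strand-ambiguous
        "EAF": [0.3, 0.5, 0.6],
        "BETA": [0.0] * 3,
        "SE": [0.01] * 3,
    }
    flipped = dict(base)
    flipped["EA"], flipped["NEA"] = ["G", "A", "G"], ["A", "T", "A"]
    flipped["EAF"] = [0.7, 0.5, 0.4]
    studies = make_studies({"u": base, "v": flipped})
    D, ids = study_distance_matrix(studies)
    assert D[0, 1] == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# per-SNV meta-regression


def test_meta_regression_perfect_linear_fit_has_zero_residual():
    rng = np.random.default_rng(0)
    axes = rng.standard_normal((8, 2))
    betas = 0.1 + axes @ np.array([0.3, -0.2])
    ses = np.full(8, 0.05)
    r = meta_regress_snv(betas, ses, axes)
    assert r.residual_het_stat == pytest.approx(0.0, abs=1e-10)
    assert r.residual_het_p == pytest.approx(1.0, abs=1e-9)


def test_meta_regression_homogeneous_effects_have_zero_ancestry_het():
    axes = np.random.default_rng(1).standard_normal((9, 3))
    betas = np.full(9, 0.12)
    ses = np.linspace(0.02, 0.1, 9)
    r = meta_regress_snv(betas, ses, axes)
    assert r.ancestry_het_stat == pytest.approx(0.0, abs=1e-12)


def test_meta_regression_matches_wls_oracle_and_q_decomposition():
    rng = np.random.default_rng(7)
    K = 10
    axes = rng.standard_normal((K, 3))
    betas = rng.normal(0.05, 0.08, K)
    ses = rng.uniform(0.02, 0.1, K)
    w = 1 / ses**2
    r = meta_regress_snv(betas, ses, axes)
    X = np.column_stack([np.ones(K), axes])
    bh, seh, rss_full = wls_oracle(X, betas, w)
    _, _, rss_int = wls_oracle(np.ones((K, 1)), betas, w)
    assert r.coefficients == pytest.approx(bh, rel=1e-8)
    assert r.coefficient_ses == pytest.approx(seh, rel=1e-8)
    assert r.assoc_stat == pytest.approx(float(w @ betas**2) - rss_full, rel=1e-8)
    assert r.ancestry_het_stat == pytest.approx(rss_int - rss_full, rel=1e-8)
    assert r.residual_het_stat == pytest.approx(rss_full, rel=1e-8)
    fe = fixed_effects_meta(betas, ses)
    assert r.ancestry_het_stat + r.residual_het_stat == pytest.approx(
        fe.q, rel=1e-8
    )
    assert r.assoc_df == 4 and r.ancestry_het_df == 3 and r.residual_het_df == 6


def test_meta_regression_singular_design_returns_none():
    axes = np.ones((8, 2))  # collinear with intercept
    r = meta_regress_snv(np.zeros(8), np.full(8, 0.1), axes)
    assert r is None


def test_bmi_adjustment_absorbs_bmi_driven_heterogeneity():
    """Effects purely linear in case BMI: adjusted ancestry het ~ 0 while the
    unadjusted statistic is large (axes built orthogonal to BMI)."""
    rng = np.random.default_rng(42)
    K = 12
    axes = rng.standard_normal((K, 2))
    # case BMI loads on axis 1 (ancestry-confounded) plus independent noise
    bmi_case = 31 + 2 * axes[:, 0] + rng.normal(0, 0.5, K)
    bmi_ctrl = 27 + rng.normal(0, 0.5, K)
    betas = 0.03 * (bmi_case - bmi_case.mean())
    ses = np.full(K, 0.01)
    unadj = meta_regress_snv(betas, ses, axes)
    adj = bmi_adjusted_meta(betas, ses, axes, bmi_case, bmi_ctrl)
    assert unadj.ancestry_het_stat > 100
    assert adj.ancestry_het_stat == pytest.approx(0.0, abs=1e-6)


def test_bmi_constant_columns_flagged_singular():
    axes = np.random.default_rng(3).standard_normal((10, 2))
    r = bmi_adjusted_meta(
        np.zeros(10), np.full(10, 0.1), axes,
        bmi_cases=np.full(10, 30.0), bmi_controls=np.full(10, 27.0),
    )
    assert r is None


def test_bmi_orthogonal_covariates_leave_het_p_unchanged():
    """BMI columns orthogonal (in the weight metric) to intercept, axes and
    effects leave the ancestry-correlated P value untouched."""
    rng = np.random.default_rng(5)
    K = 14
    ses = np.full(K, 0.05)  # equal weights -> Euclidean orthogonality suffices
    axes = rng.standard_normal((K, 2))
    betas = 0.05 + axes @ np.array([0.1, -0.05]) + rng.normal(0, 0.02, K)
    basis = np.column_stack([np.ones(K), axes, betas])
    Q, _ = np.linalg.qr(basis, mode="complete")
    bmi1, bmi2 = Q[:, 4], Q[:, 5]  # orthogonal complement directions
    unadj = meta_regress_snv(betas, ses, axes)
    adj = bmi_adjusted_meta(betas, ses, axes, bmi1, bmi2)
    assert adj.ancestry_het_p == pytest.approx(unadj.ancestry_het_p, abs=1e-6)


def test_allele_flip_invariance_of_meta_scan(studies_null):
    """Flipping EA/NEA with beta sign and EAF complement in some studies
    leaves every statistic unchanged."""
    import copy

    studies, _ = studies_null
    flipped = copy.deepcopy(studies)
    for st in flipped[::3]:
        t = st.table
        t["EA"], t["NEA"] = t["NEA"].copy(), t["EA"].copy()
        t["BETA"] = -t["BETA"]
        t["EAF"] = 1.0 - t["EAF"]
    a = run_meta_scan(studies, n_axes=2, min_studies=5).meta
    b = run_meta_scan(flipped, n_axes=2, min_studies=5).meta
    for col in ["P_ASSOC", "P_ANC_HET", "P_RES_HET", "STAT_ASSOC"]:
        np.testing.assert_allclose(a[col], b[col], rtol=1e-10)


# ---------------------------------------------------------------------------
# fixed-effects meta-analysis


def test_fixed_effects_closed_forms():
    single = fixed_effects_meta([0.2], [0.05])
    assert single.beta == pytest.approx(0.2, rel=1e-14)
    assert single.se == pytest.approx(0.05, rel=1e-14)

    r = fixed_effects_meta([0.0, 0.2], [0.1, 0.1])
    assert r.beta == pytest.approx(0.1)
    assert r.se == pytest.approx(0.1 / np.sqrt(2))
    assert r.q == pytest.approx(2.0)


def test_fixed_effects_matches_direct_formula_and_order_invariance():
    rng = np.random.default_rng(9)
    b = rng.normal(0, 0.1, 5)
    s = rng.uniform(0.02, 0.2, 5)
    r = fixed_effects_meta(b, s)
    w = 1 / s**2
    assert r.beta == pytest.approx(float(w @ b / w.sum()), rel=1e-12)
    perm = [3, 1, 4, 0, 2]
    r2 = fixed_effects_meta(b[perm], s[perm])
    assert r2.beta == pytest.approx(r.beta, rel=1e-14)
    assert r2.q == pytest.approx(r.q, rel=1e-12)


def test_zero_axes_meta_regression_equals_fixed_effects():
    rng = np.random.default_rng(12)
    b = rng.normal(0.05, 0.1, 8)
    s = rng.uniform(0.02, 0.2, 8)
    r = meta_regress_snv(b, s, np.empty((8, 0)))
    fe = fixed_effects_meta(b, s)
    assert r.coefficients[0] == pytest.approx(fe.beta, rel=1e-14)
    assert r.coefficient_ses[0] == pytest.approx(fe.se, rel=1e-14)
    assert r.residual_het_stat == pytest.approx(fe.q, rel=1e-12)


# ---------------------------------------------------------------------------
# follow-up statistics


def test_lambda_definition_and_null_and_scaling():
    assert genomic_control_lambda(np.full(101, 0.5)) == 1.0

    rng = np.random.default_rng(2)
    p = rng.uniform(size=100_000)
    assert genomic_control_lambda(p) == pytest.approx(1.0, abs=0.01)

    chi = stats.chi2.rvs(1, size=100_000, random_state=3) * 1.2
    p_inf = stats.chi2.sf(chi, 1)
    assert genomic_control_lambda(p_inf) == pytest.approx(1.2, abs=0.02)


def test_lambda_rejects_bad_input():
    with pytest.raises(ValueError):
        genomic_control_lambda([])
    with pytest.raises(ValueError):
        genomic_control_lambda([0.5, 0.0])


def _meta_result_with_slopes(slopes, ses):
    from mameta.meta import MetaResult

    coeff = np.r_[0.1, slopes]
    se = np.r_[0.01, ses]
    return MetaResult(
        snv="s", coefficients=coeff, coefficient_ses=se,
        assoc_stat=1, assoc_df=4, assoc_p=0.5,
        ancestry_het_stat=0, ancestry_het_df=3, ancestry_het_p=1,
        residual_het_stat=0, residual_het_df=5, residual_het_p=1,
        n_studies=10, n_axes=len(slopes),
    )


def test_axis_zscores_and_strongest_axis():
    mr = _meta_result_with_slopes([0.02, -0.04, 0.01], [0.01] * 3)
    z, strongest = axis_association_zscores(mr, pooled_beta=0.3)
    np.testing.assert_allclose(z, [2, -4, 1])
    assert strongest == 1  # axis 2

    z2, s2 = axis_association_zscores(mr, pooled_beta=-0.3)
    np.testing.assert_allclose(z2, [-2, 4, -1])
    assert s2 == 1


def test_bonferroni_thresholds_round_to_printed_values():
    assert bonferroni_threshold(0.05, 1289) == 3.9e-5
    assert bonferroni_threshold(0.05, 222) == 0.00023
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.05, 1289, rounded=False) == 0.05 / 1289


def test_binomial_enrichment_matches_tail_summation():
    p, expected = binomial_enrichment_test(0, 100, 0.01)
    assert p == 1.0 and expected == pytest.approx(1.0)

    alpha = 0.05 / 1289
    p4, exp4 = binomial_enrichment_test(4, 1289, alpha)
    # direct summation oracle
    k = np.arange(4, 1290)
    oracle = float(np.sum(stats.binom.pmf(k, 1289, alpha)))
    assert p4 == pytest.approx(oracle, rel=1e-12)
    assert exp4 == pytest.approx(0.05, rel=1e-12)  # "less than one signal"


def test_null_meta_regression_p_values_are_uniform():
    """Kolmogorov-Smirnov check of all three tests under the null."""
    rng = np.random.default_rng(21)
    K, n_snv = 12, 4000
    axes = rng.standard_normal((K, 2))
    ses = rng.uniform(0.02, 0.08, (n_snv, K))
    pvals = np.empty((n_snv, 3))
    for i in range(n_snv):
        b = rng.normal(0, ses[i])
        r = meta_regress_snv(b, ses[i], axes)
        pvals[i] = [r.assoc_p, r.ancestry_het_p, r.residual_het_p]
    crit = 1.628 / np.sqrt(n_snv)  # 1% critical value
    for j in range(3):
        d = stats.kstest(pvals[:, j], "uniform").statistic
        assert d < crit
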
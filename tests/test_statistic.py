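import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from triotau import (
    MomentInputs,
    TraitSpec,
    TrioCohort,
    association_test,
    centered_trait_scores,
    chi_square_test,
    conditional_moments,
    estimate_maf_from_parents,
    expected_log_trio_count,
    pairwise_ld_r2,
    region_scan,
    trio_moment_oracle,
    u_statistic_direct,
    u_statistic_fast,
    variance_log_trio_count,
)
from conftest import random_cohort

P_GRID = (0.01, 0.03, 0.05, 0.1, 0.25, 0.4)


def test_simplified_form_equals_pairwise_double_sum(rng):
    """The O(nmq) single-sum form equals the brute-force pairwise U-statistic."""
    for _ in range(60):
        cohort = random_cohort(rng)
        fast = u_statistic_fast(cohort)
        direct = u_statistic_direct(cohort)
        np.testing.assert_allclose(fast, direct, rtol=1e-10, atol=1e-12)


def test_u_statistic_zero_for_identical_traits(rng):
    t = np.tile([[1.0, 2.0]], (5, 1))
    g = rng.integers(0, 3, size=(5, 3))
    cohort = TrioCohort(g, g, g, t, t, t, TraitSpec(("quantitative", "ordinal")))
    np.testing.assert_allclose(u_statistic_fast(cohort), 0.0, atol=1e-12)


def test_u_statistic_scales_with_quantitative_traits(rng):
    cohort = random_cohort(rng, kinds=("quantitative",))
    doubled = TrioCohort(
        cohort.father_genotypes, cohort.mother_genotypes, cohort.child_genotypes,
        2 * cohort.father_traits, 2 * cohort.mother_traits, 2 * cohort.child_traits,
        cohort.trait_spec,
    )
    np.testing.assert_allclose(
        u_statistic_fast(doubled), 2 * u_statistic_fast(cohort), rtol=1e-10
    )


def test_expected_log_trio_count_printed_value():
    # p = 1/2, n = 100: 3 log 100 - 4.5 log 2
    expected = 3 * np.log(100) - 4.5 * np.log(2)
    assert expected_log_trio_count(0.5, 100) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("p", P_GRID)
def test_closed_form_mean_matches_enumeration(p):
    mean, _ = trio_moment_oracle(p, n=100)
    assert expected_log_trio_count(p, 100) == pytest.approx(mean, abs=1e-10)


@pytest.mark.parametrize("p", P_GRID)
def test_closed_form_variance_matches_enumeration(p):
    _, var = trio_moment_oracle(p)
    assert variance_log_trio_count(p) == pytest.approx(var, abs=1e-10)


def test_moment_formulas_symmetry_and_domain():
    assert expected_log_trio_count(0.3, 50) == pytest.approx(
        expected_log_trio_count(0.7, 50), rel=1e-12
    )
    grid = np.linspace(0.001, 0.5, 200)
    assert np.all(variance_log_trio_count(grid) >= 0)
    for bad in (0.0, 1.0, -0.1):
        with pytest.raises(ValueError):
            expected_log_trio_count(bad, 10)
        with pytest.raises(ValueError):
            variance_log_trio_count(bad)


def test_oracle_child_marginal_is_hwe():
    from triotau.statistic import _child_probs, _hwe_probs

    for p in (0.05, 0.3):
        probs = _hwe_probs(p)
        child = np.zeros(3)
        for gf in range(3):
            for gm in range(3):
                child += probs[gf] * probs[gm] * _child_probs(gf, gm)
        np.testing.assert_allclose(child, probs, atol=1e-12)
        assert child.sum() == pytest.approx(1.0)


def test_conditional_mean_vanishes_for_shared_maf(rng):
    for _ in range(10):
        cohort = random_cohort(rng)
        scores = centered_trait_scores(cohort)
        maf = MomentInputs(rng.uniform(0.03, 0.05, cohort.m), cohort.n)
        e_u, var_u = conditional_moments(scores, maf)
        np.testing.assert_allclose(e_u, 0.0, atol=1e-10)
        np.testing.assert_allclose(var_u, var_u.T)
        assert np.linalg.eigvalsh(var_u).min() > -1e-10


def test_conditional_variance_hand_computation():
    # single quantitative trait, identical per-role scores (-1, 0, 1), one
    # locus at p = 0.25: var_u = (2/(n-1))^2 * Var_term * S with S the
    # outer-product sum of the score rows
    cohort = TrioCohort(
        np.zeros((3, 1), int), np.zeros((3, 1), int), np.zeros((3, 1), int),
        [[1.0], [2.0], [3.0]], [[1.0], [2.0], [3.0]], [[1.0], [2.0], [3.0]],
        TraitSpec(("quantitative",)),
    )
    scores = centered_trait_scores(cohort)
    e_u, var_u = conditional_moments(scores, MomentInputs([0.25], 3))
    s = scores.scores.T @ scores.scores
    expected = (2 / 2) ** 2 * variance_log_trio_count(0.25) * s
    np.testing.assert_allclose(var_u, expected, rtol=1e-12)


def test_conditional_variance_quadratic_in_trait_scale(rng):
    cohort = random_cohort(rng, kinds=("quantitative",))
    maf = MomentInputs(rng.uniform(0.03, 0.05, cohort.m), cohort.n)
    _, v1 = conditional_moments(centered_trait_scores(cohort), maf)
    scaled = TrioCohort(
        cohort.father_genotypes, cohort.mother_genotypes, cohort.child_genotypes,
        3 * cohort.father_traits, 3 * cohort.mother_traits, 3 * cohort.child_traits,
        cohort.trait_spec,
    )
    _, v9 = conditional_moments(centered_trait_scores(scaled), maf)
    np.testing.assert_allclose(v9, 9 * v1, rtol=1e-10)


def test_chi_square_zero_at_the_mean():
    var = np.eye(4)
    chi2, df, p = chi_square_test(np.ones(4), np.ones(4), var)
    assert chi2 == 0.0 and df == 4 and p == pytest.approx(1.0)


def test_chi_square_matches_dense_solve(rng):
    a = rng.normal(size=(6, 6))
    var = a @ a.T + 6 * np.eye(6)  # full rank
    u = rng.normal(size=6)
    chi2, df, p = chi_square_test(u, np.zeros(6), var)
    expected = u @ np.linalg.solve(var, u)
    assert df == 6
    assert chi2 == pytest.approx(expected, abs=1e-8)
    assert p == pytest.approx(float(chi2_dist.sf(expected, 6)), abs=1e-10)


@pytest.mark.parametrize("rank", [1, 2, 4])
def test_chi_square_rank_deficient_df(rng, rank):
    vs = rng.normal(size=(rank, 6))
    var = vs.T @ vs
    u = vs.sum(axis=0)
    _, df, _ = chi_square_test(u, np.zeros(6), var)
    assert df == rank


def test_chi_square_degenerate_variance_errors():
    with pytest.raises(ValueError):
        chi_square_test(np.zeros(3), np.zeros(3), np.zeros((3, 3)))


def test_chi_square_invariant_to_block_and_locus_permutation(rng):
    """The quadratic form ignores the (arbitrary) ordering conventions."""
    cohort = random_cohort(rng, n=8, m=4, kinds=("binary", "ordinal"))
    maf = rng.uniform(0.05, 0.3, cohort.m)
    base = association_test(cohort, maf=maf)
    # permute loci
    perm = rng.permutation(cohort.m)
    shuffled = cohort.subset_loci(perm)
    res_l = association_test(shuffled, maf=maf[perm])
    assert res_l.chi2 == pytest.approx(base.chi2, rel=1e-10)
    assert res_l.df == base.df
    # permute the 3q blocks of U and Var(U|T) directly
    scores = centered_trait_scores(cohort)
    u = u_statistic_fast(cohort, scores)
    e_u, var_u = conditional_moments(scores, MomentInputs(maf, cohort.n))
    bperm = rng.permutation(u.size)
    chi2_b, df_b, _ = chi_square_test(
        u[bperm], e_u[bperm], var_u[np.ix_(bperm, bperm)]
    )
    assert chi2_b == pytest.approx(base.chi2, rel=1e-10)
    assert df_b == base.df


def test_estimate_maf_from_parents_examples():
    t = np.zeros((2, 1))
    spec = TraitSpec(("binary",))

    def cohort(gf, gm):
        g = np.zeros((2, 3), dtype=int)
        return TrioCohort(np.array(gf), np.array(gm), g, t, t, t, spec)

    c = cohort([[1, 0, 2], [0, 0, 2]], [[0, 0, 2], [0, 0, 2]])
    p_hat, keep = estimate_maf_from_parents(c)
    np.testing.assert_allclose(p_hat, [0.125, 0.0, 1.0])
    np.testing.assert_array_equal(keep, [True, False, False])


def test_region_scan_windowing(rng):
    cohort = random_cohort(rng, n=30, m=93, kinds=("quantitative",))
    maf = rng.uniform(0.03, 0.05, 93)
    results = region_scan(cohort, window=40, maf=maf)
    assert [r.region for r in results] == [(1, 40), (41, 80), (81, 93)]
    assert [r.n_loci_used for r in results] == [40, 40, 13]
    # window >= m collapses to a single region identical to one direct test
    single = region_scan(cohort, window=200, maf=maf)
    assert len(single) == 1
    direct = association_test(cohort, maf=maf)
    assert single[0].chi2 == pytest.approx(direct.chi2, rel=1e-12)


def test_ld_r2_properties(rng):
    g = rng.integers(0, 3, size=(200, 4)).astype(float)
    g[:, 1] = g[:, 0]          # identical columns
    g[:, 2] = 2 - g[:, 0]      # flipped coding
    r2 = pairwise_ld_r2(g)
    assert r2[0, 1] == pytest.approx(1.0)
    assert r2[0, 2] == pytest.approx(1.0)  # invariant to allele recoding
    np.testing.assert_allclose(r2, r2.T)
    np.testing.assert_allclose(np.diag(r2), 1.0)
    # monomorphic column: undefined off-diagonal entries
    g[:, 3] = 1.0
    r2 = pairwise_ld_r2(g)
    assert np.isnan(r2[0, 3]) and r2[3, 3] == 1.0


def test_ld_r2_independent_loci_near_zero(rng):
    g = rng.binomial(2, 0.3, size=(10000, 5)).astype(float)
    r2 = pairwise_ld_r2(g)
    off = r2[~np.eye(5, dtype=bool)]
    assert np.nanmax(off) < 0.01
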
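"""Unit and property tests of the association statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import xlogy

import poolfreqtest as pft
from poolfreqtest import LocusTable
from poolfreqtest.association import (
    TEST_NAMES,
    cmh_batch,
    cmh_plus_woolf_call,
    cmh_test,
    fit_glm_binomial_m1,
    fit_glm_binomial_m2,
    fit_glm_quasibinomial,
    fit_lm,
    g_test,
    g_test_batch,
    glm_binomial_m1_batch,
    glm_binomial_m2_batch,
    glm_quasibinomial_batch,
    handle_zero_cells,
    heterogeneity_veto,
    lm_batch,
    run_tests,
    woolf_test,
)

# ---------------------------------------------------------------------------
# worked example: the motivating inconsistent table
# ---------------------------------------------------------------------------

class TestWorkedExample:
    def test_cmh_statistic_and_common_odds_ratio(self, table1):
        res = cmh_test(table1)
        assert res.statistic == pytest.approx(55.66, abs=0.005)
        assert res.df == 1
        assert res.effect == pytest.approx(6.98, abs=0.005)
        assert res.p_main < 1e-4

    def test_woolf_detects_the_heterogeneity(self, table1):
        res = woolf_test(table1)
        assert res.df == 2
        assert res.p_main < 0.05

    def test_combined_call_vetoes_the_locus(self, table1):
        assert cmh_plus_woolf_call(table1, alpha=0.05) == 1.0


# ---------------------------------------------------------------------------
# zero-cell handling
# ---------------------------------------------------------------------------

def test_zero_rule_identity_without_zeros(table1):
    out = handle_zero_cells(table1)
    np.testing.assert_array_equal(out.counts_a, table1.counts_a)


@pytest.mark.parametrize("mode", ["all_cells_plus1", "per_count_plus1"])
def test_zero_rule_increments_every_count(mode):
    table = LocusTable(
        counts_a=np.array([[0, 5], [3, 4], [2, 2]]),
        coverage=np.array([[10, 10], [10, 10], [10, 10]]),
    )
    out = handle_zero_cells(table, mode=mode)
    np.testing.assert_array_equal(out.counts_a, table.counts_a + 1)
    np.testing.assert_array_equal(out.coverage, table.coverage + 2)


def test_zero_rule_rejects_unknown_mode(table1):
    with pytest.raises(ValueError):
        handle_zero_cells(table1, mode="haldane")


# ---------------------------------------------------------------------------
# CMH / Woolf properties
# ---------------------------------------------------------------------------

def test_cmh_symmetric_strata_give_unit_odds_ratio():
    table = LocusTable(
        counts_a=np.full((3, 2), 10), coverage=np.full((3, 2), 20)
    )
    res = cmh_test(table)
    assert res.effect == pytest.approx(1.0)
    assert res.p_main == pytest.approx(1.0)


def test_cmh_invariant_to_swapping_rows_and_columns(random_tables):
    for t in random_tables[:10]:
        stat, _, _ = cmh_batch(t.counts_a[None], t.coverage[None])
        swapped_a = (t.coverage - t.counts_a)[:, ::-1]
        stat2, _, _ = cmh_batch(swapped_a[None], t.coverage[:, ::-1][None])
        assert stat2[0] == pytest.approx(stat[0], rel=1e-12)


def test_woolf_zero_for_homogeneous_odds_ratios():
    table = LocusTable(
        counts_a=np.array([[20, 10]] * 3), coverage=np.array([[30, 30]] * 3)
    )
    res = woolf_test(table)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_main == pytest.approx(1.0)


def test_woolf_needs_two_strata():
    table = LocusTable(counts_a=np.array([[5, 6]]), coverage=np.array([[10, 10]]))
    with pytest.raises(ValueError):
        woolf_test(table)


def test_veto_rule_pass_through_and_veto():
    assert heterogeneity_veto(0.001, 0.5, 0.05) == 0.001
    assert heterogeneity_veto(0.001, 0.01, 0.05) == 1.0
    out = heterogeneity_veto(np.array([0.001, 0.2]), np.array([0.5, 0.01]))
    np.testing.assert_allclose(out, [0.001, 1.0])


# ---------------------------------------------------------------------------
# G-test
# ---------------------------------------------------------------------------

def test_g_zero_for_identical_cells():
    table = LocusTable(counts_a=np.full((3, 2), 7), coverage=np.full((3, 2), 20))
    res = g_test(table)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_main == pytest.approx(1.0)


def test_g_partition_additivity(random_tables):
    for t in random_tables:
        res = g_test_batch(t.counts_a[None], t.coverage[None])
        assert res["g_pooled"][0] + res["g_het"][0] == pytest.approx(
            res["g_total"][0], abs=1e-10
        )


def _g_brute_force(a, b, c, d):
    """G for one 2x2 table as twice the multinomial log-likelihood-ratio of the
    saturated model over the independence model."""
    n = a + b + c + d
    obs = np.array([a, b, c, d], dtype=float)
    p_sat = obs / n
    row = np.array([a + b, a + b, c + d, c + d], dtype=float) / n
    col = np.array([a + c, b + d, a + c, b + d], dtype=float) / n
    ll_sat = xlogy(obs, p_sat).sum()
    ll_ind = xlogy(obs, row * col).sum()
    return 2.0 * (ll_sat - ll_ind)


def test_g_per_stratum_matches_brute_force_likelihood(random_tables):
    for t in random_tables:
        res = g_test_batch(t.counts_a[None], t.coverage[None])
        g_total = 0.0
        for r in range(t.k):
            a = t.counts_a[r, 0]
            b = t.coverage[r, 0] - a
            c = t.counts_a[r, 1]
            d = t.coverage[r, 1] - c
            g_total += _g_brute_force(a, b, c, d)
        assert res["g_total"][0] == pytest.approx(g_total, abs=1e-8)


# ---------------------------------------------------------------------------
# GLMs / LM behaviour
# ---------------------------------------------------------------------------

def _identical_cells_table(k=3, count=7, cov=20):
    return LocusTable(
        counts_a=np.full((k, 2), count), coverage=np.full((k, 2), cov)
    )


def test_glm_m1_null_on_identical_cells():
    res = fit_glm_binomial_m1(_identical_cells_table())
    assert res.p_main == pytest.approx(1.0)
    assert res.effect == pytest.approx(0.0, abs=1e-12)


def test_glm_m1_needs_replication():
    with pytest.raises(ValueError):
        fit_glm_binomial_m1(_identical_cells_table(k=1))


def test_glm_m1_saturated_decomposition(random_tables):
    # the four sequential deviance drops reconstruct the null deviance exactly
    # because the full interaction model is saturated
    for t in random_tables[:10]:
        res = glm_binomial_m1_batch(t.counts_a[None], t.coverage[None])
        total = (
            res["dev_treatment"][0]
            + res["dev_replicate"][0]
            + res["dev_interaction"][0]
        )
        assert total == pytest.approx(res["dev_null"][0], abs=1e-6)


def test_glm_m2_null_and_sign_symmetry():
    res = fit_glm_binomial_m2(_identical_cells_table())
    assert res.p_main == pytest.approx(1.0)
    assert res.effect == pytest.approx(0.0, abs=1e-12)

    rng = np.random.default_rng(5)
    cov = rng.integers(30, 200, size=(4, 2))
    ca = np.clip(rng.binomial(cov, 0.3), 1, cov - 1)
    t = LocusTable(counts_a=ca, coverage=cov)
    swapped = LocusTable(counts_a=ca[:, ::-1], coverage=cov[:, ::-1])
    r1, r2 = fit_glm_binomial_m2(t), fit_glm_binomial_m2(swapped)
    assert r2.effect == pytest.approx(-r1.effect, rel=1e-12)
    assert r2.p_main == pytest.approx(r1.p_main, rel=1e-12)


def test_quasibinomial_matches_binomial_point_estimates(random_tables):
    for t in random_tables[:10]:
        m2 = glm_binomial_m2_batch(t.counts_a[None], t.coverage[None])
        q = glm_quasibinomial_batch(t.counts_a[None], t.coverage[None])
        assert q["coef"][0] == pytest.approx(m2["coef"][0], rel=1e-12)


def test_quasibinomial_needs_residual_df():
    with pytest.raises(ValueError):
        fit_glm_quasibinomial(_identical_cells_table(k=1))


def test_quasibinomial_dispersion_near_one_for_binomial_data():
    # counts generated exactly binomial: phi estimates average 1
    rng = np.random.default_rng(17)
    n_loci, k, ct = 4000, 4, 120
    pi = rng.uniform(0.2, 0.8, size=n_loci)
    cov = np.full((n_loci, k, 2), ct)
    ca = rng.binomial(ct, pi[:, None, None], size=(n_loci, k, 2))
    q = glm_quasibinomial_batch(ca, cov)
    se = q["dispersion"].std() / np.sqrt(n_loci)
    assert q["dispersion"].mean() == pytest.approx(1.0, abs=3 * se + 0.02)


def test_lm_closed_form_matches_textbook_ols(random_tables):
    for t in random_tables[:10]:
        res = lm_batch(t.counts_a[None], t.coverage[None])
        f = (t.counts_a / t.coverage).reshape(-1)
        x = np.tile([0.0, 1.0], t.k)
        slope = np.cov(x, f, ddof=1)[0, 1] / np.var(x, ddof=1)
        resid = f - f.mean() - slope * (x - x.mean())
        se = np.sqrt(resid @ resid / (2 * t.k - 2) / ((x - x.mean()) @ (x - x.mean())))
        assert res["slope"][0] == pytest.approx(slope, abs=1e-10)
        assert res["se"][0] == pytest.approx(se, abs=1e-10)


def test_lm_degenerate_cases():
    # equal frequencies everywhere: slope 0, p = 1
    res = fit_lm(_identical_cells_table())
    assert res.p_main == pytest.approx(1.0)
    # distinct group means with zero residual variance: flagged, p missing
    t = LocusTable(
        counts_a=np.array([[12, 8], [12, 8]]), coverage=np.full((2, 2), 20)
    )
    res = fit_lm(t)
    assert res.effect == pytest.approx(-0.2)
    assert "degenerate_zero_residual" in res.flags
    assert np.isnan(res.p_main)


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def test_run_tests_produces_all_rows(random_tables):
    t = random_tables[0]
    df = run_tests(t.counts_a[None], t.coverage[None])
    assert len(df) == len(TEST_NAMES)
    assert set(df["test"]) == set(TEST_NAMES)
    assert df["p_main"].between(0, 1).all()


def test_run_tests_matches_per_locus_api(random_tables):
    t = random_tables[1]
    df = run_tests(t.counts_a[None], t.coverage[None]).set_index("test")
    assert df.loc["cmh", "statistic"] == pytest.approx(cmh_test(t).statistic)
    assert df.loc["glm_quasi", "p_main"] == pytest.approx(
        fit_glm_quasibinomial(t).p_main
    )
    assert df.loc["lm", "effect"] == pytest.approx(fit_lm(t).effect)
    assert df.loc["gtest", "p_het"] == pytest.approx(g_test(t).p_het)


def test_run_tests_rejects_unknown_name(random_tables):
    t = random_tables[0]
    with pytest.raises(ValueError):
        run_tests(t.counts_a[None], t.coverage[None], tests=("fisher",))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.integers(2, 5),
    st.integers(0, 2**31 - 1),
)
def test_all_p_values_in_unit_interval(k, seed):
    rng = np.random.default_rng(seed)
    cov = rng.integers(2, 300, size=(1, k, 2))
    ca = rng.integers(0, cov + 1)
    # keep the locus polymorphic overall (the simulator guarantees this)
    if ca.sum() == 0:
        ca[0, 0, 0] = 1
    if (cov - ca).sum() == 0:
        ca[0, 0, 0] -= 1
    df = run_tests(ca, cov)
    p = df[["p_main", "p_het"]].to_numpy(dtype=float)
    p = p[~np.isnan(p)]
    assert np.all((p >= 0) & (p <= 1))
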
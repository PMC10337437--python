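"""Contingency analysis and the undiagnosed-status logistic model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import carecascade as cc
from carecascade.associations import ContingencyTable
from carecascade.types import GeneratorParams


def _case_frame(rows):
    """Minimal case-level frame: (sex, age_group, undiagnosed) tuples."""
    records = []
    for i, (sex, age_group, undiag) in enumerate(rows):
        records.append(dict(
            participant_id=f"P{i}", household_id=f"H{i}",
            setting="hospital_based", age_years=45 if age_group == "40-49" else 65,
            age_group=age_group, sex=sex, education="primary",
            marital="married_or_with_spouse",
            **{f"asset_{j+1:02d}": 0 for j in range(20)},
            fbg_mg_dl=150.0, hba1c_pct=9.0,
            takes_t2d_drugs=False, takes_insulin=False,
            ever_tested_3y=not undiag, ever_told_t2d=not undiag,
            care_past_12m=False, advice_diet=False, advice_weight=False,
            advice_smoking=False, advice_exercise=False,
            provider_of_diagnosis="none" if undiag else "public"))
    return pd.DataFrame(records)


def _frame_from_2x2(a, b, c, d):
    """a/b: diagnosed male/female; c/d: undiagnosed male/female."""
    rows = ([("male", "60+", False)] * a + [("female", "60+", False)] * b
            + [("male", "60+", True)] * c + [("female", "60+", True)] * d)
    return _case_frame(rows)


def test_crosstab_cells_match_brute_force_counts(sim_df):
    cases = sim_df[cc.case_mask(sim_df)]
    undiag = cc.undiagnosed_mask(sim_df)
    for cov in ("sex", "age_group", "setting", "wealth_quintile"):
        tab = cc.crosstab(sim_df, cov).table
        for level in tab.index:
            sub = cases[cases[cov] == level]
            assert tab.loc[level, "diagnosed"] == int(
                (~undiag.loc[sub.index]).sum())
            assert tab.loc[level, "undiagnosed"] == int(
                undiag.loc[sub.index].sum())
        assert tab.sum().sum() == len(cases)


def test_single_level_covariate_gives_degenerate_partition():
    df = _frame_from_2x2(0, 10, 0, 6)   # all female
    tab = cc.crosstab(df, "sex")
    assert tab.table.shape == (1, 2)
    assert tuple(tab.column_margins) == (10, 6)
    with pytest.raises(cc.DegenerateInputError):
        cc.chi_square_test(tab)


def test_crosstab_requires_cases():
    df = _frame_from_2x2(1, 1, 1, 1)
    df["fbg_mg_dl"] = 90.0   # demote everyone to non-case
    with pytest.raises(cc.DegenerateInputError, match="no cases"):
        cc.crosstab(df, "sex")


def test_chi_square_identical_rows_gives_independence():
    tab = ContingencyTable("sex", pd.DataFrame(
        {"diagnosed": [30, 60], "undiagnosed": [10, 20]},
        index=["male", "female"]))
    stat, df_, p = cc.chi_square_test(tab)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df_ == 1
    assert p == pytest.approx(1.0)


def test_chi_square_warns_on_low_expected_counts():
    tab = ContingencyTable("sex", pd.DataFrame(
        {"diagnosed": [2, 40], "undiagnosed": [3, 35]},
        index=["male", "female"]))
    with pytest.warns(UserWarning, match="expected cell"):
        cc.chi_square_test(tab)


def permutation_pvalue(table, n_draws=20_000, seed=0):
    """Independent label-permutation oracle for the Pearson statistic.

    Expands the table to individual (row, column) labels, permutes the
    column labels conditional on both margins, and counts permuted Pearson
    statistics at least as large as the observed one.
    """
    obs = np.asarray(table, dtype=float)
    nr, nc = obs.shape
    n = int(obs.sum())
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    stat = ((obs - expected) ** 2 / expected).sum()
    rows = np.repeat(np.arange(nr), obs.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(nc), obs.sum(axis=0).astype(int))
    rng = np.random.default_rng(seed)
    # all permutations at once: argsort of random keys shuffles the labels
    keys = rng.random((n_draws, n))
    perms = cols[np.argsort(keys, axis=1)]
    flat = (np.arange(n_draws)[:, None] * (nr * nc)
            + rows[None, :] * nc + perms)
    counts = np.bincount(flat.ravel(), minlength=n_draws * nr * nc)
    tables = counts.reshape(n_draws, nr, nc).astype(float)
    stats_null = ((tables - expected) ** 2 / expected).sum(axis=(1, 2))
    return float((stats_null >= stat - 1e-12).mean())


def random_small_tables(n_tables=12, n_range=(250, 500), shape=(3, 2),
                        seed=123):
    """Seeded stream of small random tables with all expected counts >= 5.

    Totals of a few hundred keep the tables small relative to the survey's
    own cross-tabs while staying outside the heavy-discreteness regime where
    an exact conditional p-value cannot track the continuous chi-square
    approximation (at total 30 a 3x2 table with all expected counts >= 5
    must have perfectly balanced margins, and the permutation distribution
    carries point masses larger than 0.1).
    """
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_tables:
        p = rng.dirichlet(np.full(shape[0] * shape[1], 4.0))
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        t = rng.multinomial(n, p).reshape(shape)
        if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
            continue
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        if (expected >= 5).all():
            out.append(t)
    return out


def test_chi_square_close_to_permutation_oracle_small_tables():
    for t in random_small_tables(n_tables=6, seed=11):
        tab = ContingencyTable("x", pd.DataFrame(
            t, columns=["diagnosed", "undiagnosed"]))
        _, _, p = cc.chi_square_test(tab)
        p_perm = permutation_pvalue(t, n_draws=20_000, seed=5)
        assert abs(p - p_perm) <= 0.02


def test_fisher_matches_scipy_for_2x2():
    tab = ContingencyTable("sex", pd.DataFrame(
        {"diagnosed": [4, 20], "undiagnosed": [9, 7]},
        index=["male", "female"]))
    assert cc.fisher_test(tab) == pytest.approx(
        stats.fisher_exact(tab.table.values).pvalue)


def test_fisher_permutation_reasonable_for_3x2():
    t = np.array([[8, 4], [6, 7], [3, 2]])
    tab = ContingencyTable("marital", pd.DataFrame(
        t, columns=["diagnosed", "undiagnosed"]))
    p = cc.fisher_test(tab, seed=3)
    assert 0.0 < p <= 1.0
    p_oracle = permutation_pvalue(t, n_draws=20_000, seed=9)
    assert abs(p - p_oracle) <= 0.03


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------

def test_saturated_2x2_equals_cross_product_odds_ratio():
    a, b, c, d = 18, 41, 27, 30   # diagnosed m/f, undiagnosed m/f
    df = _frame_from_2x2(a, b, c, d)
    model = cc.fit_undiagnosed_model(df, covariates=["sex"], alpha=0.999)
    # odds(undiag | male) / odds(undiag | female)
    expected = (c / a) / (d / b)
    assert model.aor("sex", "male") == pytest.approx(expected, abs=1e-6)


def test_elimination_is_deterministic(sim_df):
    m1 = cc.fit_undiagnosed_model(sim_df)
    m2 = cc.fit_undiagnosed_model(sim_df)
    assert m1.elimination_trace == m2.elimination_trace
    assert m1.retained_blocks == m2.retained_blocks
    pd.testing.assert_frame_equal(m1.estimates, m2.estimates)


def test_default_planted_effects_retained_and_plausible(sim_df):
    # generated with the published adjusted odds ratios planted
    model = cc.fit_undiagnosed_model(sim_df)
    assert "age_group" in model.retained_blocks
    assert "sex" in model.retained_blocks
    lo, hi = model.ci("age_group", "40-49")
    assert lo <= 3.2 <= hi
    assert lo < hi
    assert model.aor("age_group", "60+") == 1.0   # reference pinned


def test_blocks_significant_at_strict_alpha_also_at_looser(sim_df):
    pvals = cc.block_pvalues(sim_df)
    strict = {b for b, p in pvals.items() if p < 0.05}
    loose = {b for b, p in pvals.items() if p < 0.10}
    assert strict <= loose


def test_wald_and_lrt_elimination_agree_on_strong_effects(sim_df):
    lrt = cc.fit_undiagnosed_model(sim_df, test="lrt")
    wald = cc.fit_undiagnosed_model(sim_df, test="wald")
    assert "age_group" in lrt.retained_blocks
    assert "age_group" in wald.retained_blocks


def test_perfect_separation_detected():
    # age 40-49 perfectly predicts undiagnosed status
    rows = ([("female", "40-49", True)] * 30
            + [("female", "60+", False)] * 30
            + [("male", "60+", True)] * 15 + [("male", "60+", False)] * 15)
    df = _case_frame(rows)
    with pytest.raises((cc.SeparationError, cc.ConvergenceError)):
        cc.fit_undiagnosed_model(df, covariates=["age_group", "sex"],
                                 alpha=0.999)


def test_no_outcome_variation_rejected():
    df = _frame_from_2x2(10, 10, 0, 0)
    with pytest.raises(cc.DegenerateInputError, match="variation"):
        cc.fit_undiagnosed_model(df, covariates=["sex"])


def test_unknown_covariate_rejected(sim_df):
    with pytest.raises(cc.ParameterError, match="unknown covariate"):
        cc.fit_undiagnosed_model(sim_df, covariates=["height"])
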
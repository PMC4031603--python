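import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from footroll.stats import (DegenerateTestError, MixedRmAnova, TrialTable,
                            UnimputableCellError, block_randomization,
                            check_assumptions, cohens_d, followup_tests,
                            impute_missing, median_difference_ci,
                            newman_keuls, rank_tests, rm_anova_interaction,
                            sample_size_rm_f)
from footroll.simulate import (TrialScenario, VariableSpec,
                               generate_trial_dataset)


def small_table(values_by_cell, var="y", kind="parametric"):
    """Build a TrialTable from {(group, timepoint): [values]} mappings."""
    rows = []
    counters = {}
    n_per_group = {g: max(len(v) for (gg, _), v in values_by_cell.items()
                          if gg == g)
                   for g in {g for g, _ in values_by_cell}}
    for (group, tp), vals in values_by_cell.items():
        for i, v in enumerate(vals):
            rows.append({"subject": f"{group[:1]}{i}", "group": group,
                         "timepoint": tp, var: v})
    return TrialTable(pd.DataFrame(rows), {var: kind})


# ---------------------------------------------------------------------------
# imputation

def test_complete_table_returned_unchanged():
    t = small_table({("control", "baseline"): [1.0, 2.0],
                     ("control", "week12"): [2.0, 3.0]})
    out = impute_missing(t)
    pd.testing.assert_frame_equal(out.data, t.data)


def test_parametric_missing_replaced_by_cell_mean():
    t = small_table({("control", "baseline"): [2.0, 4.0, np.nan]})
    out = impute_missing(t)
    assert out.data["y"].tolist() == [2.0, 4.0, 3.0]


def test_nonparametric_missing_replaced_by_cell_median():
    t = small_table({("control", "baseline"): [1.0, 2.0, 9.0, np.nan]},
                    kind="nonparametric")
    out = impute_missing(t)
    assert out.data["y"].tolist() == [1.0, 2.0, 9.0, 2.0]


def test_empty_cell_is_unimputable():
    t = small_table({("control", "baseline"): [np.nan, np.nan]})
    with pytest.raises(UnimputableCellError):
        impute_missing(t)


@pytest.mark.parametrize("seed", range(5))
def test_imputation_preserves_cell_means_and_observed_values(seed):
    table, _ = generate_trial_dataset(
        TrialScenario(variables=(VariableSpec("v", 50, 5, 0.3),),
                      missing_rate=0.15), seed=seed)
    out = impute_missing(table)
    obs = table.data["v"].notna()
    pd.testing.assert_series_equal(out.data.loc[obs, "v"],
                                   table.data.loc[obs, "v"])
    for (g, tp), sub in table.data.groupby(["group", "timepoint"],
                                           observed=True):
        before = sub["v"].mean()
        after = out.data[(out.data.group == g)
                         & (out.data.timepoint == tp)]["v"].mean()
        assert after == pytest.approx(before)


# ---------------------------------------------------------------------------
# assumption checks

def test_identical_cells_have_zero_levene_statistic():
    x = np.arange(10.0)
    rep = check_assumptions({"a": x, "b": x.copy()})
    assert rep.levene[0] == pytest.approx(0.0)


def test_normal_samples_rarely_flagged():
    rng = np.random.default_rng(11)
    flags = 0
    for _ in range(50):
        rep = check_assumptions({"a": rng.normal(0, 1, 60),
                                 "b": rng.normal(0, 1, 60)})
        flags += any(p <= 0.05 for _, p in rep.normality.values())
    assert flags <= 10  # >= 90 % of null replicates pass each cell


def test_gross_heteroscedasticity_detected():
    rng = np.random.default_rng(2)
    rep = check_assumptions({"a": rng.normal(0, 1, 30),
                             "b": rng.normal(0, 10, 30)})
    assert rep.levene[1] < 0.01


def test_too_few_observations_rejected():
    with pytest.raises(ValueError, match="fewer than 3"):
        check_assumptions({"a": np.array([1.0, 2.0]), "b": np.arange(5.0)})


# ---------------------------------------------------------------------------
# mixed rm-ANOVA

def toy_table(seed=42, n_per_group=4, effect=1.5):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_group):
        g = "control" if i < n_per_group else "intervention"
        for tp in ("baseline", "week12"):
            mu = 10 + (effect if (g == "intervention" and tp == "week12")
                       else 0)
            rows.append(dict(subject=f"s{i}", group=g, timepoint=tp,
                             y=rng.normal(mu, 2)))
    return TrialTable(pd.DataFrame(rows), {"y": "parametric"})


def test_additive_cell_means_give_zero_interaction():
    # group adds 2, time adds 3, no interaction
    t = small_table({
        ("control", "baseline"): [9.0, 10.0, 11.0],
        ("control", "week12"): [12.0, 13.0, 14.0],
        ("intervention", "baseline"): [11.0, 12.0, 13.0],
        ("intervention", "week12"): [14.0, 15.0, 16.0],
    })
    res = rm_anova_interaction(t, "y")
    f, *_ , p = res.terms["interaction"]
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_matches_independent_glm_to_six_decimals():
    pg = pytest.importorskip("pingouin")
    t = toy_table()
    res = rm_anova_interaction(t, "y")
    ref = pg.mixed_anova(data=t.data, dv="y", within="timepoint",
                         subject="subject", between="group")
    for term, source in (("group", "group"), ("time", "timepoint"),
                         ("interaction", "Interaction")):
        f, d1, d2, p = res.terms[term]
        row = ref[ref.Source == source].iloc[0]
        assert f == pytest.approx(row.F, abs=1e-6)
        assert p == pytest.approx(row.p_unc, abs=1e-6)
        assert (d1, d2) == (row.DF1, row.DF2)


def test_unbalanced_groups_match_glm_on_shared_terms():
    pg = pytest.importorskip("pingouin")
    table, _ = generate_trial_dataset(
        TrialScenario(variables=(VariableSpec("v", 100, 10, 0.5),),
                      missing_rate=0.0), seed=9)
    res = rm_anova_interaction(table, "v")
    d = table.data[table.data.timepoint.isin(["baseline", "week12"])]
    ref = pg.mixed_anova(data=d, dv="v", within="timepoint",
                         subject="subject", between="group")
    for term, source in (("group", "group"), ("interaction", "Interaction")):
        f, _, _, p = res.terms[term]
        row = ref[ref.Source == source].iloc[0]
        assert f == pytest.approx(row.F, abs=1e-6)
        assert p == pytest.approx(row.p_unc, abs=1e-6)


def test_interaction_power_at_design_effect_size():
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        table, _ = generate_trial_dataset(
            TrialScenario(variables=(VariableSpec("v", 100, 10, 0.8),),
                          missing_rate=0.0), seed=seed)
        res = rm_anova_interaction(table, "v")
        hits += res.p("interaction") < 0.05
    assert hits / n_rep >= 0.80


def test_incomplete_design_rejected():
    t = small_table({("control", "baseline"): [1.0, np.nan],
                     ("control", "week12"): [1.0, 2.0],
                     ("intervention", "baseline"): [1.0, 2.0],
                     ("intervention", "week12"): [1.0, 2.0]})
    with pytest.raises(ValueError, match="impute"):
        MixedRmAnova(t, "y")


def test_results_summary_table():
    res = MixedRmAnova(toy_table(), "y").fit()
    s = res.summary()
    assert list(s.source) == ["group", "time", "interaction"]
    assert ((s.p >= 0) & (s.p <= 1)).all()


# ---------------------------------------------------------------------------
# Newman–Keuls

def test_equal_means_yield_no_rejections():
    out = newman_keuls(np.array([5.0, 5.0, 5.0, 5.0]), mse=2.0, n=10, df=36)
    assert not out.significant.any()


def test_widely_spread_means_all_rejected_and_q_matches_hand_formula():
    means = np.array([0.0, 10.0, 25.0])
    out = newman_keuls(means, mse=1.0, n=9, df=24)
    assert out.significant.all()
    full = out[(out.level_low == "cell0") & (out.level_high == "cell2")].iloc[0]
    assert full.q == pytest.approx(25.0 / np.sqrt(1.0 / 9))
    assert full.span == 3


def test_containment_no_significant_subrange_inside_accepted_range():
    rng = np.random.default_rng(3)
    for _ in range(50):
        k = rng.integers(3, 7)
        means = rng.normal(0, rng.uniform(0.1, 3), k)
        out = newman_keuls(means, mse=1.0, n=8, df=40)
        order = np.argsort(means, kind="stable")
        labels = [f"cell{i}" for i in order]
        pos = {lab: i for i, lab in enumerate(labels)}
        sig = {(pos[r.level_low], pos[r.level_high]): r.significant
               for r in out.itertuples()}
        for (i, j), s in sig.items():
            if s:
                for a, b in ((i - 1, j), (i, j + 1)):
                    if (min(a, b) >= 0 and max(a, b) < k and (a, b) in sig):
                        assert sig[(a, b)], "significant subrange inside an " \
                            "accepted containing range"


def test_nonpositive_mse_rejected():
    with pytest.raises(ValueError, match="mse"):
        newman_keuls(np.array([1.0, 2.0]), mse=0.0, n=5, df=8)


# ---------------------------------------------------------------------------
# follow-up tests

def test_constant_values_give_zero_friedman_statistic():
    rows = []
    for i in range(6):
        for tp in ("baseline", "week12", "week24"):
            rows.append(dict(subject=f"s{i}", group="intervention",
                             timepoint=tp, y=3.0))
    t = TrialTable(pd.DataFrame(rows), {"y": "nonparametric"})
    res = followup_tests(t, "y")
    assert res.test == "friedman"
    assert res.statistic == 0.0 and res.p == 1.0


def test_rm_anova_f_matches_statsmodels_on_toy_table():
    from statsmodels.stats.anova import AnovaRM
    rng = np.random.default_rng(8)
    rows = []
    for i in range(4):
        for j, tp in enumerate(("baseline", "week12", "week24")):
            rows.append(dict(subject=f"s{i}", group="intervention",
                             timepoint=tp, y=rng.normal(5 + j, 1)))
    df = pd.DataFrame(rows)
    t = TrialTable(df, {"y": "parametric"})
    res = followup_tests(t, "y")
    ref = AnovaRM(df, "y", "subject", within=["timepoint"]).fit()
    assert res.statistic == pytest.approx(
        float(ref.anova_table["F Value"].iloc[0]), abs=1e-8)
    assert res.p == pytest.approx(
        float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-8)


def test_reverting_shift_detected_in_most_replicates():
    hits = 0
    for seed in range(40):
        table, _ = generate_trial_dataset(
            TrialScenario(variables=(VariableSpec("v", 100, 10, 0.8,
                                                  reverts=True),),
                          missing_rate=0.0), seed=seed)
        res = followup_tests(table, "v")
        hits += res.p < 0.05
    assert hits / 40 >= 0.80


def test_followup_requires_three_timepoints():
    t = toy_table()
    with pytest.raises(ValueError, match="week24"):
        followup_tests(t, "y")


# ---------------------------------------------------------------------------
# rank tests

def test_identical_samples_p_is_one():
    s, p = rank_tests([1, 2, 3], [1, 2, 3])
    assert p == 1.0


def test_separated_samples_exact_enumeration_value():
    s, p = rank_tests([1, 2, 3], [4, 5, 6])
    assert s == 0.0
    assert p == pytest.approx(0.1)  # 2 of the 20 orderings are as extreme


def test_all_zero_paired_differences_degenerate():
    with pytest.raises(DegenerateTestError):
        rank_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)


def test_large_sample_approximation_close_to_exact():
    rng = np.random.default_rng(21)
    for _ in range(10):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.8, 1, 10)
        _, p_exact = rank_tests(a, b)  # n=10: exact path
        p_approx = sps.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.02


# ---------------------------------------------------------------------------
# effect sizes

@pytest.mark.parametrize("m1, s1, m2, s2, d_expected, label", [
    (17.4, 5.4, 19.9, 3.7, 0.5, "medium"),     # heel TPP, c vs d
    (119.5, 43.7, 91.7, 21.4, 0.8, "large"),   # midfoot PP, c vs e
    (10.0, 2.0, 10.0, 3.0, 0.0, "small"),
])
def test_cohens_d_values_and_labels(m1, s1, m2, s2, d_expected, label):
    es = cohens_d(m1, s1, m2, s2)
    assert round(es.d, 1) == d_expected
    assert es.label == label


def test_cohens_d_symmetric_and_scale_invariant():
    a = cohens_d(17.4, 5.4, 19.9, 3.7)
    b = cohens_d(19.9, 3.7, 17.4, 5.4)
    assert a.d == pytest.approx(b.d)
    c = cohens_d(174.0, 54.0, 199.0, 37.0)
    assert c.d == pytest.approx(a.d)


def test_cohens_d_undefined_for_two_zero_sds():
    with pytest.raises(DegenerateTestError):
        cohens_d(1.0, 0.0, 2.0, 0.0)


# ---------------------------------------------------------------------------
# Hodges–Lehmann

def test_pure_shift_recovered():
    a = np.array([3.0, 1.0, 7.0, 5.0])
    est, _ = median_difference_ci(a, a + 3.0)
    assert est == pytest.approx(3.0)


def test_pairwise_difference_enumeration():
    est, _ = median_difference_ci([1.0, 2.0], [2.0, 4.0])
    assert est == pytest.approx(1.5)  # median of {0, 1, 2, 3}


def test_ci_covers_true_shift():
    rng = np.random.default_rng(13)
    covered = 0
    n_rep = 300
    for _ in range(n_rep):
        a = rng.normal(0, 1, 25)
        b = rng.normal(1.0, 1, 25)
        _, (lo, hi) = median_difference_ci(a, b)
        covered += lo <= 1.0 <= hi
    assert covered / n_rep >= 0.93


def test_insufficient_data_rejected():
    with pytest.raises(ValueError):
        median_difference_ci([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# randomization and sample size

def test_block_randomization_deterministic():
    assert block_randomization(100, seed=5) == block_randomization(100, seed=5)
    assert block_randomization(100, seed=5) != block_randomization(100, seed=6)


def test_prefix_imbalance_never_exceeds_eight():
    for seed in range(10):
        seq = block_randomization(1000, seed=seed)
        running = np.cumsum([1 if g == "control" else -1 for g in seq])
        assert np.abs(running).max() <= 8


def test_block_sizes_cover_one_to_eight():
    seen = set()
    for seed in range(100):
        _, sizes = block_randomization(40, seed=seed, return_blocks=True)
        seen.update(sizes)
    assert seen == set(range(1, 9))


def test_sample_size_self_consistent():
    from footroll.stats import _rm_f_power
    res = sample_size_rm_f(0.36, alpha=0.05, power=0.81)
    assert res.achieved_power >= 0.81
    assert _rm_f_power(res.n_total - 1, 0.36, 0.05, 2, 2, 0.5) < 0.81


def test_huge_effect_returns_minimum_design_size():
    res = sample_size_rm_f(10.0, alpha=0.05, power=0.50)
    assert res.n_total == 3  # two groups need at least one residual df


def test_loss_inflation_applied():
    res = sample_size_rm_f(0.36, loss_fraction=0.10)
    assert res.n_inflated == int(np.ceil(res.n_total / 0.9))
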
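import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pbsi.core import aggregate_pbsi, compute_pbsi
from pbsi.errors import AnalysisError
from pbsi.groups import (chi_square, compare_groups, demographics_table,
                         duration_split, exclude_outliers, iqr_keep_mask,
                         match_groups, tukey_kramer)
from pbsi.synthetic import simulate_cohort, spec_presets

from conftest import oracle_chi_square, oracle_iqr_keep, tiny_spec


# -- IQR outlier exclusion ---------------------------------------------------

def test_single_extreme_flagged():
    values = list(range(1, 11)) + [100]
    keep = iqr_keep_mask(values)
    assert list(keep) == oracle_iqr_keep(values)
    assert keep[:-1].all() and not keep[-1]


def test_no_extremes_nothing_flagged():
    rng = np.random.default_rng(0)
    values = np.clip(rng.standard_normal(50), -2, 2)
    assert iqr_keep_mask(values).all()


def test_degenerate_iqr_keeps_all():
    assert iqr_keep_mask([5.0] * 8).all()


def test_matches_oracle_random():
    rng = np.random.default_rng(1)
    for _ in range(50):
        values = rng.standard_t(df=3, size=rng.integers(5, 40))
        assert list(iqr_keep_mask(values)) == oracle_iqr_keep(list(values))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=5, max_size=40),
       st.floats(0.1, 50), st.floats(-1000, 1000))
def test_affine_equivariance(values, scale, shift):
    # round to keep magnitudes representable after the affine map, so the
    # check exercises the statistic rather than float absorption
    values = [round(v, 3) for v in values]
    before = iqr_keep_mask(values)
    after = iqr_keep_mask([scale * v + shift for v in values])
    assert list(before) == list(after)


def test_nans_kept():
    values = [1, 2, 3, 4, 5, np.nan, 100]
    keep = iqr_keep_mask(values)
    assert keep[5] and not keep[6]


def test_too_few_values_rejected():
    with pytest.raises(AnalysisError):
        iqr_keep_mask([1.0, 2.0, 3.0])


def test_exclusion_is_per_group_and_policy():
    idx = pd.Index([f"S{i}" for i in range(10)], name="subject_id")
    scores = pd.DataFrame({
        "group": ["A"] * 5 + ["B"] * 5,
        "raw_thickness": [1, 2, 3, 4, 100, 1, 2, 3, 4, 5],
        "raw_area": [1, 2, 3, 4, 5, 1, 2, 3, 4, 5],
    }, index=idx, dtype=object).astype({"raw_thickness": float, "raw_area": float})
    keep = exclude_outliers(scores, measures=["raw_thickness", "raw_area"])
    assert not keep.loc["S4", "raw_thickness"]
    assert keep.loc["S4", "raw_area"]          # per-measure: other column kept
    assert keep.drop("S4").all(axis=None)

    keep_lw = exclude_outliers(scores, measures=["raw_thickness", "raw_area"],
                               policy="listwise")
    assert not keep_lw.loc["S4"].any()


# -- matching ----------------------------------------------------------------

def _meta(ages_t, ages_c, sex_t=None, sex_c=None):
    n_t, n_c = len(ages_t), len(ages_c)
    ids = pd.Index([f"P{i}" for i in range(n_t)] + [f"C{i}" for i in range(n_c)],
                   name="subject_id")
    return pd.DataFrame({
        "group": ["SCZ"] * n_t + ["HC"] * n_c,
        "site": "s",
        "age": list(ages_t) + list(ages_c),
        "sex": (sex_t or [0] * n_t) + (sex_c or [0] * n_c),
    }, index=ids)


def test_identical_pools_fully_retained():
    ages = [25.0, 30.0, 35.0, 40.0]
    meta = _meta(ages, ages)
    retained = match_groups(meta, ["SCZ"], "HC", seed=0)
    assert len(retained) == len(meta)
    matched = meta.loc[retained]
    gap = matched.groupby("group")["age"].mean()
    assert gap["SCZ"] == pytest.approx(gap["HC"], abs=1e-12)


def test_matching_shrinks_age_gap():
    rng = np.random.default_rng(2)
    ages_t = rng.uniform(30, 50, 40)
    ages_c = rng.uniform(20, 45, 60)  # overlapping but younger pool
    meta = _meta(list(ages_t), list(ages_c))
    pre_gap = abs(ages_t.mean() - ages_c.mean())
    retained = match_groups(meta, ["SCZ"], "HC", seed=0)
    matched = meta.loc[retained]
    post_gap = abs(matched.loc[matched["group"] == "SCZ", "age"].mean()
                   - matched.loc[matched["group"] == "HC", "age"].mean())
    assert post_gap < pre_gap


def test_sex_strata_exact():
    meta = _meta([30.0] * 4, [30.0] * 4, sex_t=[0, 0, 1, 1], sex_c=[0, 1, 1, 1])
    retained = match_groups(meta, ["SCZ"], "HC", seed=0)
    matched = meta.loc[retained]
    controls = matched[matched["group"] == "HC"]
    assert (controls["sex"] == 0).sum() <= 1   # only one male control exists


def test_empty_stratum_warns():
    meta = _meta([30.0, 31.0, 29.0], [30.0, 31.0], sex_t=[1, 1, 0], sex_c=[1, 1])
    with pytest.warns(UserWarning, match="stratum"):
        match_groups(meta, ["SCZ"], "HC", seed=0)


def test_deterministic_given_seed():
    rng = np.random.default_rng(3)
    meta = _meta(list(rng.uniform(20, 50, 30)), list(rng.uniform(20, 50, 50)))
    r1 = match_groups(meta, ["SCZ"], "HC", seed=7)
    r2 = match_groups(meta, ["SCZ"], "HC", seed=7)
    assert list(r1) == list(r2)


def test_paper_like_matching_balance_100_seeds():
    ok = 0
    for seed in range(100):
        cohort = simulate_cohort(spec_presets("paper-like", seed=seed))
        meta = cohort.meta
        retained = match_groups(meta, ["recent", "chronic"], "HC", seed=seed)
        matched = meta.loc[retained]
        patients = matched[matched["group"] != "HC"]
        controls = matched[matched["group"] == "HC"]
        t_p = stats.ttest_ind(patients["age"], controls["age"]).pvalue
        counts = pd.crosstab(matched["group"] != "HC", matched["sex"]).to_numpy()
        chi_p = chi_square(counts)[1]
        ok += int(t_p > 0.05 and chi_p > 0.05)
    assert ok >= 90


# -- Tukey-Kramer and compare_groups ----------------------------------------

def test_tukey_reduces_to_t_test_at_k2():
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 20), rng.normal(0.4, 1, 20)
    values = np.concatenate([a, b])
    groups = np.array(["A"] * 20 + ["B"] * 20)
    tukey = tukey_kramer(values, groups)
    t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
    assert tukey.loc[0, "p_adj"] == pytest.approx(t_p, abs=1e-10)


def test_tukey_unbalanced_reduces_to_t_test_at_k2():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 31)
    tukey = tukey_kramer(np.concatenate([a, b]),
                         np.array(["A"] * 12 + ["B"] * 31))
    t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
    assert tukey.loc[0, "p_adj"] == pytest.approx(t_p, abs=1e-10)


def test_tukey_identical_means_zero_noise():
    values = np.tile([1.0, 2.0, 3.0], 3)
    groups = np.repeat(["A", "B", "C"], 3)
    # same values in every group -> all pairwise differences zero
    tukey = tukey_kramer(np.concatenate([[1, 2, 3]] * 3), groups)
    assert np.allclose(tukey["diff"], 0.0)


def test_tukey_antisymmetric_under_swap():
    rng = np.random.default_rng(6)
    values = rng.normal(size=30)
    groups = np.array((["A"] * 10) + (["B"] * 10) + (["C"] * 10))
    tukey = tukey_kramer(values, groups)
    ab = tukey[(tukey.group1 == "A") & (tukey.group2 == "B")]["diff"].iloc[0]
    swapped = tukey_kramer(values, np.where(groups == "A", "B",
                                            np.where(groups == "B", "A", "C")))
    ba = swapped[(swapped.group1 == "B") & (swapped.group2 == "A")]["diff"].iloc[0]
    assert ab == pytest.approx(ba, abs=1e-12)


def test_tukey_p_geq_unadjusted_t_for_k3():
    rng = np.random.default_rng(7)
    for _ in range(20):
        samples = [rng.normal(rng.normal(0, 0.5), 1, rng.integers(8, 20))
                   for _ in range(3)]
        values = np.concatenate(samples)
        groups = np.concatenate([[f"G{i}"] * len(s) for i, s in enumerate(samples)])
        tukey = tukey_kramer(values, groups)
        df_within = len(values) - 3
        for _, row in tukey.iterrows():
            # unadjusted pairwise t on the same pooled within-group variance
            t_p = 2 * stats.t.sf(row.q / np.sqrt(2), df_within)
            assert row.p_adj >= t_p - 1e-12


def test_anova_null_calibration_iid_scores():
    # three groups drawn from one distribution: p-values uniform
    rng = np.random.default_rng(8)
    idx = pd.Index([f"S{i}" for i in range(90)], name="subject_id")
    meta = pd.DataFrame({"group": np.repeat(["HC", "recent", "chronic"], 30),
                         "site": "s", "age": rng.uniform(20, 50, 90),
                         "sex": rng.integers(0, 2, 90)}, index=idx)
    ps = []
    for _ in range(1000):
        scores = pd.DataFrame({"group": meta["group"],
                               "z_total": rng.standard_normal(90)}, index=idx)
        result = compare_groups(scores, meta, measures=["z_total"])
        ps.append(result.measures["z_total"].anova_p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_compare_groups_row_order_invariance():
    cohort = simulate_cohort(tiny_spec(seed=10, group_sizes={"HC": 12, "recent": 12,
                                                            "chronic": 12},
                                       heterogeneity={"HC": 1.0, "recent": 2.0,
                                                      "chronic": 3.0}))
    scores = aggregate_pbsi(compute_pbsi(cohort.tables))
    r1 = compare_groups(scores, cohort.meta, measures=["z_total"])
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(scores))
    r2 = compare_groups(scores.iloc[perm], cohort.meta, measures=["z_total"])
    assert r1.measures["z_total"].anova_f == pytest.approx(
        r2.measures["z_total"].anova_f, rel=1e-10)
    t1 = r1.measures["z_total"].tukey.set_index(["group1", "group2"])["p_adj"]
    t2 = r2.measures["z_total"].tukey.set_index(["group1", "group2"])["p_adj"]
    for key, val in t1.items():
        lookup = t2.get(key, t2.get((key[1], key[0])))
        assert val == pytest.approx(lookup, rel=1e-10)


def test_compare_groups_regression_adjusts_age_sex():
    cohort = simulate_cohort(tiny_spec(seed=11, group_sizes={"HC": 20, "recent": 20,
                                                            "chronic": 20},
                                       heterogeneity={"HC": 1.0, "recent": 2.5,
                                                      "chronic": 3.5}))
    scores = aggregate_pbsi(compute_pbsi(cohort.tables))
    result = compare_groups(scores, cohort.meta, measures=["z_total"])
    reg = result.measures["z_total"].regression.set_index("term")
    assert {"const", "group[chronic]", "group[recent]", "age", "sex"} == set(reg.index)
    assert reg.loc["group[chronic]", "coef"] < 0  # more heterogeneous than HC
    assert (reg["p"].between(0, 1)).all()


def test_compare_groups_power_under_alternative():
    hits = 0
    for seed in range(20):
        cohort = simulate_cohort(tiny_spec(
            seed=seed, group_sizes={"HC": 50, "SCZ": 50},
            heterogeneity={"HC": 1.0, "SCZ": 2.0}))
        scores = aggregate_pbsi(compute_pbsi(cohort.tables))
        result = compare_groups(scores, cohort.meta, measures=["z_total"],
                                control_group="HC")
        hits += int(result.measures["z_total"].tukey["p_adj"].iloc[0] < 0.05)
    assert hits >= 16   # >= 80% power


# -- demographics ------------------------------------------------------------

def test_chi_square_matches_hand_summed_oracle():
    counts = np.array([[12, 18, 9], [15, 14, 12]])
    stat, p, dof = chi_square(counts)
    assert stat == pytest.approx(oracle_chi_square(counts), abs=1e-12)
    assert dof == 2
    assert p == pytest.approx(stats.chi2.sf(stat, 2), abs=1e-14)


def test_identical_groups_p_near_one():
    idx = pd.Index([f"S{i}" for i in range(30)], name="subject_id")
    meta = pd.DataFrame({
        "group": np.repeat(["HC", "recent", "chronic"], 10),
        "site": "s",
        "age": np.tile(np.arange(10, dtype=float) + 25, 3),
        "sex": np.tile([0, 1] * 5, 3),
    }, index=idx)
    table = demographics_table(meta)
    age_row = table[table["variable"] == "age"].iloc[0]
    assert age_row["p"] == pytest.approx(1.0, abs=1e-10)
    sex_row = table[table["variable"] == "sex"].iloc[0]
    assert sex_row["p"] == pytest.approx(1.0, abs=1e-10)


def test_demographics_from_cohort():
    cohort = simulate_cohort(tiny_spec(seed=12, group_sizes={"HC": 20, "recent": 15,
                                                            "chronic": 15},
                                       heterogeneity={"HC": 1.0, "recent": 1.0,
                                                      "chronic": 1.0}))
    table = demographics_table(cohort.meta, cohort.clinical)
    assert {"age", "sex", "fsiq", "mq", "gaf", "panss_total",
            "illness_duration", "antipsychotic_dose"} <= set(table["variable"])
    hc_n = table.loc[table["variable"] == "age", "HC_n"].iloc[0]
    assert hc_n == 20
    dur = table[table["variable"] == "illness_duration"].iloc[0]
    assert dur["test"] == "ttest"
    assert dur["HC_n"] == 0


def test_duration_split_rule():
    durations = pd.Series([0.5, 5.0, 5.0001, 12.0, np.nan])
    labels = duration_split(durations)
    assert list(labels[:4]) == ["recent", "recent", "chronic", "chronic"]
    assert pd.isna(labels.iloc[4])
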
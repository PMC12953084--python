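"""Descriptives, ANOVA decompositions and the Bonferroni family rules."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glymquant.stats import describe, oneway_anova, rm_anova, stars


def long_table(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"animal_id": f"{g}{i}", "group": g, "value": v})
    return pd.DataFrame(rows)


def test_describe_trivial_and_exact():
    d = describe(long_table({"a": [1.0, 1.0, 1.0], "b": [2.0, 4.0]}))
    a = d[d.group == "a"].iloc[0]
    assert a["mean"] == 1.0 and a["sd"] == 0.0
    b = d[d.group == "b"].iloc[0]
    assert b["mean"] == 3.0
    assert b["sd"] == pytest.approx(np.sqrt(2))
    # 95% t CI, df=1: 3 +/- 12.706 * sqrt(2)/sqrt(2)
    assert b["ci_high"] == pytest.approx(3 + sps.t.ppf(0.975, 1))


def test_describe_flags_single_observation():
    d = describe(long_table({"a": [1.0], "b": [1.0, 2.0]}))
    assert "undefined" in d[d.group == "a"].iloc[0]["flag"]
    assert np.isnan(d[d.group == "a"].iloc[0]["sd"])


def test_identical_groups_give_f_zero_p_one():
    res = oneway_anova(long_table({"a": [5.0] * 4, "b": [5.0] * 4}))
    eff = res.effects.iloc[0]
    assert eff["F"] == 0.0 and eff["p"] == 1.0


def test_two_group_f_equals_squared_t():
    rng = np.random.default_rng(0)
    t = long_table({"a": list(rng.normal(0, 1, 8)), "b": list(rng.normal(1, 1, 8))})
    res = oneway_anova(t)
    tt = sps.ttest_ind(t[t.group == "a"].value, t[t.group == "b"].value)
    assert res.effects.iloc[0]["F"] == pytest.approx(tt.statistic**2)
    assert res.effects.iloc[0]["p"] == pytest.approx(tt.pvalue)


def test_three_group_sums_of_squares_match_hand_oracle():
    """Toy 9-observation table, sums of squares worked by hand:
    groups {1,2,3}, {2,4,6}, {3,6,9}; grand mean 4; SSB = 3[(2-4)^2 +
    (4-4)^2 + (6-4)^2] = 24; SSW = 2 + 8 + 18 = 28."""
    t = long_table({"a": [1, 2, 3], "b": [2, 4, 6], "c": [3, 6, 9]})
    res = oneway_anova(t)
    eff = res.effects.set_index("effect")
    assert eff.loc["group", "ss"] == pytest.approx(24.0)
    assert eff.loc["residual", "ss"] == pytest.approx(28.0)
    assert eff.loc["group", "F"] == pytest.approx((24 / 2) / (28 / 6))


def test_bonferroni_dominance_and_cap():
    rng = np.random.default_rng(1)
    t = long_table({g: list(rng.normal(0, 1, 6)) for g in "abcd"})
    res = oneway_anova(t)
    assert res.bonferroni_m == 6
    assert (res.pairwise["p_bonf"] >= res.pairwise["p_raw"] - 1e-15).all()
    assert (res.pairwise["p_bonf"] <= 1.0).all()
    # CI contains the point estimate
    assert (res.pairwise["ci_low"] <= res.pairwise["diff"]).all()
    assert (res.pairwise["diff"] <= res.pairwise["ci_high"]).all()
    # adjusted CIs are wider
    assert (res.pairwise["ci_low_bonf"] <= res.pairwise["ci_low"]).all()


def test_group_with_single_observation_rejected():
    with pytest.raises(ValueError):
        oneway_anova(long_table({"a": [1.0], "b": [1.0, 2.0]}))


def test_null_permutation_type_one_error_near_nominal():
    """Rejection rate at alpha = 0.05 over label permutations of null data
    stays within Monte-Carlo error of 5%."""
    rng = np.random.default_rng(123)
    n_rep, rejections = 200, 0
    for _ in range(n_rep):
        vals = rng.normal(0, 1, 24)
        labels = rng.permutation(np.repeat(list("abc"), 8))
        t = pd.DataFrame({"animal_id": range(24), "group": labels, "value": vals})
        if oneway_anova(t).effects.iloc[0]["p"] < 0.05:
            rejections += 1
    # binomial SE at p=0.05, n=200 is ~1.5%; allow 3 SE
    assert 0.005 <= rejections / n_rep <= 0.095


def rm_table(effect=1.0, n=6, times=(1, 2, 3), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, shift in (("C", 0.0), ("PDN", effect)):
        for i in range(n):
            base = rng.normal(0, 0.5)
            for t in times:
                rows.append({"animal_id": f"{g}{i}", "group": g, "time": t,
                             "value": rng.normal(shift + base + 0.1 * t, 0.5)})
    return pd.DataFrame(rows)


def test_rm_anova_single_time_reduces_to_oneway():
    t = rm_table(times=(1,))
    res = rm_anova(t)
    ref = oneway_anova(t)
    assert res.effects.iloc[0]["F"] == pytest.approx(ref.effects.iloc[0]["F"])
    assert res.bonferroni_m == ref.bonferroni_m


def test_rm_anova_effects_and_family_size():
    res = rm_anova(rm_table())
    assert set(res.effects["effect"]) == {"group", "time", "Interaction"}
    # GG-corrected p reported for the within effect
    time_row = res.effects[res.effects.effect == "time"].iloc[0]
    assert np.isfinite(time_row["p_gg"])
    # family: 1 group pair x 3 time points
    assert res.bonferroni_m == 3
    assert len(res.pairwise) == 3
    assert (res.pairwise["p_bonf"] >= res.pairwise["p_raw"] - 1e-15).all()


def test_rm_anova_excludes_incomplete_subjects_with_warning():
    t = rm_table()
    t = t[~((t.animal_id == "C0") & (t.time == 3))]
    with pytest.warns(UserWarning, match="C0"):
        res = rm_anova(t)
    assert "C0" in res.notes[0]


def test_rm_anova_rejects_duplicate_measurements():
    t = rm_table()
    with pytest.raises(ValueError, match="duplicated"):
        rm_anova(pd.concat([t, t.head(1)]))


def test_all_equal_rm_values_give_zero_f():
    t = rm_table()
    t["value"] = 7.0
    res = rm_anova(t)
    grp = res.effects[res.effects.effect == "group"].iloc[0]
    assert grp["F"] == pytest.approx(0.0, abs=1e-10) or np.isnan(grp["F"])


def test_polarization_group_contrast_power():
    """Simulated cohorts at the printed polarization means/SDs separate
    C from PDN at alpha = 0.05 in >= 90% of seeded replicates, and the
    printed group ordering PDN < PMA < OMT < C holds as often."""
    from glymquant.simulate import CohortConfig, generate_cohort

    n_rep, sig, ordered = 60, 0, 0
    for seed in range(n_rep):
        cohort = generate_cohort(CohortConfig(seed=seed, measures=("polarization",)))
        t = cohort.rename(columns={"value": "value"})
        res = oneway_anova(t)
        pw = res.pairwise
        row = pw[(pw.group_a == "C") & (pw.group_b == "PDN")].iloc[0]
        if row["p_bonf"] < 0.05:
            sig += 1
        means = t.groupby("group")["value"].mean()
        if means["PDN"] < means["PMA"] < means["OMT"] < means["C"]:
            ordered += 1
    assert sig / n_rep >= 0.9
    assert ordered / n_rep >= 0.9


def test_stars_convention():
    assert stars(0.2) == "ns"
    assert stars(0.04) == "*"
    assert stars(0.004) == "**"
    assert stars(0.0004) == "***"
    assert stars(0.00004) == "****"
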
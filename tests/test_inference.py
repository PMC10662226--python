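"""Mixed-design repeated-measures ANOVA and treatment t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import leafphys as lp


def make_table(attached, excised):
    """Build a long table from per-subject (AM, PM) value pairs."""
    rows = []
    for label, data in (("attached", attached), ("excised", excised)):
        for i, (am, pm) in enumerate(data):
            rep = f"{label}{i}"
            rows.append(dict(replicate=rep, treatment=label, time="AM", value=am))
            rows.append(dict(replicate=rep, treatment=label, time="PM", value=pm))
    return pd.DataFrame(rows)


def textbook_mixed_anova(table):
    """Independent oracle: classical sums-of-squares decomposition for a
    balanced two-treatment x two-time mixed design."""
    wide = table.pivot_table(index=["treatment", "replicate"], columns="time",
                             values="value")
    groups = wide.index.get_level_values(0)
    labels = sorted(set(groups))
    Y = wide.to_numpy()                     # (subjects, 2 times)
    n = (groups == labels[0]).sum()
    assert (groups == labels[1]).sum() == n, "oracle needs balanced data"
    b = Y.shape[1]
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    cell = np.array([[Y[groups == g][:, t].mean() for t in range(b)]
                     for g in labels])
    treat_means = cell.mean(axis=1)
    time_means = np.array([Y[:, t].mean() for t in range(b)])

    ss_treat = b * n * ((treat_means - grand) ** 2).sum()
    ss_subj = b * ((subj_means - np.repeat(treat_means, n)) ** 2).sum()
    ss_time = 2 * n * ((time_means - grand) ** 2).sum()
    ss_int = n * ((cell - treat_means[:, None] - time_means[None, :]
                   + grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_treat - ss_subj - ss_time - ss_int

    df_between, df_within = 2 * n - 2, 2 * n - 2
    F_treat = ss_treat / (ss_subj / df_between)
    F_time = ss_time / (ss_err_within / df_within)
    F_int = ss_int / (ss_err_within / df_within)
    return F_treat, F_time, F_int


class TestRMAnova:
    def test_matches_textbook_decomposition(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            att = rng.normal(0, 1, (4, 2)) + [0.0, 0.5]
            exc = rng.normal(0, 1, (4, 2)) + [0.3, 1.0]
            table = make_table(att, exc)
            res = lp.two_way_rm_anova(table)
            Ft, Fh, Fi = textbook_mixed_anova(table)
            assert res.treatment.F == pytest.approx(Ft, abs=1e-8)
            assert res.time.F == pytest.approx(Fh, abs=1e-8)
            assert res.interaction.F == pytest.approx(Fi, abs=1e-8)

    def test_matches_pingouin_balanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        table = make_table(rng.normal(0, 1, (6, 2)), rng.normal(0.4, 1, (6, 2)))
        res = lp.two_way_rm_anova(table)
        out = pg.mixed_anova(table, dv="value", within="time",
                             subject="replicate", between="treatment")
        by = dict(zip(out["Source"].str.lower(), out["F"]))
        assert res.treatment.F == pytest.approx(by["treatment"], rel=1e-8)
        assert res.time.F == pytest.approx(by["time"], rel=1e-8)
        assert res.interaction.F == pytest.approx(by["interaction"], rel=1e-8)

    def test_treatment_f_equals_oneway_on_subject_means(self):
        rng = np.random.default_rng(9)
        att, exc = rng.normal(0, 1, (5, 2)), rng.normal(0.8, 1, (7, 2))
        res = lp.two_way_rm_anova(make_table(att, exc))
        F, p = stats.f_oneway(att.mean(axis=1), exc.mean(axis=1))
        assert res.treatment.F == pytest.approx(F, rel=1e-10)
        assert res.treatment.p == pytest.approx(p, rel=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(10)
        table = make_table(rng.normal(0, 1, (5, 2)), rng.normal(0.5, 1, (5, 2)))
        res1 = lp.two_way_rm_anova(table)
        table2 = table.assign(value=3.7 * table["value"] - 11.0)
        res2 = lp.two_way_rm_anova(table2)
        for eff in ("treatment", "time", "interaction"):
            assert getattr(res1, eff).p == pytest.approx(getattr(res2, eff).p,
                                                         rel=1e-10)

    def test_constant_response_signalled(self):
        table = make_table(np.ones((4, 2)), np.ones((4, 2)))
        with pytest.raises(lp.DegenerateDataError):
            lp.two_way_rm_anova(table)

    def test_missing_time_dropped_with_warning(self):
        table = make_table(np.random.default_rng(1).normal(size=(4, 2)),
                           np.random.default_rng(2).normal(size=(4, 2)))
        table = table.drop(table[(table.replicate == "attached0")
                                 & (table.time == "PM")].index)
        with pytest.warns(RuntimeWarning):
            res = lp.two_way_rm_anova(table)
        assert res.n_subjects == 7
        assert res.n_dropped == 1

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = {"treatment": 0, "time": 0, "interaction": 0}
        n_sims = 200
        for _ in range(n_sims):
            table = make_table(rng.normal(0, 1, (8, 2)), rng.normal(0, 1, (8, 2)))
            res = lp.two_way_rm_anova(table)
            for eff in rejections:
                rejections[eff] += getattr(res, eff).p < 0.05
        for eff, count in rejections.items():
            assert 0.01 <= count / n_sims <= 0.10, eff


class TestTTests:
    def test_paired_symmetric_differences(self):
        res = lp.compare_treatments_t([1.0, 2.0, 3.0], [2.0, 2.0, 2.0],
                                      paired=True)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_paired_hand_value(self):
        # differences (1,2,3): mean 2, sd 1, t = 2/(1/sqrt(3))
        res = lp.compare_treatments_t([3.0, 4.0, 5.0], [2.0, 2.0, 2.0],
                                      paired=True)
        assert res.t == pytest.approx(3.464, abs=1e-3)
        assert res.df == 2
        assert res.flavor == "one_sample_on_differences"

    def test_identical_groups(self):
        res = lp.compare_treatments_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0.0
        assert res.p == pytest.approx(1.0)

    def test_welch_matches_scipy_and_pooled_limit(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 50), rng.normal(0.2, 1, 50)
        res = lp.compare_treatments_t(x, y)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(t)
        t_pooled, p_pooled = stats.ttest_ind(x, y, equal_var=True)
        assert res.p == pytest.approx(p_pooled, rel=0.01)  # equal n, similar var

    def test_zero_variance_signalled(self):
        with pytest.raises(lp.DegenerateDataError):
            lp.compare_treatments_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestSamplingDateCheck:
    def _table(self, shift=0.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "date": ["d1"] * n + ["d2"] * n,
            "gs": np.r_[rng.normal(0.3, 0.02, n), rng.normal(0.3 + shift, 0.02, n)],
            "A": np.r_[rng.normal(25, 2, n), rng.normal(25, 2, n)],
        })

    def test_identical_values_combine(self):
        table = pd.DataFrame({"date": ["d1"] * 3 + ["d2"] * 3,
                              "wp": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = lp.sampling_date_check(table)
        assert res.loc[0, "p"] == pytest.approx(1.0)
        assert bool(res.loc[0, "combine"])

    def test_large_shift_flagged_with_high_power(self):
        flagged = sum(
            not lp.sampling_date_check(self._table(shift=0.06, seed=s))
            .set_index("trait").loc["gs", "combine"]
            for s in range(40))
        assert flagged / 40 >= 0.95  # d = 3 at n = 8

    def test_null_flag_rate_near_alpha(self):
        flagged = sum(
            not lp.sampling_date_check(self._table(seed=s))
            .set_index("trait").loc["A", "combine"]
            for s in range(200))
        assert 0.01 <= flagged / 200 <= 0.10

    def test_wrong_date_count_rejected(self):
        with pytest.raises(ValueError):
            lp.sampling_date_check(pd.DataFrame({"date": ["d1"] * 4,
                                                 "x": [1, 2, 3, 4.0]}))

    def test_barley_water_potential_power(self):
        # a +0.044 MPa treatment shift with 0.02 MPa noise at n=8 is
        # detectable in nearly all realisations
        detected = 0
        n_seeds = 200
        for seed in range(n_seeds):
            design = lp.ExperimentDesign(
                "barley", 8, seed=seed,
                effects={"water_potential": lp.EffectSpec(
                    -0.237, treatment_delta=0.044, noise_sd=0.02)})
            table = lp.generate_trait_table(design, "water_potential",
                                            repeated=False)
            res = lp.compare_treatments_t(
                table.loc[table.treatment == "excised", "value"],
                table.loc[table.treatment == "attached", "value"])
            detected += res.p < 0.05
        assert detected / n_seeds >= 0.9
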
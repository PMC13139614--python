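"""Group statistics against hand computations and library oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spheroid_doct.longitudinal_stats import (
    build_timecourse,
    one_way_anova,
    pearson_corr,
    piecewise_slopes,
    significance_report,
    significance_symbol,
    summarize_timecourse,
    tukey_hsd,
)


def make_table(conditions=("control",), concentrations=(0.0,), n_reps=4, times=(0.0, 12.0, 100.0), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for conc in concentrations:
            for rep in range(n_reps):
                for t in times:
                    rows.append(
                        {
                            "condition": cond,
                            "concentration_um": conc,
                            "sample_id": f"{cond}_{conc}_{rep}",
                            "time_hr": t,
                            "volume_um3": rng.normal(1e6, 1e4),
                            "mean_liv_db2": rng.normal(20, 1) + (conc if t >= 12 else 0),
                        }
                    )
    return pd.DataFrame(rows)


class TestBuildTimecourse:
    def test_row_counts(self):
        df = build_timecourse(make_table(n_reps=4, times=tuple(np.arange(0, 104, 4.0))))
        assert len(df) == 4 * 26

    def test_study2_shape(self):
        times = tuple(np.arange(0, 100.5, 0.5))
        df = build_timecourse(
            make_table(conditions=("control", "dox", "tam", "ptx"), n_reps=3, times=times)
        )
        assert len(df) == 3 * 201 * 4

    def test_missing_timepoint_reflected_in_summary_n(self):
        table = make_table(n_reps=3)
        table = table.drop(table[(table.sample_id == "control_0.0_0") & (table.time_hr == 12.0)].index)
        df = build_timecourse(table)
        summary = summarize_timecourse(df, "mean_liv_db2")
        n12 = summary[summary.time_hr == 12.0]["n"].iloc[0]
        n0 = summary[summary.time_hr == 0.0]["n"].iloc[0]
        assert (n0, n12) == (3, 2)

    def test_duplicate_keys_rejected(self):
        table = make_table()
        with pytest.raises(ValueError):
            build_timecourse(pd.concat([table, table.iloc[:1]]))


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_example_by_hand(self):
        # groups: {1,2,3,4}, {2,3,4,5}, {4,5,6,7}
        # grand mean = 46/12; SSB = 4*[(2.5-m)^2+(3.5-m)^2+(5.5-m)^2],
        # SSW = 3*[var... ] worked by hand below
        g1, g2, g3 = [1, 2, 3, 4], [2, 3, 4, 5], [4, 5, 6, 7]
        m = np.mean(g1 + g2 + g3)
        ssb = 4 * ((2.5 - m) ** 2 + (3.5 - m) ** 2 + (5.5 - m) ** 2)
        ssw = sum((x - 2.5) ** 2 for x in g1) + sum((x - 3.5) ** 2 for x in g2) + sum(
            (x - 5.5) ** 2 for x in g3
        )
        f_hand = (ssb / 2) / (ssw / 9)
        res = one_way_anova([g1, g2, g3])
        assert res.f_statistic == pytest.approx(f_hand, abs=1e-6)
        assert (res.df_between, res.df_within) == (2, 9)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc, 1.0, size=n) for loc, n in ((0, 5), (0.5, 7), (1.0, 6))]
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_type_i_error_calibration(self):
        # 4 equal-mean groups: rejection rate at alpha=0.05 within 0.05 +/- 0.01
        rng = np.random.default_rng(11)
        n_sims, k, n = 10000, 4, 6
        data = rng.normal(size=(n_sims, k, n))
        gm = data.mean(axis=2)
        grand = data.mean(axis=(1, 2))
        ssb = n * ((gm - grand[:, None]) ** 2).sum(axis=1)
        ssw = ((data - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        f = (ssb / (k - 1)) / (ssw / (k * (n - 1)))
        p = sps.f.sf(f, k - 1, k * (n - 1))
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06
        # spot-check the vectorized null against the implementation
        res = one_way_anova(list(data[0]))
        assert res.p_value == pytest.approx(p[0], rel=1e-10)

    @pytest.mark.parametrize("groups", [[[1, 2, 3]], [[1], [2, 3]], [[1, 1], [1, 1]]])
    def test_invalid_inputs_rejected(self, groups):
        with pytest.raises(ValueError):
            one_way_anova(groups)


class TestTukey:
    def test_identical_groups_p_near_one(self):
        df = tukey_hsd([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        assert df["p_adj"].iloc[0] >= 0.999

    def test_matches_scipy_tukey_oracle(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1.0, size=6) for m in (0.0, 0.8, 1.6)]
        ours = tukey_hsd(groups)
        oracle = sps.tukey_hsd(*groups)
        for row in ours.itertuples():
            i = int(row.group_a.removeprefix("group"))
            j = int(row.group_b.removeprefix("group"))
            assert row.p_adj == pytest.approx(oracle.pvalue[i, j], abs=1e-8)

    def test_adjusted_p_not_below_t_test(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            groups = [rng.normal(0, 1, 5) for _ in range(3)]
            ours = tukey_hsd(groups)
            for row in ours.itertuples():
                i = int(row.group_a.removeprefix("group"))
                j = int(row.group_b.removeprefix("group"))
                t_p = sps.ttest_ind(groups[i], groups[j]).pvalue
                assert row.p_adj >= t_p - 0.05  # adjusted p dominates pairwise t

    def test_family_wise_error_controlled(self):
        # 3 equal-mean groups: P(any pair declared significant) <= alpha + 3 SE
        rng = np.random.default_rng(19)
        n_sims, k, n = 2000, 3, 5
        data = rng.normal(size=(n_sims, k, n))
        gm = data.mean(axis=2)
        ssw = ((data - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        df_w = k * (n - 1)
        ms_within = ssw / df_w
        q_crit = sps.studentized_range.ppf(0.95, k, df_w)
        ranges = gm.max(axis=1) - gm.min(axis=1)
        q_max = ranges / np.sqrt(ms_within / n)
        fwe = (q_max > q_crit).mean()
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert fwe <= 0.05 + 3 * se
        # the implementation's smallest adjusted p agrees with the max-q route
        idx = int(np.argmax(q_max))
        ours = tukey_hsd(list(data[idx]))
        assert (ours["p_adj"].min() < 0.05) == bool(q_max[idx] > q_crit)


class TestPearson:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_corr(x, -2 * x) == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(size=10000), rng.normal(size=10000)
        assert abs(pearson_corr(x, y)) < 0.05

    def test_matches_hand_computation(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([10.0, 9.0, 6.0, 4.0, 1.0])
        xc, yc = x - x.mean(), y - y.mean()
        hand = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert pearson_corr(x, y) == pytest.approx(hand, abs=1e-10)
        assert pearson_corr(x, y) == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestSignificanceReport:
    @pytest.mark.parametrize("p,symbol", [(0.2, "-"), (0.03, "*"), (0.005, "**")])
    def test_symbol_rule(self, p, symbol):
        assert significance_symbol(p) == symbol

    def test_report_gates_tukey_on_significance(self):
        table = build_timecourse(
            make_table(concentrations=(0.0, 0.1, 1.0, 10.0), n_reps=4, seed=3)
        )
        rep = significance_report(table, "mean_liv_db2", times_hr=(0.0, 12.0))
        at0 = rep[rep.time_hr == 0.0].iloc[0]
        at12 = rep[rep.time_hr == 12.0].iloc[0]
        # concentration effect is injected only from 12 hr on
        assert at0.symbol == "-" and at0.tukey is None
        assert at12.p_value < 0.05 and at12.tukey is not None
        assert len(at12.tukey) == 6  # C(4,2) unordered pairs

    def test_missing_time_rejected(self):
        table = build_timecourse(make_table())
        with pytest.raises(ValueError):
            significance_report(table, "mean_liv_db2", times_hr=(55.0,))


class TestPiecewiseSlopes:
    def test_known_kink(self):
        t = np.arange(0, 20.0)
        v = np.where(t <= 10, 2.0 * t, 20.0 + 0.5 * (t - 10))
        out = piecewise_slopes(t, v, breakpoint_hr=10.0)
        assert out["slope_before"] == pytest.approx(2.0)
        assert out["slope_after"] == pytest.approx(0.5)
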
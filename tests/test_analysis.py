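"""Stay probabilities, contrasts, ANOVA, group tests, BMI regression."""

import io
import shutil
import subprocess
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from conftest import make_session

from twostep import (
    HYBRID,
    Parameters,
    TaskConfig,
    contrast_terms,
    eta_squared_h,
    kruskal_wallis_eta2,
    make_reward_walks,
    pairwise_group_comparisons,
    simulate_session,
    stay_probabilities,
    three_way_anova,
)
from twostep.analysis import (
    StayTable,
    bmi_polynomial_regression,
    cohort_stay_frame,
    normality_variance_screen,
    orthogonal_poly,
)


def wsls_session(rewards, transitions_common, start=0):
    """Win-stay/lose-shift bot: repeat iff the previous trial was rewarded."""
    n = len(rewards)
    a1 = [start]
    for t in range(1, n):
        a1.append(a1[-1] if rewards[t - 1] else 1 - a1[-1])
    a1 = np.array(a1)
    s2 = np.where(transitions_common, a1, 1 - a1)
    return make_session(a1, s2, np.zeros(n, int), np.asarray(rewards))


class TestStayProbabilities:
    def test_hand_counted_five_trial_log(self):
        # choices A A B B B; all predecessor trials rewarded-common
        s = make_session([0, 0, 1, 1, 1], [0, 0, 1, 1, 1], [0] * 5, [1] * 5)
        t = stay_probabilities(s)
        assert t.p_rc == 0.75 and t.n_rc == 4
        assert np.isnan(t.p_rr) and np.isnan(t.p_uc) and np.isnan(t.p_ur)
        with pytest.raises(ValueError, match="empty stay cell"):
            contrast_terms(t)

    def test_always_repeating_agent_has_all_ones(self, rng):
        n = 100
        rewards = rng.integers(0, 2, n)
        common = rng.random(n) < 0.7
        a1 = np.zeros(n, int)
        s2 = np.where(common, 0, 1)
        t = stay_probabilities(make_session(a1, s2, np.zeros(n, int), rewards))
        assert t.complete
        np.testing.assert_array_equal(t.cells, 1.0)
        assert t.n_rc + t.n_rr + t.n_uc + t.n_ur == n - 1

    def test_win_stay_lose_shift_signature(self, rng):
        n = 400
        rewards = rng.integers(0, 2, n)
        common = rng.random(n) < 0.7
        t = stay_probabilities(wsls_session(rewards, common))
        assert t.p_rc == 1.0 and t.p_rr == 1.0
        assert t.p_uc == 0.0 and t.p_ur == 0.0
        assert contrast_terms(t) == (0.0, 2.0)

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError):
            stay_probabilities(make_session([0], [0], [0], [0]))


class TestContrastTerms:
    def _table(self, rc, rr, uc, ur):
        return StayTable("x", rc, rr, uc, ur, 10, 10, 10, 10)

    def test_hand_arithmetic(self):
        inter, main = contrast_terms(self._table(0.9, 0.6, 0.5, 0.8))
        np.testing.assert_allclose([inter, main], [0.6, 0.2])

    def test_equal_cells_give_zero(self):
        assert contrast_terms(self._table(0.4, 0.4, 0.4, 0.4)) == (0.0, 0.0)

    def test_swapping_reward_rows_negates_main_term(self):
        i1, m1 = contrast_terms(self._table(0.9, 0.6, 0.5, 0.8))
        i2, m2 = contrast_terms(self._table(0.5, 0.8, 0.9, 0.6))
        assert m2 == -m1


def _stay_frame(cells_by_group, rng, noise=0.0):
    rows = []
    for g, (cells, n) in cells_by_group.items():
        for i in range(n):
            c = np.clip(np.asarray(cells, float) + rng.normal(0, noise, 4), 0, 1)
            rows.append(
                {"subject_id": f"{g}{i}", "group": g, "bmi": np.nan,
                 "p_stay_rc": c[0], "p_stay_rr": c[1],
                 "p_stay_uc": c[2], "p_stay_ur": c[3]}
            )
    return pd.DataFrame(rows)


class TestThreeWayAnova:
    def test_identical_groups_give_zero_group_effects(self, rng):
        base = _stay_frame({"A": ((0.9, 0.6, 0.5, 0.8), 10)}, rng, noise=0.05)
        df = pd.concat(
            [base.assign(group=g) for g in ("A", "B", "C")], ignore_index=True
        )
        res = three_way_anova(df)
        for eff in ("Group", "Group:Reward", "Group:Reward:Transition"):
            np.testing.assert_allclose(res.loc[eff, "F"], 0.0, atol=1e-12)

    def test_planted_group_interaction_detected(self, rng):
        df = _stay_frame(
            {
                "A": ((0.85, 0.55, 0.55, 0.85), 30),  # interaction 0.6
                "B": ((0.85, 0.55, 0.55, 0.85), 30),
                "C": ((0.70, 0.55, 0.55, 0.70), 30),  # interaction 0.3
            },
            rng,
            noise=0.08,
        )
        res = three_way_anova(df)
        assert res.loc["Group:Reward:Transition", "p"] < 0.05

    def test_equivalence_with_oneway_contrast_f(self, rng):
        # the three-way F must equal the one-way F on per-subject contrasts
        df = _stay_frame(
            {"A": ((0.8, 0.6, 0.5, 0.7), 12), "B": ((0.7, 0.6, 0.6, 0.7), 11),
             "C": ((0.75, 0.5, 0.5, 0.75), 13)},
            rng,
            noise=0.1,
        )
        res = three_way_anova(df)
        inter = (df.p_stay_rc - df.p_stay_rr) - (df.p_stay_uc - df.p_stay_ur)
        main = (df.p_stay_rc + df.p_stay_rr) - (df.p_stay_uc + df.p_stay_ur)
        groups = [g for _, g in df.groupby("group")]
        f_inter = st.f_oneway(*[inter[g.index] for g in groups]).statistic
        f_main = st.f_oneway(*[main[g.index] for g in groups]).statistic
        np.testing.assert_allclose(res.loc["Group:Reward:Transition", "F"], f_inter, atol=1e-8)
        np.testing.assert_allclose(res.loc["Group:Reward", "F"], f_main, atol=1e-8)

    def test_matches_r_car_type3_oracle(self, rng, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript oracle unavailable"
        df = _stay_frame(
            {"NW": ((0.8, 0.6, 0.5, 0.7), 9), "OW": ((0.7, 0.55, 0.6, 0.7), 8),
             "OB": ((0.75, 0.6, 0.55, 0.72), 10)},
            rng,
            noise=0.07,
        )
        path = tmp_path / "stay.csv"
        df.to_csv(path, index=False)
        script = Path(__file__).with_name("anova_oracle.R")
        out = subprocess.run(
            [rscript, str(script), str(path)], capture_output=True, text=True, check=True
        )
        oracle = pd.read_csv(io.StringIO(out.stdout)).set_index("effect")
        res = three_way_anova(df)
        mapping = {
            "Group": "group", "Reward": "reward", "Group:Reward": "group:reward",
            "Transition": "transition", "Group:Transition": "group:transition",
            "Reward:Transition": "reward:transition",
            "Group:Reward:Transition": "group:reward:transition",
        }
        for mine, theirs in mapping.items():
            np.testing.assert_allclose(
                res.loc[mine, "F"], oracle.loc[theirs, "F"], rtol=1e-6
            )
            np.testing.assert_allclose(
                res.loc[mine, ["df1", "df2"]].to_numpy(float),
                oracle.loc[theirs, ["df1", "df2"]].to_numpy(float),
            )

    def test_incomplete_subjects_dropped(self, rng):
        df = _stay_frame(
            {"A": ((0.8, 0.6, 0.5, 0.7), 6), "B": ((0.7, 0.6, 0.6, 0.7), 6)},
            rng, noise=0.05,
        )
        df.loc[0, "p_stay_rr"] = np.nan
        res = three_way_anova(df)
        assert res.loc["Group", "df2"] == 9  # 11 subjects - 2 groups


class TestPairwiseComparisons:
    def test_identical_groups(self):
        vals = np.tile(np.arange(10.0), 2)
        groups = np.repeat(["A", "B"], 10)
        res = pairwise_group_comparisons(vals, groups)
        assert res.t.abs().max() < 1e-12 and res.p.min() > 0.999

    def test_df_matches_group_sizes(self, rng):
        vals = rng.normal(size=61)
        groups = np.array(["NW"] * 31 + ["OB"] * 30)
        res = pairwise_group_comparisons(vals, groups)
        assert res.df.iloc[0] == 59

    def test_power_for_one_sd_shift(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(0, 1, 30)
            b = rng.normal(1, 1, 30)
            res = pairwise_group_comparisons(
                np.concatenate([a, b]), np.repeat(["A", "B"], 30)
            )
            hits += res.p.iloc[0] < 0.05
        assert hits / reps > 0.95

    def test_small_group_skipped(self):
        res = pairwise_group_comparisons(
            np.array([1.0, 2.0, 3.0]), np.array(["A", "A", "B"])
        )
        assert res.empty


class TestKruskalWallis:
    @pytest.mark.parametrize(
        "H, expected", [(11.5, 0.11), (17.3, 0.18), (16.9, 0.17)]
    )
    def test_worked_effect_sizes(self, H, expected):
        assert round(eta_squared_h(H, k=3, n=90), 2) == expected

    def test_null_expectation_is_zero(self):
        assert eta_squared_h(2.0, k=3, n=90) == 0.0

    def test_matches_scipy_h_statistic(self, rng):
        vals = rng.normal(size=60)
        groups = np.repeat(["A", "B", "C"], 20)
        H, p, eta = kruskal_wallis_eta2(vals, groups)
        H2, p2 = st.kruskal(vals[:20], vals[20:40], vals[40:])
        assert H == pytest.approx(H2) and p == pytest.approx(p2)
        assert eta == pytest.approx((H - 2) / 57)


class TestBmiRegression:
    def test_orthogonal_predictors(self, rng):
        bmi = rng.uniform(18, 45, 90)
        P = orthogonal_poly(bmi, 2)
        assert abs(np.corrcoef(P[:, 0], P[:, 1])[0, 1]) < 1e-10
        assert abs(P[:, 0].mean()) < 1e-12 and abs(P[:, 1].mean()) < 1e-12

    def test_exact_linear_relationship(self, rng):
        bmi = rng.uniform(18, 45, 50)
        y = 0.03 * bmi - 1.0
        res = bmi_polynomial_regression(y, bmi)
        assert res.beta_bmi > 0
        assert abs(res.beta_bmi2) < 1e-10
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_pure_quadratic_relationship(self):
        # symmetric design: (bmi - mean)^2 is exactly orthogonal to the
        # linear predictor, so the quadratic term carries everything
        bmi = np.linspace(18, 45, 50)
        y = (bmi - bmi.mean()) ** 2
        res = bmi_polynomial_regression(y, bmi)
        assert abs(res.beta_bmi) < 1e-10
        assert abs(res.beta_bmi2) > 0.9
        assert res.p_bmi2 < 1e-6

    def test_constant_bmi_rejected(self):
        with pytest.raises(ValueError):
            bmi_polynomial_regression(np.arange(5.0), np.full(5, 25.0))


class TestScreening:
    def test_reports_per_group_and_levene(self, rng):
        vals = rng.normal(size=45)
        groups = np.repeat(["A", "B", "C"], 15)
        res = normality_variance_screen(vals, groups)
        assert set(res.test) == {"shapiro", "levene"}
        assert len(res) == 4
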
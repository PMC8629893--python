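"""Behavioural measures: RT filter, accuracy, stay analysis, ANOVA machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_session
from revlearn3 import behaviour
from revlearn3.task import TaskConfig


class TestRtFilter:
    def test_strict_threshold_semantics(self):
        sess = make_session([0, 1, 2, 0], [1, -1, 1, -1],
                            rt_ms=np.array([150.0, 250.0, 199.0, 300.0]))
        filtered, n = behaviour.filter_fast_rt(sess)
        assert n == 2
        assert filtered.n_trials == 2
        assert list(filtered.rt_ms) == [250.0, 300.0]
        # boundary: exactly 200 ms is kept ("faster than" is strict)
        sess2 = make_session([0, 1], [1, -1], rt_ms=np.array([200.0, 201.0]))
        _, n2 = behaviour.filter_fast_rt(sess2)
        assert n2 == 0

    def test_noop_cases(self):
        sess = make_session([0, 1], [1, -1], rt_ms=np.array([500.0, 400.0]))
        same, n = behaviour.filter_fast_rt(sess)
        assert n == 0 and same is sess
        no_rt = make_session([0, 1], [1, -1])
        same2, n2 = behaviour.filter_fast_rt(no_rt)
        assert n2 == 0 and same2 is no_rt

    def test_filter_preserves_phase_membership(self):
        cfg = TaskConfig(n_trials=4, reversal_trial=3)
        sess = make_session([0, 1, 1, 0], [1, -1, 1, -1], config=cfg,
                            rt_ms=np.array([100.0, 300.0, 100.0, 300.0]))
        filtered, _ = behaviour.filter_fast_rt(sess)
        m = behaviour.accuracy_metrics(filtered)
        # surviving trials: trial 2 (acquisition, P-R), trial 4 (reversal, R-P)
        assert m["acquisition"]["pPunish_raw"] == 1.0
        assert m["reversal"]["pPunish_raw"] == 1.0


class TestAccuracy:
    def test_deterministic_rp_chooser(self, config):
        sess = make_session(np.zeros(80, int), np.ones(80), config=config)
        m = behaviour.accuracy_metrics(sess)
        assert m["acquisition"]["pReward_corrected"] == pytest.approx(2 / 3)
        assert m["reversal"]["pReward_corrected"] == pytest.approx(-1 / 3)

    def test_hand_computed_toy_sequence(self):
        cfg = TaskConfig(n_trials=12, reversal_trial=7)
        choices = [0, 0, 1, 2, 0, 1,   1, 1, 0, 2, 2, 1]
        outcomes = [1, -1] * 6
        sess = make_session(choices, outcomes, config=cfg)
        m = behaviour.accuracy_metrics(sess)
        assert m["acquisition"]["pReward_corrected"] == pytest.approx(1 / 6)
        assert m["acquisition"]["pAvoidPunish_corrected"] == pytest.approx(0.0)
        assert m["acquisition"]["pNeutral_corrected"] == pytest.approx(-1 / 6)
        assert m["reversal"]["pReward_corrected"] == pytest.approx(1 / 6)
        assert m["reversal"]["pAvoidPunish_corrected"] == pytest.approx(1 / 6)
        assert m["reversal"]["pNeutral_corrected"] == pytest.approx(0.0)

    def test_avoid_conventions(self):
        cfg = TaskConfig(n_trials=4, reversal_trial=3)
        sess = make_session([2, 2, 2, 2], [1, 1, 1, 1], config=cfg)
        chance = behaviour.accuracy_metrics(sess, avoid_convention="chance")
        third = behaviour.accuracy_metrics(sess, avoid_convention="third")
        assert chance["acquisition"]["pAvoidPunish_corrected"] == pytest.approx(1 / 3)
        assert third["acquisition"]["pAvoidPunish_corrected"] == pytest.approx(2 / 3)

    def test_uniform_chooser_scores_zero_on_all_corrected_metrics(self):
        rng = np.random.default_rng(6)
        cfg = TaskConfig(n_trials=10_000, reversal_trial=5_001,
                         schedule_mode="iid", max_run=None)
        sess = make_session(rng.integers(0, 3, 10_000),
                            rng.choice([-1.0, 1.0], 10_000), config=cfg)
        m = behaviour.accuracy_metrics(sess)
        for phase in m:
            for key in ("pReward_corrected", "pAvoidPunish_corrected",
                        "pNeutral_corrected"):
                assert abs(m[phase][key]) < 0.02

    def test_raw_probabilities_sum_to_one(self, small_cohort):
        dataset, _, _ = small_cohort
        m = behaviour.accuracy_metrics(dataset[0][0])
        for phase in m:
            total = (m[phase]["pReward_raw"] + m[phase]["pPunish_raw"]
                     + m[phase]["pNeutral_raw"])
            assert total == pytest.approx(1.0)


class TestStayProbabilities:
    def test_perseverator_and_lose_shifter(self):
        cfg = TaskConfig(n_trials=8, reversal_trial=5)
        stay = behaviour.stay_probabilities(
            make_session([1] * 8, [1, -1] * 4, config=cfg))
        assert (stay["p_stay"].dropna() == 1.0).all()
        # strict lose-shift: change after every loss
        choices = [0, 1, 2, 0, 1, 2, 0, 1]
        shifter = behaviour.stay_probabilities(
            make_session(choices, [-1.0] * 8, config=cfg))
        loss_rows = shifter[shifter["outcome"] == "loss"]
        assert (loss_rows["p_stay"].dropna() == 0.0).all()
        # no win trials at all -> win bins are reported missing
        assert shifter[shifter["outcome"] == "win"]["p_stay"].isna().all()

    def test_hand_computed_bins(self):
        cfg = TaskConfig(n_trials=6, reversal_trial=4)
        stay = behaviour.stay_probabilities(make_session(
            [0, 0, 1, 1, 1, 0], [1, -1, -1, 1, 1, -1], config=cfg))
        table = stay.set_index(["phase", "outcome"])["p_stay"]
        assert table["acquisition", "win"] == 1.0
        assert table["acquisition", "loss"] == 0.5
        assert table["reversal", "win"] == 0.5
        assert np.isnan(table["reversal", "loss"])

    def test_uniform_agent_stays_at_chance(self):
        rng = np.random.default_rng(1)
        cfg = TaskConfig(n_trials=10_000, reversal_trial=5_001,
                         schedule_mode="iid", max_run=None)
        stay = behaviour.stay_probabilities(make_session(
            rng.integers(0, 3, 10_000), rng.choice([-1.0, 1.0], 10_000),
            config=cfg))
        assert np.allclose(stay["p_stay"], 1 / 3, atol=0.03)


def _score_table(rng, n=102, effect=0.0):
    """Accuracy-shaped table with a controllable acquisition-only
    drug-by-WM interaction injected directly on the scores."""
    wm = rng.normal(0, 1, n)
    bis = rng.normal(0, 1, n)
    rows = []
    for i in range(n):
        base = rng.normal(0.2, 0.08)
        for phase in ("acquisition", "reversal"):
            for valence in ("pReward", "pAvoidPunish"):
                for drug in ("MPH", "placebo"):
                    v = base + rng.normal(0, 0.1)
                    if phase == "acquisition":
                        v += effect * wm[i] * (1 if drug == "MPH" else -1)
                    rows.append({"subject": i, "phase": phase,
                                 "valence": valence, "drug": drug, "value": v,
                                 "wm_span": wm[i], "bis": bis[i]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_single_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.2, 0.1, 24)
        b = a + rng.normal(0.05, 0.08, 24)
        rows = [{"subject": i, "phase": ph, "value": v}
                for i in range(24) for ph, v in
                (("acquisition", a[i]), ("reversal", b[i]))]
        rep = behaviour.rm_anova(pd.DataFrame(rows), covariates=(),
                                 factors=("phase",))
        t, p = stats.ttest_rel(a, b)
        row = rep[rep["effect"] == "Phase"].iloc[0]
        assert row["F"] == pytest.approx(t**2, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)
        assert row["df2"] == 23

    def test_matches_independent_implementations(self):
        """Cross-check against statsmodels AnovaRM and pingouin on the same
        within-subject data (no covariates)."""
        import pingouin as pg
        from statsmodels.stats.anova import AnovaRM

        table = _score_table(np.random.default_rng(7), n=20)
        mine = behaviour.rm_anova(table, covariates=()).set_index("effect")
        sm = AnovaRM(table, "value", "subject",
                     within=["valence", "phase", "drug"],
                     aggregate_func="mean").fit().anova_table
        for sm_name, my_name in [("valence", "Valence"), ("phase", "Phase"),
                                 ("drug", "Drug"),
                                 ("valence:phase", "Valence x Phase"),
                                 ("valence:phase:drug", "Valence x Phase x Drug")]:
            assert mine.loc[my_name, "F"] == pytest.approx(
                sm.loc[sm_name, "F Value"], rel=1e-6)
        two = table[table["drug"] == "MPH"]
        pga = pg.rm_anova(data=two, dv="value", within=["valence", "phase"],
                          subject="subject", detailed=True).set_index("Source")
        mine2 = behaviour.rm_anova(two, covariates=(),
                                   factors=("valence", "phase")).set_index("effect")
        assert mine2.loc["Valence", "F"] == pytest.approx(
            pga.loc["valence", "F"], abs=1e-3)
        assert mine2.loc["Phase", "F"] == pytest.approx(
            pga.loc["phase", "F"], abs=1e-3)

    def test_two_level_factors_report_unit_epsilon(self, small_cohort):
        dataset, _, _ = small_cohort
        rep = behaviour.rm_anova(behaviour.accuracy_table(dataset))
        assert (rep["hf_epsilon"] == 1.0).all()
        assert np.allclose(rep["p_hf"], rep["p"])
        assert (rep["F"] >= 0).all()
        assert ((rep["partial_eta2"] >= 0) & (rep["partial_eta2"] <= 1)).all()
        # covariate interactions present for every within effect
        assert "Phase x Drug x WM" in set(rep["effect"])

    def test_unbalanced_design_rejected_with_cells_named(self, small_cohort):
        dataset, _, _ = small_cohort
        table = behaviour.accuracy_table(dataset)
        broken = table.drop(table[(table.subject == "S001")
                                  & (table.drug == "MPH")].index)
        with pytest.raises(ValueError, match="missing cells"):
            behaviour.rm_anova(broken)


class TestSimpleEffects:
    def test_injected_acquisition_only_effect_is_localised(self):
        """Score-level power experiment: an acquisition-only drug-by-WM
        interaction shows up in the acquisition split and not in the
        reversal split in >= 80% of replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            table = _score_table(rng, effect=0.02)
            se = behaviour.simple_effects(table, split_by="phase",
                                          covariates=("wm_span", "bis"))
            pa = se["acquisition"].query("effect == 'Drug x WM'")["p"].iloc[0]
            pr = se["reversal"].query("effect == 'Drug x WM'")["p"].iloc[0]
            hits += (pa < 0.05) and (pr >= 0.05)
        assert hits >= 80

    def test_null_split_behaves_like_null(self):
        rng = np.random.default_rng(13)
        sig = 0
        for _ in range(60):
            table = _score_table(rng, effect=0.0)
            se = behaviour.simple_effects(table, split_by="phase",
                                          covariates=("wm_span", "bis"))
            sig += (se["acquisition"].query("effect == 'Drug x WM'")["p"]
                    .iloc[0] < 0.05)
        assert sig <= 10  # ~5% nominal

    def test_degenerate_split_rejected(self, small_cohort):
        dataset, _, _ = small_cohort
        table = behaviour.accuracy_table(dataset)
        with pytest.raises(ValueError, match="unknown factor"):
            behaviour.simple_effects(table, split_by="nope")
        with pytest.raises(ValueError, match="fewer than 2"):
            behaviour.simple_effects(table[table.phase == "reversal"],
                                     split_by="phase")


class TestParameterChangeStats:
    def _inputs(self, delta):
        n = len(delta)
        params = pd.DataFrame({"phi_placebo": np.full(n, 0.6),
                               "phi_MPH": 0.6 + delta})
        cov = pd.DataFrame({"wm_span": np.arange(n), "bis": np.zeros(n)})
        return params, cov

    def test_zero_change_gives_null_t(self):
        params, cov = self._inputs(np.zeros(10))
        out = behaviour.parameter_change_stats(params, cov)
        assert out["t"] == 0.0 and out["p_t"] == 1.0

    def test_monotone_change_gives_perfect_rank_correlation(self):
        params, cov = self._inputs(np.linspace(-0.1, 0.1, 12))
        out = behaviour.parameter_change_stats(params, cov)
        assert out["spearman_wm_r"] == pytest.approx(1.0)

    def test_spearman_with_ties_matches_rank_then_pearson(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            delta = rng.integers(-3, 4, 20) / 10.0  # heavy ties
            wm = rng.integers(10, 20, 20).astype(float)
            params, cov = self._inputs(delta)
            cov["wm_span"] = wm
            out = behaviour.parameter_change_stats(params, cov)
            r_oracle = np.corrcoef(stats.rankdata(delta), stats.rankdata(wm))[0, 1]
            assert out["spearman_wm_r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_performance_change_correlation_reported(self, small_cohort):
        dataset, subjects, _ = small_cohort
        table = behaviour.accuracy_table(dataset)
        perf = behaviour.performance_change(table)
        params = pd.DataFrame({
            "phi_placebo": np.linspace(0.4, 0.8, len(perf)),
            "phi_MPH": np.linspace(0.5, 0.7, len(perf))}, index=perf.index)
        cov = subjects.rename_axis("subject")[["wm_span", "bis"]]
        out = behaviour.parameter_change_stats(params, cov, perf)
        assert "spearman_perf_r" in out and np.isfinite(out["spearman_perf_r"])

    def test_wm_median_split_puts_median_in_low_group(self):
        wm = pd.Series([10, 20, 30, 40, 50])
        groups = behaviour.wm_median_split(wm)
        assert list(groups) == ["low", "low", "low", "high", "high"]

    def test_minimum_sample_size(self):
        params, cov = self._inputs(np.zeros(2))
        with pytest.raises(ValueError, match="at least 3"):
            behaviour.parameter_change_stats(params, cov)
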
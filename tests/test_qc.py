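"""Baseline CV quality control and the Kruskal-Wallis / Dunn statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microecg import SimConfig, apply_inclusion, compare_doses, compute_cv, \
    simulate_recording
from microecg.errors import InsufficientBeatsError
from microecg.qc import QCReport


class TestCV:
    def test_constant_bp_has_zero_cv(self):
        assert compute_cv([1.0, 1.0, 1.0]) == 0.0

    def test_hand_computed_example(self):
        # mean 4/3, sample SD sqrt(1/3) = 0.5774 -> 43.3 %
        assert compute_cv([1.0, 1.0, 2.0]) == pytest.approx(43.30127, abs=1e-4)

    def test_fewer_than_two_beats_raises(self):
        with pytest.raises(InsufficientBeatsError):
            compute_cv([1.0])

    def test_programmed_cv_recovered_from_simulation(self):
        # ~100 beats with 5 % programmed BP CV -> estimate within 1.5 points
        rec, gt = simulate_recording(SimConfig(
            duration=105.0, bp_mean=1.0, bp_cv_pct=5.0, fpd_mean=0.35, seed=0))
        assert len(gt.bp) >= 100
        assert compute_cv(gt.bp) == pytest.approx(5.0, abs=1.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=2 ** 16))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        bp = rng.uniform(0.5, 3.0, size=20)
        assert compute_cv(bp * scale) == pytest.approx(compute_cv(bp), rel=1e-9)


class TestInclusion:
    @pytest.mark.parametrize("cv,expected", [
        (13.0, True),    # typical included tissue
        (25.0, True),    # boundary: only strictly-above is discarded
        (25.1, False),
    ])
    def test_rule(self, cv, expected):
        assert apply_inclusion(cv) is expected

    def test_monotone_in_cv(self):
        grid = np.linspace(0.0, 60.0, 121)
        flags = [apply_inclusion(cv) for cv in grid]
        # once excluded, always excluded
        assert flags == sorted(flags, reverse=True)

    def test_report_from_baseline(self):
        report = QCReport.from_baseline("T1", [1.0, 1.1, 0.9, 1.0])
        assert report.included
        assert report.tissue_id == "T1"


class TestGroupComparison:
    def test_identical_groups_do_not_reject(self):
        groups = {"baseline": [1.0, 2.0, 3.0], "dose": [1.0, 2.0, 3.0]}
        res = compare_doses(groups)
        assert res.pvalue > 0.9
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_separated_groups_hand_rank_formula(self):
        # ranks 1-5 vs 6-10: H = 12/110 * (5*(3-5.5)^2 + 5*(8-5.5)^2) = 6.8182
        groups = {"a": [1, 2, 3, 4, 5], "b": [10, 11, 12, 13, 14]}
        res = compare_doses(groups)
        assert res.statistic == pytest.approx(6.81818, abs=1e-4)

    def test_dunn_against_frozen_hand_computation(self):
        # two groups, no ties: mean ranks 3 and 8; var = (10*11/12)*(2/5)
        # z = (3-8)/sqrt(11/3) = -2.6112; p = 2*(1-Phi(2.6112)) = 0.009023
        groups = {"a": [1, 2, 3, 4, 5], "b": [10, 11, 12, 13, 14]}
        res = compare_doses(groups, baseline_group="a")
        row = res.dunn.iloc[0]
        assert row["z"] == pytest.approx(-2.61116, abs=1e-4)
        assert row["p_unadjusted"] == pytest.approx(0.009023, abs=1e-5)
        assert res.adjustment == "bonferroni"

    def test_all_tied_degenerate_input_warns(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}
        res = compare_doses(groups)
        assert res.warning is not None
        assert res.statistic == 0.0

    def test_type_one_error_calibrated(self):
        """Three null groups, alpha 0.05: rejection rate within 0.05 +/- 0.02."""
        rng = np.random.default_rng(42)
        n_sim, rejections = 1000, 0
        for _ in range(n_sim):
            groups = {k: rng.normal(size=5) for k in ("g1", "g2", "g3")}
            if compare_doses(groups).pvalue < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_doses({"only": [1, 2, 3]})
        with pytest.raises(ValueError):
            compare_doses({"a": [1], "b": [1, 2]})


class TestCohortSummary:
    def test_cohort_means_recovered_within_two_sem(self):
        """A simulated cohort programmed to the published baseline spread
        (BP 1.9 +/- 0.7 s, FPD 0.69 +/- 0.25 s) is summarized to within
        2 SEM of the programmed means."""
        from microecg import FieldPotentialModel
        from microecg.qc import cohort_summary

        rng = np.random.default_rng(11)
        n_tissues, reports = 12, []
        bp_pop, bp_sd = 1.9, 0.7
        fpd_pop, fpd_sd = 0.69, 0.25
        for i in range(n_tissues):
            bp = float(np.clip(rng.normal(bp_pop, bp_sd), 1.0, 3.5))
            fpd = float(np.clip(rng.normal(fpd_pop, fpd_sd), 0.3,
                                bp - 0.25))
            rec, _ = simulate_recording(SimConfig(
                duration=30.0, bp_mean=bp, fpd_mean=fpd, seed=1000 + i))
            from microecg import AnalysisConfig
            res = FieldPotentialModel(
                rec, AnalysisConfig.for_geometry(bp, fpd)).fit()
            reports.append(QCReport.from_baseline(
                f"T{i}", res.beat_table["bp_s"].dropna(),
                baseline=res.ep_summary))
        table = cohort_summary(reports).set_index("parameter")
        assert table.loc["bp_s", "n_tissues"] >= 10
        for param, pop_mean, pop_sd in (("bp_s", bp_pop, bp_sd),
                                        ("fpd_s", fpd_pop, fpd_sd)):
            sem = pop_sd / np.sqrt(table.loc[param, "n_tissues"])
            # truncation shifts the programmed population mean slightly, so
            # compare against the realized programmed values via 2 SEM
            assert abs(table.loc[param, "mean"] - pop_mean) <= 2 * sem
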
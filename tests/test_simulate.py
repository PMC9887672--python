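"""The synthetic field-potential generator and its ground truth."""

import numpy as np
import pytest

from microecg import (AnalysisConfig, FieldPotentialModel, HillEffect,
                      SimConfig, simulate_drug_experiment, simulate_recording)
from microecg.beats import detect_depolarizations
from microecg.errors import ConfigurationError


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(duration=10.0, seed=5, ectopic_rate_per_min=2.0)
        rec1, gt1 = simulate_recording(cfg)
        rec2, gt2 = simulate_recording(cfg)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)
        np.testing.assert_array_equal(gt1.beat_times, gt2.beat_times)

    def test_noise_seed_does_not_move_ground_truth(self):
        cfg = SimConfig(duration=20.0, seed=5, ectopic_rate_per_min=2.0)
        rec1, gt1 = simulate_recording(cfg)
        rec2, gt2 = simulate_recording(cfg.replace(noise_seed=999))
        np.testing.assert_array_equal(gt1.beat_times, gt2.beat_times)
        np.testing.assert_array_equal(gt1.fpd, gt2.fpd)
        np.testing.assert_array_equal(gt1.ectopic_times, gt2.ectopic_times)
        assert not np.array_equal(rec1.samples, rec2.samples)


class TestRendering:
    def test_beat_count_matches_period(self):
        rec, gt = simulate_recording(SimConfig(
            duration=10.0, bp_mean=1.0, bp_cv_pct=0.0, fpd_mean=0.4,
            noise_snr_db=None, seed=0))
        assert abs(len(gt.beat_times) - 10) <= 1

    def test_annotations_sit_on_rendered_extrema(self):
        rec, gt = simulate_recording(SimConfig(
            duration=10.0, bp_mean=1.0, fpd_mean=0.4, noise_snr_db=None,
            seed=0))
        x = rec.samples[0]
        for bt in gt.beat_times:
            i = int(round(bt * rec.sampling_rate))
            lo, hi = i - 40, i + 40
            assert i == lo + int(np.argmax(np.abs(x[lo:hi])))

    def test_requested_snr_realized_within_one_db(self):
        cfg = SimConfig(duration=30.0, noise_snr_db=20.0, seed=3)
        noisy, _ = simulate_recording(cfg)
        clean, _ = simulate_recording(cfg.replace(noise_snr_db=None))
        noise = noisy.samples[0] - clean.samples[0]
        snr = 10 * np.log10(np.mean(clean.samples[0] ** 2)
                            / np.mean(noise ** 2))
        assert snr == pytest.approx(20.0, abs=1.0)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(bp_mean=0.8, fpd_mean=0.9)

    def test_cessation_stops_beats(self):
        rec, gt = simulate_recording(SimConfig(
            duration=30.0, cessation_after=10.0, seed=2))
        assert gt.beat_times.max() <= 10.0

    def test_redetection_recovers_nearly_all_beats(self):
        """Rendering then re-detecting at high SNR finds >= 99 % of beats."""
        total, found = 0, 0
        for seed in range(10):
            rec, gt = simulate_recording(SimConfig(
                duration=30.0, noise_snr_db=40.0, seed=seed))
            table = detect_depolarizations(
                rec.samples[0], rec.sampling_rate,
                AnalysisConfig.for_geometry(1.9, 0.69))
            total += len(gt.beat_times)
            det = table["peak_time_s"].to_numpy()
            found += sum(np.min(np.abs(det - bt)) <= 0.005
                         for bt in gt.beat_times)
        assert found / total >= 0.99


class TestHillExperiments:
    def test_analytic_crossing_dose(self):
        eff = HillEffect(emax_pct=30.0, ec50=0.1)
        dose = eff.crossing_dose(15.0)
        assert eff.true_pct_dfpdcf(dose) == pytest.approx(15.0, abs=0.01)

    def test_null_effect_has_zero_true_change(self):
        eff = HillEffect(emax_pct=0.0, ec50=1.0)
        for d in (0.01, 1.0, 100.0):
            assert eff.true_pct_dfpdcf(d) == 0.0

    def test_bp_slowing_reduces_corrected_change(self):
        both = HillEffect(emax_pct=30.0, ec50=0.1, bp_emax_pct=20.0)
        fpd_only = HillEffect(emax_pct=30.0, ec50=0.1)
        assert both.true_pct_dfpdcf(1.0) < fpd_only.true_pct_dfpdcf(1.0)

    def test_arrhythmia_programming_counts_tissues(self):
        base = SimConfig(duration=20.0, seed=0)
        eff = HillEffect(emax_pct=0.0, ec50=1.0, arrhythmia_above=0.4,
                         arrhythmia_tissue_fraction=2.0 / 3.0)
        doses = [0.1, 0.2, 0.4, 0.8]
        exp = simulate_drug_experiment(base, doses, n_tissues=3, effect=eff,
                                       seed=9)
        affected = {tid for tid in exp.tissue_ids
                    if len(exp.ground_truths[(tid, 0.4)].ectopic_times)}
        assert len(affected) == 2
        for tid in exp.tissue_ids:
            assert len(exp.ground_truths[(tid, 0.2)].ectopic_times) == 0

    def test_experiment_manifest_round_trip(self, tmp_path):
        from microecg.manifest import load_manifest
        from microecg.simulate import write_experiment

        base = SimConfig(duration=12.0, seed=1)
        eff = HillEffect(emax_pct=10.0, ec50=1.0)
        exp = simulate_drug_experiment(base, [0.5, 1.0], n_tissues=2,
                                       effect=eff, seed=3)
        mpath = write_experiment(exp, tmp_path, base, c_max=1.0, f_etpc=1.0)
        manifest = load_manifest(mpath)
        assert [c.name for c in manifest.compounds] == ["simdrug"]
        assert manifest.compounds[0].doses == [0.5, 1.0]
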
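"""Template averaging, cross-correlation alignment and fiducial extraction."""

import numpy as np
import pandas as pd
import pytest

from microecg import AnalysisConfig, SimConfig, simulate_recording
from microecg.beats import (build_average_patterns, detect_depolarizations,
                            locate_fiducials, PatternPair)
from microecg.errors import DegeneratePatternError

FS = 2000.0


def _detect(rec, bp, fpd):
    cfg = AnalysisConfig.for_geometry(bp, fpd)
    return detect_depolarizations(rec.samples[0], rec.sampling_rate, cfg), cfg


class TestAveraging:
    def test_identical_beats_average_to_single_window(self):
        rec, gt = simulate_recording(SimConfig(
            duration=12.0, bp_mean=1.0, bp_cv_pct=0.0, fpd_mean=0.4,
            fpd_cv_pct=0.0, noise_snr_db=None, seed=0))
        beats, cfg = _detect(rec, 1.0, 0.4)
        assert len(beats) >= 10
        patterns, refined = build_average_patterns(
            rec.samples[0], beats, rec.sampling_rate, cfg)
        # any single complete window equals the template
        ok = refined[refined["flag"] == ""].iloc[2]
        s = (int(ok["peak_index"])
             + int(round(cfg.depol_start_offset * rec.sampling_rate))
             + int(ok["align_offset_depol"]))
        window = rec.samples[0][s:s + len(patterns.depol)]
        np.testing.assert_allclose(patterns.depol, window, rtol=1e-9, atol=1e-9)
        assert patterns.convergence_iterations <= 2

    def test_injected_jitter_recovered_exactly(self):
        """Shifting the detected peaks by known integers is undone by the
        alignment, up to a common constant offset."""
        rec, gt = simulate_recording(SimConfig(
            duration=16.0, bp_mean=1.5, bp_cv_pct=0.0, fpd_mean=0.5,
            fpd_cv_pct=0.0, noise_snr_db=None, seed=1))
        beats, cfg = _detect(rec, 1.5, 0.5)
        rng = np.random.default_rng(0)
        jitter = rng.integers(-10, 11, size=len(beats))
        shifted = beats.copy()
        shifted["peak_index"] = beats["peak_index"] + jitter
        shifted["peak_time_s"] = shifted["peak_index"] / rec.sampling_rate
        patterns, refined = build_average_patterns(
            rec.samples[0], shifted, rec.sampling_rate, cfg)
        off = refined["align_offset_depol"].to_numpy()
        undo = off + jitter  # should be the same constant for every beat
        inner = refined["flag"].to_numpy() == ""
        assert len(np.unique(undo[inner])) == 1

    def test_alignment_error_does_not_increase(self):
        rec, _ = simulate_recording(SimConfig(duration=30.0, seed=5))
        beats, cfg = _detect(rec, 1.9, 0.69)
        patterns, _ = build_average_patterns(
            rec.samples[0], beats, rec.sampling_rate, cfg)
        mse = np.asarray(patterns.alignment_mse)
        assert patterns.convergence_iterations <= cfg.max_align_iterations
        assert mse[-1] <= mse[0] * (1 + 1e-9)
        # per-step non-increase with a small numerical slack
        assert np.all(np.diff(mse) <= 0.01 * mse[:-1] + 1e-12)

    def test_single_beat_is_its_own_template(self):
        rec, _ = simulate_recording(SimConfig(
            duration=12.0, bp_mean=1.0, fpd_mean=0.4, noise_snr_db=None, seed=0))
        beats, cfg = _detect(rec, 1.0, 0.4)
        one = beats.iloc[[3]].reset_index(drop=True)
        patterns, _ = build_average_patterns(
            rec.samples[0], one, rec.sampling_rate, cfg)
        assert patterns.n_beats_averaged == 1
        assert patterns.convergence_iterations == 0

    def test_out_of_bounds_window_dropped_not_raised(self):
        rec, _ = simulate_recording(SimConfig(
            duration=12.0, bp_mean=1.0, fpd_mean=0.4, noise_snr_db=None, seed=0))
        beats, cfg = _detect(rec, 1.0, 0.4)
        # append a fake beat whose repol window exceeds the trace
        extra = beats.iloc[[-1]].copy()
        extra["peak_index"] = rec.n_samples - 10
        extra["peak_time_s"] = extra["peak_index"] / rec.sampling_rate
        beats2 = pd.concat([beats, extra], ignore_index=True)
        patterns, refined = build_average_patterns(
            rec.samples[0], beats2, rec.sampling_rate, cfg)
        assert (refined["flag"] != "").sum() >= 1
        assert patterns.n_beats_averaged <= len(beats2)


class TestFiducials:
    def test_depol_peak_at_annotated_extremum(self):
        rec, gt = simulate_recording(SimConfig(
            duration=20.0, noise_snr_db=None, bp_cv_pct=0.0, fpd_cv_pct=0.0,
            seed=2))
        beats, cfg = _detect(rec, 1.9, 0.69)
        patterns, _ = build_average_patterns(
            rec.samples[0], beats, rec.sampling_rate, cfg)
        fids = locate_fiducials(patterns, rec.sampling_rate, cfg)
        # detected peaks sit on the spike extremum, so the template peak
        # offset must be zero within one sample
        assert abs(fids.depol_peak_offset) <= 1.0 / rec.sampling_rate + 1e-12
        assert fids.depol_onset_offset < fids.depol_peak_offset

    def test_repol_fiducial_at_programmed_fpd(self):
        rec, gt = simulate_recording(SimConfig(
            duration=30.0, bp_mean=1.2, fpd_mean=0.40, fpd_cv_pct=0.0,
            noise_snr_db=30.0, seed=4))
        beats, cfg = _detect(rec, 1.2, 0.40)
        patterns, _ = build_average_patterns(
            rec.samples[0], beats, rec.sampling_rate, cfg)
        fids = locate_fiducials(patterns, rec.sampling_rate, cfg)
        assert fids.repol_peak_offset == pytest.approx(0.40, abs=0.01)

    def test_flat_template_raises(self):
        cfg = AnalysisConfig()
        flat = PatternPair(depol=np.ones(1000), repol=np.ones(1400),
                           n_beats_averaged=3, convergence_iterations=1)
        with pytest.raises(DegeneratePatternError):
            locate_fiducials(flat, FS, cfg)
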
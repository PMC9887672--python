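"""Fridericia correction, percent changes, threshold calls and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microecg import (ThresholdSet, assemble_dose_response, call_thresholds,
                      fridericia_correct, percent_change)
from microecg.beats import EPSummary
from microecg.dose import DIR_DOWN, DIR_NONE, DIR_UP, DoseResponse
from microecg.errors import InputError


class TestFridericia:
    def test_published_baseline_example(self):
        # FPD 0.69 s at BP 1.9 s -> 0.557 s, printed as 0.56 s
        value = fridericia_correct(0.69, 1.9)
        assert value == pytest.approx(0.5571, abs=5e-4)
        assert round(value, 2) == 0.56

    def test_identity_at_one_hertz(self):
        assert fridericia_correct(0.45, 1.0) == pytest.approx(0.45)

    def test_exact_cube(self):
        assert fridericia_correct(0.5, 8.0) == pytest.approx(0.25)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(InputError):
            fridericia_correct(0.0, 1.0)
        with pytest.raises(InputError):
            fridericia_correct(0.5, -1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(fpd=st.floats(0.05, 2.0), bp=st.floats(0.2, 10.0),
           c=st.floats(0.1, 10.0))
    def test_homogeneity(self, fpd, bp, c):
        assert fridericia_correct(c * fpd, bp) == pytest.approx(
            c * fridericia_correct(fpd, bp), rel=1e-12)


class TestPercentChange:
    @pytest.mark.parametrize("base,val,expected", [
        (0.56, 0.70, 25.0),
        (0.56, 0.56, 0.0),
        (0.60, 0.48, -20.0),
    ])
    def test_examples(self, base, val, expected):
        assert percent_change(base, val) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(InputError):
            percent_change(0.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=st.floats(0.1, 5.0), b=st.floats(0.1, 5.0))
    def test_swap_identity(self, a, b):
        # pc(a,b) = -100*pc(b,a)/(100+pc(b,a))
        forward = percent_change(a, b)
        backward = percent_change(b, a)
        assert forward == pytest.approx(-100.0 * backward / (100.0 + backward),
                                        rel=1e-9)


def make_dr(doses, pcts, **kwargs):
    table = pd.DataFrame({
        "dose": doses, "pct_dfpdcf_mean": pcts,
        "pct_dfpdcf_sem": np.zeros(len(doses)),
    })
    defaults = dict(compound="x", vehicle=False, doses=np.asarray(doses),
                    table=table)
    defaults.update(kwargs)
    return DoseResponse(**defaults)


class TestCallThresholds:
    def test_dofetilide_style_margin(self):
        dr = make_dr([0.001, 0.002, 0.01], [12.0, 17.0, 30.0], c_max=0.002)
        call = call_thresholds(dr)
        mid = call.at("MID")
        assert mid.direction == DIR_UP
        assert mid.concentration == pytest.approx(0.002)
        assert mid.margin == pytest.approx(1.0)

    def test_high_margin_scales_with_concentration(self):
        # MID at 1 uM, HIGH at 10 uM with C_max 0.3 -> margins 3.33 and 33.3
        dr = make_dr([0.06, 1.0, 10.0], [11.0, 16.0, 25.0], c_max=0.3)
        call = call_thresholds(dr)
        assert call.at("MID").margin == pytest.approx(3.333, abs=5e-3)
        assert call.at("HIGH").margin == pytest.approx(10 * call.at("MID").margin)

    def test_no_crossing_everywhere(self):
        dr = make_dr([1.0, 2.0, 3.0], [2.0, -4.0, 6.0])
        call = call_thresholds(dr)
        for name in ("LOW", "MID", "HIGH"):
            assert call.at(name).direction == DIR_NONE
            assert call.at(name).concentration is None

    def test_shortening_called_at_same_absolute_cutoffs(self):
        dr = make_dr([0.1, 0.5], [-12.0, -22.0])
        call = call_thresholds(dr)
        assert call.at("LOW").direction == DIR_DOWN
        assert call.at("HIGH").direction == DIR_DOWN
        assert call.at("HIGH").concentration == pytest.approx(0.5)

    def test_effective_concentration_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            doses = np.sort(rng.uniform(0.01, 10.0, 5))
            pcts = np.sort(rng.uniform(0.0, 40.0, 5))  # monotone response
            call = call_thresholds(make_dr(doses, pcts))
            concs = [call.at(n).concentration for n in ("LOW", "MID", "HIGH")]
            present = [c for c in concs if c is not None]
            assert present == sorted(present)
            # once absent, absent for every higher threshold
            absent_started = False
            for c in concs:
                if c is None:
                    absent_started = True
                else:
                    assert not absent_started


def summary_with(fpd_cf, cessation=False):
    return EPSummary(bp_mean=1.9, bp_sd=0.1, fpd_mean=0.69, fpd_sd=0.02,
                     fpd_cf_mean=fpd_cf, fpd_cf_sd=0.02, amp_mean=250.0,
                     amp_sd=10.0, n_beats=30, total_duration=60.0,
                     snr_db=25.0, cessation=cessation)


class _Obj:
    def __init__(self, summary, arrhythmia=False):
        self.ep_summary = summary
        self.arrhythmia_detected = arrhythmia


class TestAssemble:
    def test_cessation_fraction_counted(self):
        doses = [1.0, 2.0, 3.0]
        tissues = {}
        for i, tid in enumerate(("T1", "T2", "T3")):
            entry = {"baseline": _Obj(summary_with(0.56)), "doses": {}}
            for d in doses:
                ceased = (tid == "T1" and d == 3.0)
                entry["doses"][d] = _Obj(summary_with(0.56, cessation=ceased))
            tissues[tid] = entry
        dr = assemble_dose_response(tissues, "x", doses)
        assert dr.cessation
        assert dr.cessation_tissue_pct == pytest.approx(100.0 / 3.0)
        row = dr.table[dr.table["dose"] == 3.0].iloc[0]
        assert row["cessation_fraction"] == pytest.approx(1.0 / 3.0)

    def test_missing_baseline_excluded(self, caplog):
        doses = [1.0]
        tissues = {
            "ok": {"baseline": _Obj(summary_with(0.56)),
                   "doses": {1.0: _Obj(summary_with(0.60))}},
            "bad": {"baseline": None,
                    "doses": {1.0: _Obj(summary_with(0.70))}},
        }
        dr = assemble_dose_response(tissues, "x", doses)
        assert dr.n_tissues == 1
        # the remaining tissue's +7.1 % is the aggregate
        assert dr.table.iloc[0]["pct_dfpdcf_mean"] == pytest.approx(
            percent_change(0.56, 0.60))

    def test_arrhythmia_lowest_dose_and_fraction(self):
        doses = [0.1, 1.0]
        tissues = {}
        for i, tid in enumerate(("T1", "T2", "T3")):
            arr = {0.1: False, 1.0: tid in ("T1", "T2")}
            tissues[tid] = {
                "baseline": _Obj(summary_with(0.56)),
                "doses": {d: _Obj(summary_with(0.56), arrhythmia=arr[d])
                          for d in doses},
            }
        dr = assemble_dose_response(tissues, "x", doses)
        assert dr.arrhythmia
        assert dr.arrhythmia_lowest_dose == pytest.approx(1.0)
        assert dr.arrhythmia_tissue_pct == pytest.approx(200.0 / 3.0)

    def test_unsorted_ladder_rejected(self):
        with pytest.raises(InputError):
            assemble_dose_response({}, "x", [1.0, 1.0])


def test_threshold_set_ordering_enforced():
    from microecg.errors import ConfigurationError
    with pytest.raises(ConfigurationError):
        ThresholdSet(LOW=20.0, MID=15.0)
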
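"""Fridericia correction, baseline-normalized dose-response and threshold calls.

Because drug exposure changes the spontaneous beating rate, the FPD is
rate-corrected with Fridericia's cube-root formula (FPDcF = FPD / BP^(1/3),
BP in seconds) before computing the percent change against each tissue's own
baseline.  A compound "crosses" a threshold T at the lowest dose whose
aggregated mean |%dFPDcF| reaches T; the sign at that dose gives the call
direction (prolongation, shortening, or no effect).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ThresholdSet
from .errors import InputError

logger = logging.getLogger(__name__)

DIR_UP = "up"
DIR_DOWN = "down"
DIR_NONE = "none"

ARROWS = {DIR_UP: "↑", DIR_DOWN: "↓", DIR_NONE: "↔"}


def fridericia_correct(fpd, bp):
    """Rate-corrected field-potential duration FPDcF = FPD / BP^(1/3).

    ``bp`` must be in seconds, so that a 1-Hz beat leaves the FPD unchanged.
    Accepts scalars or arrays; non-positive inputs raise.
    """
    fpd_arr = np.asarray(fpd, dtype=float)
    bp_arr = np.asarray(bp, dtype=float)
    if np.any(fpd_arr <= 0) or np.any(bp_arr <= 0):
        raise InputError("FPD and BP must be positive for Fridericia correction")
    out = fpd_arr / np.cbrt(bp_arr)
    return float(out) if np.isscalar(fpd) and np.isscalar(bp) else out


def percent_change(baseline, value):
    """Signed percent change 100 * (value - baseline) / baseline."""
    baseline_arr = np.asarray(baseline, dtype=float)
    if np.any(baseline_arr == 0):
        raise InputError("zero baseline in percent change")
    out = 100.0 * (np.asarray(value, dtype=float) - baseline_arr) / baseline_arr
    return float(out) if np.isscalar(value) and np.isscalar(baseline) else out


@dataclass
class ThresholdCall:
    """Direction and effective concentration at one percent-change threshold."""

    direction: str = DIR_NONE
    concentration: float | None = None  # molar-consistent units (uM throughout)
    margin: float | None = None  # concentration / C_max

    @property
    def arrow(self) -> str:
        return ARROWS[self.direction]


@dataclass
class CompoundCall:
    """Per-threshold calls for one compound."""

    compound: str
    calls: dict[str, ThresholdCall] = field(default_factory=dict)
    arrhythmia: bool = False
    arrhythmia_lowest_dose: float | None = None
    arrhythmia_tissue_pct: float | None = None
    cessation: bool = False
    cessation_tissue_pct: float | None = None
    c_max: float | None = None
    f_etpc: float | None = None
    max_tested: float | None = None

    def at(self, name: str) -> ThresholdCall:
        return self.calls.get(name, ThresholdCall())


@dataclass
class DoseResponse:
    """Aggregated dose ladder for one compound.

    ``table`` has one row per dose with columns ``dose``, ``n_tissues``,
    ``pct_dfpdcf_mean``, ``pct_dfpdcf_sem``, ``arrhythmia_fraction``,
    ``cessation_fraction`` plus per-dose EP means.
    """

    compound: str
    vehicle: bool
    doses: np.ndarray
    table: pd.DataFrame
    arrhythmia: bool = False
    arrhythmia_lowest_dose: float | None = None
    arrhythmia_tissue_pct: float | None = None
    cessation: bool = False
    cessation_tissue_pct: float | None = None
    c_max: float | None = None
    f_etpc: float | None = None
    n_tissues: int = 0

    @property
    def max_tested(self) -> float | None:
        return float(self.doses[-1]) if len(self.doses) else None


def call_thresholds(dr: DoseResponse,
                    thresholds: ThresholdSet | None = None,
                    names: tuple[str, ...] = ("LOW", "MID", "HIGH"),
                    ) -> CompoundCall:
    """Threshold-crossing calls from the aggregated mean percent changes.

    Prolongation and shortening share the same absolute cut-offs; the call
    direction is the sign of the mean change at the crossing dose.  Margins
    (crossing concentration / C_max) are attached when C_max is known.
    """
    thresholds = thresholds or ThresholdSet()
    grid = thresholds.as_dict()
    call = CompoundCall(
        compound=dr.compound,
        arrhythmia=dr.arrhythmia,
        arrhythmia_lowest_dose=dr.arrhythmia_lowest_dose,
        arrhythmia_tissue_pct=dr.arrhythmia_tissue_pct,
        cessation=dr.cessation,
        cessation_tissue_pct=dr.cessation_tissue_pct,
        c_max=dr.c_max,
        f_etpc=dr.f_etpc,
        max_tested=dr.max_tested,
    )
    pct = dr.table["pct_dfpdcf_mean"].to_numpy(dtype=float)
    doses = dr.table["dose"].to_numpy(dtype=float)
    for name in names:
        t = grid[name]
        crossed = np.nonzero(np.abs(pct) >= t)[0]
        if len(crossed) == 0:
            call.calls[name] = ThresholdCall()
            continue
        i = int(crossed[0])
        direction = DIR_UP if pct[i] > 0 else DIR_DOWN
        margin = None
        if dr.c_max is not None and dr.c_max > 0:
            margin = float(doses[i] / dr.c_max)
        call.calls[name] = ThresholdCall(direction=direction,
                                         concentration=float(doses[i]),
                                         margin=margin)
    return call


def assemble_dose_response(tissue_analyses: dict[str, dict],
                           compound: str,
                           doses,
                           vehicle: bool = False,
                           c_max: float | None = None,
                           f_etpc: float | None = None) -> DoseResponse:
    """Aggregate per-tissue analyses into a compound dose-response.

    Parameters
    ----------
    tissue_analyses : mapping of tissue id to a per-tissue dict with keys
        ``"baseline"`` (an object with ``fpd_cf_mean`` and ``cessation``
        attributes, e.g. :class:`~microecg.beats.EPSummary` or
        :class:`~microecg.model.FieldPotentialResults`-like) and ``"doses"``
        (mapping of dose to an object additionally exposing
        ``arrhythmia_detected``).  Tissues lacking a baseline are excluded
        with a log entry.
    doses : strictly increasing dose ladder (micromolar).
    """
    doses = np.asarray(sorted(doses), dtype=float)
    if len(doses) and np.any(np.diff(doses) <= 0):
        raise InputError("dose ladder must be strictly increasing")

    def _summary(obj):
        return obj.ep_summary if hasattr(obj, "ep_summary") else obj

    def _arrh(obj):
        if hasattr(obj, "arrhythmia_detected"):
            return bool(obj.arrhythmia_detected)
        return bool(getattr(obj, "arrhythmia", False))

    usable: dict[str, dict] = {}
    for tid, entry in tissue_analyses.items():
        base = entry.get("baseline")
        if base is None or not math.isfinite(_summary(base).fpd_cf_mean):
            logger.warning("tissue %s excluded from %s: missing baseline",
                           tid, compound)
            continue
        usable[tid] = entry

    rows = []
    arr_lowest, stop_lowest = None, None
    tissues_arr, tissues_stop = set(), set()
    for dose in doses:
        pcts, fpds, bps, amps = [], [], [], []
        n_arr = n_stop = n_present = 0
        for tid, entry in usable.items():
            obj = entry["doses"].get(dose)
            if obj is None:
                continue
            n_present += 1
            s = _summary(obj)
            if s.cessation:
                n_stop += 1
                tissues_stop.add(tid)
                if stop_lowest is None:
                    stop_lowest = dose
                continue
            if _arrh(obj):
                n_arr += 1
                tissues_arr.add(tid)
                if arr_lowest is None:
                    arr_lowest = dose
            base = _summary(entry["baseline"]).fpd_cf_mean
            if math.isfinite(s.fpd_cf_mean) and base > 0:
                pcts.append(percent_change(base, s.fpd_cf_mean))
            if math.isfinite(s.fpd_mean):
                fpds.append(s.fpd_mean)
            if math.isfinite(s.bp_mean):
                bps.append(s.bp_mean)
            if math.isfinite(s.amp_mean):
                amps.append(s.amp_mean)
        pcts = np.asarray(pcts, dtype=float)
        sem = (float(np.std(pcts, ddof=1) / np.sqrt(len(pcts)))
               if len(pcts) >= 2 else 0.0)
        rows.append({
            "dose": dose,
            "n_tissues": n_present,
            "pct_dfpdcf_mean": float(np.mean(pcts)) if len(pcts) else np.nan,
            "pct_dfpdcf_sem": sem,
            "fpd_mean_s": float(np.mean(fpds)) if fpds else np.nan,
            "bp_mean_s": float(np.mean(bps)) if bps else np.nan,
            "amp_mean_uV": float(np.mean(amps)) if amps else np.nan,
            "arrhythmia_fraction": n_arr / n_present if n_present else np.nan,
            "cessation_fraction": n_stop / n_present if n_present else np.nan,
        })

    n_tissues = len(usable)
    return DoseResponse(
        compound=compound,
        vehicle=vehicle,
        doses=doses,
        table=pd.DataFrame(rows),
        arrhythmia=bool(tissues_arr),
        arrhythmia_lowest_dose=arr_lowest,
        arrhythmia_tissue_pct=(100.0 * len(tissues_arr) / n_tissues
                               if n_tissues and tissues_arr else None),
        cessation=bool(tissues_stop),
        cessation_tissue_pct=(100.0 * len(tissues_stop) / n_tissues
                              if n_tissues and tissues_stop else None),
        c_max=c_max,
        f_etpc=f_etpc,
        n_tissues=n_tissues,
    )


def results_table(calls: list[CompoundCall]) -> pd.DataFrame:
    """Screen results in the published layout: per-threshold arrow +
    concentration, arrhythmia/stop columns, and C_max margins."""
    rows = []
    for c in calls:
        row = {"compound": c.compound}
        for name in ("LOW", "MID", "HIGH"):
            tc = c.at(name)
            row[f"{name}_direction"] = tc.arrow
            row[f"{name}_conc_uM"] = tc.concentration
            row[f"{name}_over_cmax"] = tc.margin
        row["arrhythmia"] = "Y" if c.arrhythmia else "N"
        row["arrhythmia_lowest_uM"] = c.arrhythmia_lowest_dose
        row["arrhythmia_tissue_pct"] = c.arrhythmia_tissue_pct
        row["cessation"] = "Y" if c.cessation else "N"
        row["cessation_tissue_pct"] = c.cessation_tissue_pct
        rows.append(row)
    return pd.DataFrame(rows)
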
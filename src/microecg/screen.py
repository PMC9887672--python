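"""End-to-end screening pipeline: recordings -> calls -> concordance -> risk.

Two entry modes exist.  Signal-level: a :class:`~microecg.manifest.RunManifest`
pointing at raw recordings is analyzed tissue by tissue, QC-filtered,
aggregated into dose-responses and called against the thresholds.
Table-level: pre-computed per-compound calls (e.g. the packaged reference
panel) skip the signal stage and feed the concordance and risk stages
directly, which is how the published classification metrics are reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import concordance as _conc
from . import dose as _dose
from . import qc as _qc
from . import risk as _risk
from .config import ThresholdSet
from .dose import CompoundCall, DoseResponse
from .errors import MicroECGError
from .manifest import RunManifest
from .model import FieldPotentialModel

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Everything a screening campaign produces."""

    calls: dict[str, CompoundCall]
    dose_responses: dict[str, DoseResponse] = field(default_factory=dict)
    qc_reports: list = field(default_factory=list)
    not_evaluable: list[str] = field(default_factory=list)

    def results_table(self) -> pd.DataFrame:
        return _dose.results_table(list(self.calls.values()))

    def concordance(self, labels: pd.DataFrame) -> dict:
        qt_cm = _conc.build_confusion(_conc.classify_qt(self.calls), labels,
                                      _conc.ENDPOINT_QT)
        tdp_cm = _conc.build_confusion(_conc.classify_arrhythmia(self.calls),
                                       labels, _conc.ENDPOINT_TDP)
        return {
            "qt": {"confusion": qt_cm, "metrics": _conc.compute_metrics(qt_cm)},
            "tdp": {"confusion": tdp_cm, "metrics": _conc.compute_metrics(tdp_cm)},
        }

    def risk_table(self, exclude_vehicle: str | None = "DMSO") -> pd.DataFrame:
        return _risk.assess_panel(self.calls, exclude_vehicle=exclude_vehicle)


def analyze_manifest(manifest: RunManifest,
                     thresholds: ThresholdSet | None = None,
                     cv_threshold: float = _qc.DEFAULT_CV_THRESHOLD
                     ) -> ScreenResult:
    """Signal-level screen: analyze every recording, QC, aggregate, call."""
    thresholds = thresholds or ThresholdSet()
    result = ScreenResult(calls={})
    for compound in manifest.compounds:
        tissue_analyses: dict[str, dict] = {}
        for tissue in compound.tissues:
            try:
                base_res = FieldPotentialModel.from_file(
                    tissue.baseline_path, config=manifest.analysis).fit()
            except MicroECGError as exc:
                logger.warning("baseline of %s/%s failed: %s",
                               compound.name, tissue.tissue_id, exc)
                continue
            bp = base_res.beat_table["bp_s"].dropna()
            try:
                report = _qc.QCReport.from_baseline(
                    tissue.tissue_id, bp, baseline=base_res.ep_summary,
                    cv_threshold=cv_threshold)
            except MicroECGError:
                report = _qc.QCReport(tissue.tissue_id, float("inf"), False,
                                      base_res.ep_summary)
            result.qc_reports.append(report)
            if not report.included:
                logger.info("tissue %s excluded by QC (CV %.1f%%)",
                            tissue.tissue_id, report.cv_bp_percent)
                continue
            entry = {"baseline": base_res, "doses": {}}
            for dose_um, path in tissue.dose_paths.items():
                try:
                    entry["doses"][dose_um] = FieldPotentialModel.from_file(
                        path, config=manifest.analysis).fit()
                except MicroECGError as exc:
                    logger.warning("dose %.4g of %s/%s failed: %s", dose_um,
                                   compound.name, tissue.tissue_id, exc)
            tissue_analyses[tissue.tissue_id] = entry
        if not tissue_analyses:
            result.not_evaluable.append(compound.name)
            continue
        dr = _dose.assemble_dose_response(
            tissue_analyses, compound.name, compound.doses,
            vehicle=compound.vehicle, c_max=compound.c_max_uM,
            f_etpc=compound.f_etpc_uM)
        result.dose_responses[compound.name] = dr
        result.calls[compound.name] = _dose.call_thresholds(dr, thresholds)
    return result


def screen_from_calls(calls: dict[str, CompoundCall]) -> ScreenResult:
    """Table-level screen from pre-computed compound calls."""
    return ScreenResult(calls=dict(calls))
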
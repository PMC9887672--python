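"""Model/Results facade over the field-potential analysis pipeline.

``FieldPotentialModel`` wraps a recording plus an :class:`AnalysisConfig`;
``fit()`` runs channel selection, the enabled zero-phase filters and the
three analysis phases, returning a :class:`FieldPotentialResults` carrying
the per-beat table, the averaged patterns, fiducials, the mean +/- SD
summary with SNR, the residual report and the cessation flag.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beats as _beats
from . import io as _io
from .beats import (EPSummary, FiducialSet, PatternPair, ResidualReport,
                    empty_beat_table)
from .config import AnalysisConfig
from .errors import (DegeneratePatternError, InputError, MicroECGError,
                     NoAnalyzableChannelError)
from .filters import preprocess
from .recording import FPRecording


@dataclass
class FieldPotentialResults:
    """Fitted beat-level description of one field-potential trace."""

    channel_id: str
    config: AnalysisConfig
    sampling_rate: float
    beat_table: pd.DataFrame
    patterns: PatternPair | None
    fiducials: FiducialSet | None
    ep_summary: EPSummary
    residual_report: ResidualReport | None
    filtered: np.ndarray

    @property
    def n_beats(self) -> int:
        return self.ep_summary.n_beats

    @property
    def snr_db(self) -> float:
        return self.ep_summary.snr_db

    @property
    def cessation(self) -> bool:
        return self.ep_summary.cessation

    @property
    def arrhythmia_detected(self) -> bool:
        return bool(self.residual_report and self.residual_report.arrhythmia_detected)

    def summary_frame(self) -> pd.DataFrame:
        d = self.ep_summary.as_dict()
        d["channel_id"] = self.channel_id
        d["arrhythmia_detected"] = self.arrhythmia_detected
        d["n_irregular_events"] = (len(self.residual_report.irregular_peaks)
                                   if self.residual_report else 0)
        return pd.DataFrame([d])

    def summary(self) -> str:
        """Human-readable summary table, statsmodels style."""
        s = self.ep_summary
        rows = [
            ("channel", self.channel_id),
            ("n beats", f"{s.n_beats}"),
            ("duration [s]", f"{s.total_duration:.2f}"),
            ("BP [s]", f"{s.bp_mean:.4f} +/- {s.bp_sd:.4f}"),
            ("FPD [s]", f"{s.fpd_mean:.4f} +/- {s.fpd_sd:.4f}"),
            ("FPDcF [s]", f"{s.fpd_cf_mean:.4f} +/- {s.fpd_cf_sd:.4f}"),
            ("AMP [uV]", f"{s.amp_mean:.1f} +/- {s.amp_sd:.1f}"),
            ("SNR [dB]", f"{s.snr_db:.1f}"),
            ("FPD endpoints", s.fpd_mode),
            ("cessation", str(s.cessation)),
            ("arrhythmic events", f"{len(self.residual_report.irregular_peaks) if self.residual_report else 0}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Field potential analysis", "=" * 40]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)

    def save(self, outdir: str | os.PathLike, prefix: str = "fp") -> dict[str, str]:
        """Write beat table, summary and event files; returns written paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "beats": os.path.join(outdir, f"{prefix}_beats.csv"),
            "summary": os.path.join(outdir, f"{prefix}_summary.csv"),
            "events": os.path.join(outdir, f"{prefix}_events.csv"),
        }
        _io.write_beat_table(self.beat_table, paths["beats"])
        self.summary_frame().to_csv(paths["summary"], index=False)
        _io.write_events(self.residual_report.irregular_peaks
                         if self.residual_report else [], paths["events"])
        return paths


class FieldPotentialModel:
    """Semi-automatic analysis model for one (possibly multichannel) recording.

    Parameters
    ----------
    recording : FPRecording
        The raw recording; with more than one channel the cleaner channel
        (highest reconstruction SNR) is selected at fit time.
    config : AnalysisConfig, optional
        Operator settings; defaults are the usual microtissue values.
    manual_peaks : array-like of float, optional
        Depolarization peak times (s) from a manual-annotation sidecar;
        these override automatic detection for signals the software cannot
        recognize on its own.
    """

    def __init__(self, recording: FPRecording,
                 config: AnalysisConfig | None = None,
                 manual_peaks: np.ndarray | None = None):
        self.recording = recording
        self.config = config or AnalysisConfig()
        self.manual_peaks = (None if manual_peaks is None
                             else np.sort(np.asarray(manual_peaks, dtype=float)))
        self.config.validate_against_rate(recording.sampling_rate)

    @classmethod
    def from_file(cls, path: str | os.PathLike,
                  config: AnalysisConfig | None = None,
                  annotations: str | os.PathLike | None = None
                  ) -> "FieldPotentialModel":
        rec = _io.read_recording(path)
        peaks = _io.read_manual_annotations(annotations) if annotations else None
        return cls(rec, config=config, manual_peaks=peaks)

    @classmethod
    def from_array(cls, x: np.ndarray, sampling_rate: float,
                   config: AnalysisConfig | None = None) -> "FieldPotentialModel":
        return cls(FPRecording(np.asarray(x, dtype=float), sampling_rate),
                   config=config)

    # -- fitting -----------------------------------------------------------

    def _fit_channel(self, x: np.ndarray) -> FieldPotentialResults:
        cfg = self.config
        fs = self.recording.sampling_rate
        if self.manual_peaks is not None:
            table = empty_beat_table()
            idx = np.round(self.manual_peaks * fs).astype(int)
            idx = idx[(idx >= 0) & (idx < len(x))]
            table["beat_index"] = np.arange(len(idx))
            table["peak_index"] = idx
            table["peak_time_s"] = idx / fs
            table["align_offset_depol"] = 0
            table["align_offset_repol"] = 0
            table["bp_s"] = np.nan
            table["fpd_s"] = np.nan
            table["fpd_cf_s"] = np.nan
            table["amp_uV"] = np.nan
            table["flag"] = "manual"
        else:
            table = _beats.detect_depolarizations(x, fs, cfg)

        if len(table) == 0:
            summary = EPSummary(
                bp_mean=np.nan, bp_sd=np.nan, fpd_mean=np.nan, fpd_sd=np.nan,
                fpd_cf_mean=np.nan, fpd_cf_sd=np.nan, amp_mean=np.nan,
                amp_sd=np.nan, n_beats=0, total_duration=len(x) / fs,
                snr_db=np.nan, cessation=True, fpd_mode=cfg.fpd_mode)
            return FieldPotentialResults(
                channel_id="", config=cfg, sampling_rate=fs,
                beat_table=table, patterns=None, fiducials=None,
                ep_summary=summary, residual_report=None, filtered=x)

        patterns, table = _beats.build_average_patterns(x, table, fs, cfg)
        try:
            fiducials = _beats.locate_fiducials(patterns, fs, cfg)
        except DegeneratePatternError:
            fiducials = FiducialSet(0.0, 0.0, None, cfg.fpd_mode)
        residual = _beats.reconstruct_and_residual(x, table, patterns, fs, cfg)
        summary, table = _beats.compute_parameters(
            x, table, fiducials, fs, cfg, patterns=patterns, residual=residual)
        residual = _beats.detect_arrhythmic_events(residual, table, patterns, fs, cfg)
        return FieldPotentialResults(
            channel_id="", config=cfg, sampling_rate=fs, beat_table=table,
            patterns=patterns, fiducials=fiducials, ep_summary=summary,
            residual_report=residual, filtered=x)

    def fit(self) -> FieldPotentialResults:
        filtered = preprocess(self.recording, self.config)
        results: dict[str, FieldPotentialResults] = {}
        failures: dict[str, str] = {}
        for cid in filtered.channel_ids:
            try:
                res = self._fit_channel(filtered.channel(cid))
            except MicroECGError as exc:
                failures[cid] = str(exc)
                continue
            res.channel_id = cid
            results[cid] = res
        if not results:
            raise NoAnalyzableChannelError(failures)
        best = select_cleaner_channel_results(results, filtered.channel_ids)
        return results[best]


def select_cleaner_channel_results(results: dict[str, FieldPotentialResults],
                                   order: list[str]) -> str:
    """Highest reconstruction SNR wins; ties and all-NaN fall back to channel order."""
    best, best_snr = None, -np.inf
    for cid in order:
        if cid not in results:
            continue
        snr = results[cid].snr_db
        score = -np.inf if not np.isfinite(snr) else snr
        if best is None or score > best_snr:
            best, best_snr = cid, score
    return best


def select_cleaner_channel(recording: FPRecording,
                           config: AnalysisConfig | None = None) -> str:
    """Run a provisional analysis on every channel and return the cleaner one.

    The qualitative criterion "depolarization and repolarization phases
    clearly better recognizable" is operationalized as the channel whose
    template reconstruction attains the highest SNR; ties break
    deterministically by channel order.
    """
    config = config or AnalysisConfig()
    filtered = preprocess(recording, config)
    model = FieldPotentialModel(recording, config)
    results: dict[str, FieldPotentialResults] = {}
    failures: dict[str, str] = {}
    for cid in filtered.channel_ids:
        try:
            res = model._fit_channel(filtered.channel(cid))
        except MicroECGError as exc:
            failures[cid] = str(exc)
            continue
        if res.n_beats == 0:
            failures[cid] = "no beats detected"
            continue
        res.channel_id = cid
        results[cid] = res
    if not results:
        raise NoAnalyzableChannelError(failures)
    return select_cleaner_channel_results(results, filtered.channel_ids)
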
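"""Three-phase semi-automatic analysis of a field-potential trace.

Phase 1 detects depolarization spikes with a Pan-Tompkins-style chain
(derivative, squaring, moving-window integration, amplitude thresholding).
Phase 2 averages per-beat depolarization and repolarization windows into
templates, iteratively re-aligned to the trace by cross-correlation.
Phase 3 locates fiducial points on the templates, maps them back onto every
beat, and derives the electrophysiological parameters (BP, FPD, AMP), the
template-superposition reconstruction, its residual, and residual-based
irregular-event (arrhythmia) and cessation flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .config import FPD_MODE_ONSET, FPD_MODE_PEAK, AnalysisConfig
from .errors import DegeneratePatternError, InputError

__all__ = [
    "PatternPair", "FiducialSet", "EPSummary", "ResidualReport",
    "detect_depolarizations", "build_average_patterns", "locate_fiducials",
    "compute_parameters", "reconstruct_and_residual",
    "detect_arrhythmic_events", "detect_cessation", "fridericia_per_beat",
]

FLAG_OK = ""
FLAG_EDGE = "window_out_of_bounds"

BEAT_DTYPES = {
    "beat_index": int, "peak_index": int, "peak_time_s": float,
    "align_offset_depol": int, "align_offset_repol": int,
    "bp_s": float, "fpd_s": float, "fpd_cf_s": float, "amp_uV": float,
    "flag": str,
}


def empty_beat_table() -> pd.DataFrame:
    return pd.DataFrame({k: pd.Series(dtype=v) for k, v in BEAT_DTYPES.items()})


@dataclass
class PatternPair:
    """Averaged depolarization / repolarization templates for one trace."""

    depol: np.ndarray
    repol: np.ndarray | None
    n_beats_averaged: int
    convergence_iterations: int
    alignment_mse: list[float] = field(default_factory=list)


@dataclass
class FiducialSet:
    """Template fiducials, as time offsets (s) relative to the depolarization peak."""

    depol_peak_offset: float
    depol_onset_offset: float
    repol_peak_offset: float | None
    fpd_mode: str

    @property
    def has_repol(self) -> bool:
        return self.repol_peak_offset is not None

    @property
    def fpd_template(self) -> float | None:
        """FPD measured on the templates, per the configured endpoint mode."""
        if self.repol_peak_offset is None:
            return None
        start = (self.depol_onset_offset if self.fpd_mode == FPD_MODE_ONSET
                 else self.depol_peak_offset)
        return self.repol_peak_offset - start


@dataclass
class EPSummary:
    """Mean +/- SD electrophysiological parameters of one recording."""

    bp_mean: float
    bp_sd: float
    fpd_mean: float
    fpd_sd: float
    fpd_cf_mean: float
    fpd_cf_sd: float
    amp_mean: float
    amp_sd: float
    n_beats: int
    total_duration: float
    snr_db: float
    cessation: bool
    fpd_mode: str = FPD_MODE_ONSET

    def as_dict(self) -> dict:
        return {
            "bp_mean_s": self.bp_mean, "bp_sd_s": self.bp_sd,
            "fpd_mean_s": self.fpd_mean, "fpd_sd_s": self.fpd_sd,
            "fpd_cf_mean_s": self.fpd_cf_mean, "fpd_cf_sd_s": self.fpd_cf_sd,
            "amp_mean_uV": self.amp_mean, "amp_sd_uV": self.amp_sd,
            "n_beats": self.n_beats, "total_duration_s": self.total_duration,
            "snr_db": self.snr_db, "cessation": self.cessation,
            "fpd_mode": self.fpd_mode,
        }


@dataclass
class ResidualReport:
    """Raw-minus-reconstruction residual and the irregular events found in it."""

    residual: np.ndarray
    irregular_peaks: list[tuple[float, float]] = field(default_factory=list)
    arrhythmia_detected: bool = False
    overlap_flagged: bool = False


# ---------------------------------------------------------------------------
# phase 1: depolarization detection


def integrated_energy(x: np.ndarray, sampling_rate: float,
                      window_s: float) -> np.ndarray:
    """Derivative -> squaring -> moving-window integration."""
    d = np.diff(x, prepend=x[:1])
    sq = d * d
    w = max(1, int(round(window_s * sampling_rate)))
    kernel = np.ones(w) / w
    return np.convolve(sq, kernel, mode="same")


def _refine_on_raw(x: np.ndarray, idx: int, half: int) -> int:
    """Snap an integrated-energy peak to the raw-trace spike extremum."""
    lo = max(0, idx - half)
    hi = min(len(x), idx + half + 1)
    base = np.median(x)
    return lo + int(np.argmax(np.abs(x[lo:hi] - base)))


def detect_depolarizations(x: np.ndarray, sampling_rate: float,
                           config: AnalysisConfig) -> pd.DataFrame:
    """Detect depolarization spikes on a single filtered trace.

    Returns a beat table with one row per accepted spike, localized on the
    raw (unsquared) trace.  An empty table (no exception) signals that no
    beats were found, which downstream becomes a cessation flag.
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise InputError("trace contains NaN samples")
    min_len = int(round(2 * config.depol_window * sampling_rate))
    if len(x) < min_len:
        raise InputError(
            f"trace of {len(x)} samples shorter than twice the depolarization "
            f"window ({min_len} samples)"
        )

    energy = integrated_energy(x, sampling_rate, config.integration_window)
    emax = energy.max()
    if emax <= 0:
        return empty_beat_table()
    threshold = config.voltage_threshold_fraction * emax
    distance = max(1, int(round(config.refractory * sampling_rate)))
    peaks, _ = _sig.find_peaks(energy, height=threshold, distance=distance)
    if len(peaks) == 0:
        return empty_beat_table()

    half = max(1, int(round(config.integration_window * sampling_rate)))
    refined = sorted({_refine_on_raw(x, p, half) for p in peaks})
    # refinement may merge neighbours; re-enforce the refractory greedily by
    # keeping the stronger spike of any violating pair
    base = np.median(x)
    kept: list[int] = []
    for idx in refined:
        if kept and idx - kept[-1] < distance:
            if abs(x[idx] - base) > abs(x[kept[-1]] - base):
                kept[-1] = idx
        else:
            kept.append(idx)

    table = empty_beat_table()
    n = len(kept)
    table["beat_index"] = np.arange(n)
    table["peak_index"] = kept
    table["peak_time_s"] = np.asarray(kept) / sampling_rate
    table["align_offset_depol"] = np.zeros(n, dtype=int)
    table["align_offset_repol"] = np.zeros(n, dtype=int)
    table["bp_s"] = np.nan
    table["fpd_s"] = np.nan
    table["fpd_cf_s"] = np.nan
    table["amp_uV"] = np.nan
    table["flag"] = FLAG_OK
    return table


# ---------------------------------------------------------------------------
# phase 2: iterative template averaging


def _window_starts(beats: pd.DataFrame, sampling_rate: float,
                   start_offset: float, offsets: np.ndarray) -> np.ndarray:
    base = beats["peak_index"].to_numpy() + int(round(start_offset * sampling_rate))
    return base + offsets


def _align_windows(x: np.ndarray, starts: np.ndarray, length: int,
                   max_shift: int, max_iter: int, tol: int):
    """Iteratively average and re-align windows by cross-correlation.

    Returns (template, offsets relative to the given starts, n_used,
    n_iterations, per-iteration mean squared alignment error).  Windows that
    would leave the signal bounds are excluded (``used`` mask False).
    """
    n = len(starts)
    offsets = np.zeros(n, dtype=int)
    used = np.ones(n, dtype=bool)

    def window(i):
        s = starts[i] + offsets[i]
        if s < 0 or s + length > len(x):
            return None
        return x[s:s + length]

    def current_windows():
        wins, idx = [], []
        for i in range(n):
            w = window(i)
            if w is None:
                used[i] = False
            else:
                wins.append(w)
                idx.append(i)
        return wins, idx

    wins, idx = current_windows()
    if not wins:
        return None, offsets, used, 0, []
    template = np.mean(wins, axis=0)
    mse_track = [float(np.mean([(w - template) ** 2 for w in wins]))]
    if len(wins) == 1:
        return template, offsets, used, 0, mse_track

    iterations = 0
    for iterations in range(1, max_iter + 1):
        max_change = 0
        for i in list(idx):
            s = starts[i] + offsets[i]
            lo = max(0, s - max_shift)
            hi = min(len(x), s + length + max_shift)
            seg = x[lo:hi]
            if len(seg) < length:
                used[i] = False
                continue
            corr = np.correlate(seg, template, mode="valid")
            shift = (lo + int(np.argmax(corr))) - s
            if shift != 0:
                offsets[i] += shift
                max_change = max(max_change, abs(shift))
        wins, idx = current_windows()
        if not wins:
            break
        template = np.mean(wins, axis=0)
        mse_track.append(float(np.mean([(w - template) ** 2 for w in wins])))
        if max_change <= tol:
            break
    return template, offsets, used, iterations, mse_track


def build_average_patterns(x: np.ndarray, beats: pd.DataFrame,
                           sampling_rate: float, config: AnalysisConfig
                           ) -> tuple[PatternPair, pd.DataFrame]:
    """Average depolarization/repolarization patterns with refined offsets.

    Depolarization and repolarization windows are aligned independently,
    each in its own window anchored to the detected peak.  Beats whose
    window falls outside the trace are dropped from the average and flagged,
    not raised.
    """
    x = np.asarray(x, dtype=float)
    beats = beats.copy().reset_index(drop=True)
    if len(beats) == 0:
        raise InputError("cannot average patterns without beats")

    ld = int(round(config.depol_window * sampling_rate))
    lr = int(round(config.repol_window * sampling_rate))
    max_shift = max(1, int(round(config.max_align_shift * sampling_rate)))

    d_starts = _window_starts(beats, sampling_rate, config.depol_start_offset,
                              np.zeros(len(beats), dtype=int))
    r_starts = _window_starts(beats, sampling_rate, config.repol_start_offset,
                              np.zeros(len(beats), dtype=int))

    d_tmpl, d_off, d_used, d_iter, d_mse = _align_windows(
        x, d_starts, ld, max_shift, config.max_align_iterations,
        config.align_tolerance)
    r_tmpl, r_off, r_used, r_iter, r_mse = _align_windows(
        x, r_starts, lr, max_shift, config.max_align_iterations,
        config.align_tolerance)

    if d_tmpl is None:
        raise InputError("no beat has a complete depolarization window")

    beats["align_offset_depol"] = d_off
    beats["align_offset_repol"] = r_off
    dropped = ~(d_used & (r_used if r_tmpl is not None else True))
    prior = beats["flag"].fillna(FLAG_OK).to_numpy(dtype=object)
    beats["flag"] = np.where(dropped, FLAG_EDGE, prior)

    pair = PatternPair(
        depol=d_tmpl,
        repol=r_tmpl,
        n_beats_averaged=int(d_used.sum()),
        convergence_iterations=max(d_iter, r_iter),
        alignment_mse=d_mse,
    )
    return pair, beats


# ---------------------------------------------------------------------------
# phase 3: fiducials, parameters, reconstruction


def locate_fiducials(patterns: PatternPair, sampling_rate: float,
                     config: AnalysisConfig) -> FiducialSet:
    """Fiducial points on the averaged patterns.

    Depolarization peak = global extremum of the baseline-removed template;
    onset = last crossing of ``onset_fraction`` of the peak amplitude before
    the peak.  Repolarization fiducial = extremum of the largest-|amplitude|
    lobe in the repolarization window after local baseline (median) removal.
    """
    d = np.asarray(patterns.depol, dtype=float)
    if np.ptp(d) <= 0:
        raise DegeneratePatternError("flat depolarization template")
    a = d - np.median(d)
    pk = int(np.argmax(np.abs(a)))
    sign = np.sign(a[pk]) or 1.0
    peak_amp = abs(a[pk])
    thr = config.onset_fraction * peak_amp
    before = np.nonzero(sign * a[:pk] <= thr)[0]
    onset = int(before[-1]) if len(before) else 0

    peak_offset = config.depol_start_offset + pk / sampling_rate
    onset_offset = config.depol_start_offset + onset / sampling_rate

    repol_offset = None
    if patterns.repol is not None:
        r = np.asarray(patterns.repol, dtype=float)
        if np.ptp(r) > 0:
            ra = r - np.median(r)
            rk = int(np.argmax(np.abs(ra)))
            repol_offset = config.repol_start_offset + rk / sampling_rate

    return FiducialSet(
        depol_peak_offset=peak_offset,
        depol_onset_offset=onset_offset,
        repol_peak_offset=repol_offset,
        fpd_mode=config.fpd_mode,
    )


def fridericia_per_beat(fpd: np.ndarray, bp: np.ndarray) -> np.ndarray:
    """Per-beat Fridericia correction FPD / BP^(1/3); NaN where BP is undefined."""
    fpd = np.asarray(fpd, dtype=float)
    bp = np.asarray(bp, dtype=float)
    out = np.full_like(fpd, np.nan)
    ok = np.isfinite(fpd) & np.isfinite(bp) & (bp > 0)
    out[ok] = fpd[ok] / np.cbrt(bp[ok])
    return out


def _sd(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    return float(np.std(values, ddof=1)) if len(values) >= 2 else (0.0 if len(values) == 1 else np.nan)


def _mean(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    return float(np.mean(values)) if len(values) else np.nan


def compute_parameters(x: np.ndarray, beats: pd.DataFrame,
                       fiducials: FiducialSet, sampling_rate: float,
                       config: AnalysisConfig,
                       patterns: PatternPair | None = None,
                       residual: "ResidualReport | None" = None,
                       ) -> tuple[EPSummary, pd.DataFrame]:
    """Per-beat BP/FPD/AMP and their mean +/- SD summary.

    BP is the interval to the next depolarization; FPD maps the template
    fiducials onto each beat through its alignment offsets; AMP is the
    peak-to-peak excursion of the depolarization spike in the raw window.
    SNR = 10 log10(reconstruction power / residual power) when a
    reconstruction is available.
    """
    x = np.asarray(x, dtype=float)
    beats = beats.copy().reset_index(drop=True)
    fs = sampling_rate
    n = len(beats)
    duration = len(x) / fs

    if n:
        times = beats["peak_time_s"].to_numpy()
        bp = np.full(n, np.nan)
        if n >= 2:
            bp[:-1] = np.diff(times)
        beats["bp_s"] = bp

        fpd = np.full(n, np.nan)
        if fiducials.has_repol and fiducials.fpd_template is not None:
            d_off = beats["align_offset_depol"].to_numpy() / fs
            r_off = beats["align_offset_repol"].to_numpy() / fs
            start = (fiducials.depol_onset_offset
                     if config.fpd_mode == FPD_MODE_ONSET
                     else fiducials.depol_peak_offset)
            fpd = (fiducials.repol_peak_offset + r_off) - (start + d_off)
        beats["fpd_s"] = fpd
        beats["fpd_cf_s"] = fridericia_per_beat(fpd, bp)

        ld = int(round(config.depol_window * fs))
        d0 = int(round(config.depol_start_offset * fs))
        amp = np.full(n, np.nan)
        for i in range(n):
            s = int(beats.loc[i, "peak_index"]) + d0 + int(beats.loc[i, "align_offset_depol"])
            e = s + ld
            s, e = max(0, s), min(len(x), e)
            if e > s:
                amp[i] = float(np.ptp(x[s:e]))
        beats["amp_uV"] = amp

    if residual is None and patterns is not None and n:
        residual = reconstruct_and_residual(x, beats, patterns, fs, config)
    snr = np.nan
    if residual is not None:
        recon = x - residual.residual
        p_res = float(np.mean(residual.residual ** 2))
        p_rec = float(np.mean(recon ** 2))
        if p_res > 0 and p_rec > 0:
            snr = 10.0 * np.log10(p_rec / p_res)
        elif p_rec > 0:
            snr = np.inf

    cessation = detect_cessation(beats, duration, config)
    summary = EPSummary(
        bp_mean=_mean(beats["bp_s"].to_numpy()) if n else np.nan,
        bp_sd=_sd(beats["bp_s"].to_numpy()) if n else np.nan,
        fpd_mean=_mean(beats["fpd_s"].to_numpy()) if n else np.nan,
        fpd_sd=_sd(beats["fpd_s"].to_numpy()) if n else np.nan,
        fpd_cf_mean=_mean(beats["fpd_cf_s"].to_numpy()) if n else np.nan,
        fpd_cf_sd=_sd(beats["fpd_cf_s"].to_numpy()) if n else np.nan,
        amp_mean=_mean(beats["amp_uV"].to_numpy()) if n else np.nan,
        amp_sd=_sd(beats["amp_uV"].to_numpy()) if n else np.nan,
        n_beats=n,
        total_duration=duration,
        snr_db=snr,
        cessation=cessation,
        fpd_mode=config.fpd_mode,
    )
    return summary, beats


def _placements(beats: pd.DataFrame, sampling_rate: float,
                config: AnalysisConfig, ld: int, lr: int):
    """Actual (start, end) sample ranges of each beat's template placements."""
    fs = sampling_rate
    d0 = int(round(config.depol_start_offset * fs))
    r0 = int(round(config.repol_start_offset * fs))
    out = []
    for _, row in beats.iterrows():
        p = int(row["peak_index"])
        ds = p + d0 + int(row["align_offset_depol"])
        rs = p + r0 + int(row["align_offset_repol"])
        out.append((ds, ds + ld, rs, rs + lr))
    return out


def reconstruct_and_residual(x: np.ndarray, beats: pd.DataFrame,
                             patterns: PatternPair, sampling_rate: float,
                             config: AnalysisConfig) -> ResidualReport:
    """Template-superposition reconstruction and its residual.

    Within one beat the depolarization template is cropped where the
    repolarization placement begins (the two windows overlap by design, and
    both average the same stretch of signal there).  Placements of distinct
    beats that overlap are summed (linear superposition) and flagged.
    """
    x = np.asarray(x, dtype=float)
    recon = np.zeros_like(x)
    coverage = np.zeros(len(x), dtype=int)
    ld = len(patterns.depol)
    lr = len(patterns.repol) if patterns.repol is not None else 0

    overlap = False
    for ds, de, rs, re_ in _placements(beats, sampling_rate, config, ld, lr):
        d_end = min(de, rs) if patterns.repol is not None else de
        segs = [(ds, d_end, patterns.depol[: max(0, d_end - ds)])]
        if patterns.repol is not None:
            segs.append((rs, re_, patterns.repol))
        cov = np.zeros(len(x), dtype=int)
        for s, e, tmpl in segs:
            s_clip, e_clip = max(0, s), min(len(x), e)
            if e_clip <= s_clip:
                continue
            recon[s_clip:e_clip] += tmpl[s_clip - s: e_clip - s]
            cov[s_clip:e_clip] = 1
        if np.any(coverage + cov > 1):
            overlap = True
        coverage += cov

    residual = x - recon
    return ResidualReport(residual=residual, overlap_flagged=overlap)


def detect_arrhythmic_events(report: ResidualReport, beats: pd.DataFrame,
                             patterns: PatternPair | None,
                             sampling_rate: float,
                             config: AnalysisConfig) -> ResidualReport:
    """Flag irregular residual excursions outside the annotated beat windows.

    An irregular peak exceeds ``k`` robust standard deviations of the
    residual (1.4826 x median absolute deviation); events are separated from
    each other by at least the refractory period and never fall inside an
    annotated depolarization/repolarization window.
    """
    r = np.asarray(report.residual, dtype=float)
    if len(r) == 0:
        report.irregular_peaks = []
        report.arrhythmia_detected = False
        return report
    mad = float(np.median(np.abs(r - np.median(r))))
    scale = 1.4826 * mad
    if scale <= 0:
        report.irregular_peaks = []
        report.arrhythmia_detected = False
        return report
    threshold = config.arrhythmia_k * scale

    # events must keep a refractory-period separation from the annotated
    # windows: reconstruction edges sit right at the window borders and must
    # not masquerade as ectopic activity
    excluded = np.zeros(len(r), dtype=bool)
    guard = max(1, int(round(config.refractory * sampling_rate)))
    if len(beats):
        ld = int(round(config.depol_window * sampling_rate))
        lr = int(round(config.repol_window * sampling_rate))
        for ds, de, rs, re_ in _placements(beats, sampling_rate, config, ld, lr):
            excluded[max(0, ds - guard):min(len(r), de + guard)] = True
            excluded[max(0, rs - guard):min(len(r), re_ + guard)] = True

    mag = np.abs(r - np.median(r))
    candidates = np.nonzero((mag > threshold) & ~excluded)[0]
    min_sep = max(1, int(round(config.refractory * sampling_rate)))
    events: list[tuple[float, float]] = []
    # greedy by magnitude: the strongest excursion of each burst is reported
    for idx in candidates[np.argsort(mag[candidates])[::-1]]:
        t = idx / sampling_rate
        if all(abs(t - te) >= min_sep / sampling_rate for te, _ in events):
            events.append((t, float(r[idx])))
    events.sort()
    report.irregular_peaks = events
    report.arrhythmia_detected = len(events) >= 1
    return report


def detect_cessation(beats: pd.DataFrame, duration: float,
                     config: AnalysisConfig) -> bool:
    """True when the detected beat rate falls below the cessation floor."""
    if duration <= 0:
        return True
    rate_bpm = len(beats) / duration * 60.0
    return rate_bpm < config.cessation_floor_bpm
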
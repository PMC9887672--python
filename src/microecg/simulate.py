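"""Parametric simulator of field-potential recordings with ground truth.

The generator renders what the analysis assumes about a beating cardiac
microtissue: a quasi-periodic train of sharp biphasic depolarization spikes
(derivative-of-Gaussian-like wavelet, dominant lobe ~20 ms wide) each
followed, FPD later, by a slower unimodal repolarization wave (Gaussian
bump), on top of additive white noise at a requested SNR, optional baseline
wander, powerline interference, ectopic extra spikes and beating cessation.
Every realization is fully determined by its seed and ships with the
ground-truth annotations (beat times, per-beat FPD, amplitudes, ectopic
times) the tests measure recovery against.

This is a phenomenological signal generator, not an ionic-current model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .recording import FPRecording

SPIKE_SIGMA = 0.004  # s, width of each depolarization lobe
SPIKE_PRELOBE_FRACTION = 0.35
SPIKE_PRELOBE_LEAD = 0.008  # s, pre-lobe precedes the main lobe
SPIKE_HALF_SUPPORT = 0.04  # s
REPOL_SIGMA = 0.05  # s, repolarization bump width
REPOL_HALF_SUPPORT = 0.175  # s (3.5 sigma)
MIN_PERIOD = 0.3  # s, truncation floor for BP jitter


@dataclass
class HillEffect:
    """Concentration-dependent drug effect applied by the simulator.

    ``emax_pct`` scales the FPD (positive = prolongation) through a Hill
    curve with midpoint ``ec50`` and coefficient ``hill``; ``bp_emax_pct``
    optionally slows the beating the same way.  Arrhythmia/cessation set in
    above a dose threshold in a configurable fraction of tissues.
    """

    emax_pct: float = 0.0
    ec50: float = 1.0
    hill: float = 1.0
    bp_emax_pct: float = 0.0
    arrhythmia_above: float | None = None
    arrhythmia_tissue_fraction: float = 1.0
    arrhythmia_rate_per_min: float = 4.0
    cessation_above: float | None = None
    cessation_tissue_fraction: float = 0.0

    def fraction(self, dose: float) -> float:
        if dose <= 0:
            return 0.0
        d = dose ** self.hill
        return d / (d + self.ec50 ** self.hill)

    def fpd_factor(self, dose: float) -> float:
        return 1.0 + self.emax_pct / 100.0 * self.fraction(dose)

    def bp_factor(self, dose: float) -> float:
        return 1.0 + self.bp_emax_pct / 100.0 * self.fraction(dose)

    def true_pct_dfpdcf(self, dose: float) -> float:
        """Analytic %change of FPDcF = FPD/BP^(1/3) at a dose."""
        return 100.0 * (self.fpd_factor(dose) / self.bp_factor(dose) ** (1 / 3) - 1.0)

    def crossing_dose(self, threshold_pct: float) -> float | None:
        """Analytic dose where |%dFPDcF| first reaches a threshold (Hill algebra)."""
        target = abs(threshold_pct)
        lo, hi = 0.0, self.ec50
        if abs(self.true_pct_dfpdcf(hi)) < target:
            for _ in range(200):
                hi *= 2.0
                if abs(self.true_pct_dfpdcf(hi)) >= target:
                    break
            else:
                return None
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if abs(self.true_pct_dfpdcf(mid)) >= target:
                hi = mid
            else:
                lo = mid
        return hi


@dataclass
class SimConfig:
    """Study conditions for one simulated recording.

    Defaults mirror a typical included baseline microtissue: BP 1.9 s with
    5 % beat-to-beat CV, FPD 0.69 s, spike amplitude 250 uV, SNR 25 dB at
    2000 samples/s for 60 s.
    """

    sampling_rate: float = 2000.0
    duration: float = 60.0
    bp_mean: float = 1.9
    bp_cv_pct: float = 5.0
    fpd_mean: float = 0.69
    fpd_cv_pct: float = 2.0
    amp_uV: float = 250.0
    repol_amp_fraction: float = 0.30
    noise_snr_db: float | None = 25.0
    wander_amp_uV: float = 0.0
    wander_freq_hz: float = 0.2
    powerline_amp_uV: float = 0.0
    powerline_freq_hz: float = 50.0
    ectopic_rate_per_min: float = 0.0
    ectopic_amp_fraction: float = 0.6
    cessation_after: float | None = None
    seed: int = 0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "duration", "bp_mean", "fpd_mean", "amp_uV"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.bp_cv_pct < 0 or self.fpd_cv_pct < 0:
            raise ConfigurationError("CV percentages must be >= 0")
        if self.fpd_mean + REPOL_HALF_SUPPORT >= self.bp_mean:
            raise ConfigurationError(
                f"infeasible geometry: FPD {self.fpd_mean} s plus the "
                f"repolarization wave does not fit into BP {self.bp_mean} s"
            )

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Construction-time annotations of a simulated recording."""

    beat_times: np.ndarray  # s, depolarization spike extrema
    fpd: np.ndarray  # s, per beat: spike extremum -> repol bump center
    amp: np.ndarray  # uV, per beat, peak-to-peak of the spike
    onset_offset: float  # s (<0): 10%-crossing onset relative to the spike extremum
    ectopic_times: np.ndarray
    cessation_time: float | None = None
    true_pct_dfpdcf: dict | None = None  # per-dose analytic %change (experiments)

    @property
    def fpd_from_onset(self) -> np.ndarray:
        """Per-beat FPD measured from the depolarization onset fiducial."""
        return self.fpd - self.onset_offset

    @property
    def bp(self) -> np.ndarray:
        return np.diff(self.beat_times)


def _spike_waveform(fs: float) -> tuple[np.ndarray, int, float]:
    """Unit-ptp biphasic spike; returns (waveform, extremum index, onset offset s).

    The dominant negative lobe sits exactly at the annotated beat time; a
    smaller positive pre-lobe precedes it, as in a typical extracellular
    depolarization.  The onset offset is the 10 %-of-peak crossing measured
    on the clean waveform, so ground truth and analysis share the fiducial
    definition by construction.
    """
    n = int(round(SPIKE_HALF_SUPPORT * fs))
    t = np.arange(-n, n + 1) / fs
    w = (SPIKE_PRELOBE_FRACTION * np.exp(-0.5 * ((t + SPIKE_PRELOBE_LEAD) / SPIKE_SIGMA) ** 2)
         - np.exp(-0.5 * (t / SPIKE_SIGMA) ** 2))
    w = w / np.ptp(w)
    center = int(np.argmax(np.abs(w)))
    peak = w[center]
    thr = 0.10 * abs(peak)
    sign = np.sign(peak)
    before = np.nonzero(sign * w[:center] <= thr)[0]
    onset_idx = int(before[-1]) if len(before) else 0
    onset_offset = (onset_idx - center) / fs
    return w, center, onset_offset


def _repol_waveform(fs: float) -> tuple[np.ndarray, int]:
    n = int(round(REPOL_HALF_SUPPORT * fs))
    t = np.arange(-n, n + 1) / fs
    w = np.exp(-0.5 * (t / REPOL_SIGMA) ** 2)
    return w, n


def _add(signal: np.ndarray, waveform: np.ndarray, center_idx: int,
         anchor: int, scale: float) -> None:
    s = center_idx - anchor
    e = s + len(waveform)
    s_clip, e_clip = max(0, s), min(len(signal), e)
    if e_clip > s_clip:
        signal[s_clip:e_clip] += scale * waveform[s_clip - s: e_clip - s]


def simulate_recording(cfg: SimConfig) -> tuple[FPRecording, GroundTruth]:
    """Render one single-channel recording and its ground truth.

    The same seed always yields a bit-identical signal; overriding only
    ``noise_seed`` re-rolls the additive noise while leaving beat times,
    FPDs and ectopic times untouched.
    """
    fs = cfg.sampling_rate
    n_samples = int(round(cfg.duration * fs))
    ss = np.random.SeedSequence(cfg.seed)
    timing_rng, ectopic_rng, noise_child = [np.random.default_rng(s)
                                            for s in ss.spawn(3)]
    noise_rng = (np.random.default_rng(cfg.noise_seed)
                 if cfg.noise_seed is not None else noise_child)

    # beat schedule: Gaussian BP jitter truncated at the refractory floor
    bp_sd = cfg.bp_mean * cfg.bp_cv_pct / 100.0
    fpd_sd = cfg.fpd_mean * cfg.fpd_cv_pct / 100.0
    tail = cfg.fpd_mean + REPOL_HALF_SUPPORT + 0.05
    t = 0.4
    beat_times, fpds = [], []
    while t < cfg.duration - tail:
        if cfg.cessation_after is None or t <= cfg.cessation_after:
            beat_times.append(t)
            fpds.append(max(0.05, timing_rng.normal(cfg.fpd_mean, fpd_sd)))
        period = timing_rng.normal(cfg.bp_mean, bp_sd)
        t += max(MIN_PERIOD, period)
    beat_times = np.asarray(beat_times)
    fpds = np.asarray(fpds)

    spike, spike_anchor, onset_offset = _spike_waveform(fs)
    repol, repol_anchor = _repol_waveform(fs)

    clean = np.zeros(n_samples)
    for bt, fpd in zip(beat_times, fpds):
        bi = int(round(bt * fs))
        _add(clean, spike, bi, spike_anchor, cfg.amp_uV)
        _add(clean, repol, int(round((bt + fpd) * fs)), repol_anchor,
             cfg.amp_uV * cfg.repol_amp_fraction)

    # ectopic extra spikes, kept clear of normal beats (and their analysis
    # windows) and of each other
    n_ect = int(round(cfg.ectopic_rate_per_min * cfg.duration / 60.0))
    ectopic_times: list[float] = []
    guard_pre, guard_post, attempts = 0.45, 0.30, 0
    while len(ectopic_times) < n_ect and attempts < 5000:
        attempts += 1
        cand = float(ectopic_rng.uniform(0.5, cfg.duration - 0.5))
        clear = all(not (bt - guard_pre < cand < bt + fpd + REPOL_HALF_SUPPORT + guard_post)
                    for bt, fpd in zip(beat_times, fpds))
        if clear and all(abs(cand - e) > 0.4 for e in ectopic_times):
            ectopic_times.append(cand)
    ectopic_times = np.asarray(sorted(ectopic_times))
    for et in ectopic_times:
        _add(clean, spike, int(round(et * fs)), spike_anchor,
             cfg.amp_uV * cfg.ectopic_amp_fraction)

    x = clean.copy()
    if cfg.wander_amp_uV > 0:
        x += cfg.wander_amp_uV * np.sin(
            2 * np.pi * cfg.wander_freq_hz * np.arange(n_samples) / fs)
    if cfg.powerline_amp_uV > 0:
        x += cfg.powerline_amp_uV * np.sin(
            2 * np.pi * cfg.powerline_freq_hz * np.arange(n_samples) / fs)
    if cfg.noise_snr_db is not None:
        p_signal = float(np.mean(clean ** 2))
        if p_signal > 0:
            sigma = math.sqrt(p_signal / 10.0 ** (cfg.noise_snr_db / 10.0))
            x += noise_rng.normal(0.0, sigma, n_samples)

    rec = FPRecording(
        x, sampling_rate=fs, channel_ids=["sim"],
        metadata={"simulated": True, "seed": cfg.seed})
    gt = GroundTruth(
        beat_times=beat_times, fpd=fpds,
        amp=np.full(len(beat_times), cfg.amp_uV),
        onset_offset=onset_offset, ectopic_times=ectopic_times,
        cessation_time=cfg.cessation_after)
    return rec, gt


# ---------------------------------------------------------------------------
# full drug experiments


@dataclass
class SimulatedExperiment:
    """A simulated multi-tissue dose-escalation campaign."""

    compound: str
    doses: list[float]
    recordings: dict  # (tissue_id, condition) -> FPRecording; condition "baseline" or dose
    ground_truths: dict  # same keys -> GroundTruth
    effect: HillEffect
    true_pct_dfpdcf: dict  # dose -> analytic %change
    tissue_ids: list[str] = field(default_factory=list)


def simulate_drug_experiment(base_cfg: SimConfig, doses, n_tissues: int,
                             effect: HillEffect, seed: int,
                             compound: str = "simdrug") -> SimulatedExperiment:
    """Baseline + incremental doses for ``n_tissues`` replicate tissues.

    Each tissue gets its own timing/noise seeds; the drug scales FPD (and
    optionally BP) through the Hill curve, switches on ectopic activity
    above ``arrhythmia_above`` in the configured fraction of tissues, and
    stops the beating above ``cessation_above`` likewise.
    """
    doses = sorted(float(d) for d in doses)
    if any(b - a <= 0 for a, b in zip(doses, doses[1:])) or not doses:
        raise ConfigurationError("dose ladder must be non-empty and strictly increasing")
    rng = np.random.default_rng(seed)
    tissue_ids = [f"T{i + 1}" for i in range(n_tissues)]
    arr_set = set(tissue_ids[: int(round(effect.arrhythmia_tissue_fraction * n_tissues))]
                  if effect.arrhythmia_above is not None else [])
    stop_set = set(tissue_ids[: int(round(effect.cessation_tissue_fraction * n_tissues))]
                   if effect.cessation_above is not None else [])

    recordings, truths = {}, {}
    for tid in tissue_ids:
        tissue_seed = int(rng.integers(0, 2 ** 31 - 1))
        base = base_cfg.replace(seed=tissue_seed)
        recordings[(tid, "baseline")], truths[(tid, "baseline")] = simulate_recording(base)
        for k, dose in enumerate(doses):
            cfg = base.replace(
                seed=tissue_seed + 1 + k,
                fpd_mean=base_cfg.fpd_mean * effect.fpd_factor(dose),
                bp_mean=base_cfg.bp_mean * effect.bp_factor(dose),
            )
            if (tid in arr_set and effect.arrhythmia_above is not None
                    and dose >= effect.arrhythmia_above):
                cfg = cfg.replace(ectopic_rate_per_min=effect.arrhythmia_rate_per_min)
            if (tid in stop_set and effect.cessation_above is not None
                    and dose >= effect.cessation_above):
                cfg = cfg.replace(cessation_after=0.0)
            recordings[(tid, dose)], truths[(tid, dose)] = simulate_recording(cfg)

    return SimulatedExperiment(
        compound=compound, doses=doses, recordings=recordings,
        ground_truths=truths, effect=effect,
        true_pct_dfpdcf={d: effect.true_pct_dfpdcf(d) for d in doses},
        tissue_ids=tissue_ids)


def write_experiment(exp: SimulatedExperiment, outdir, base_cfg: SimConfig,
                     c_max: float | None = None,
                     f_etpc: float | None = None) -> str:
    """Write recordings + a YAML manifest consumable by the screening CLI."""
    import os

    import yaml

    from . import io as _io

    os.makedirs(outdir, exist_ok=True)
    tissues = []
    for tid in exp.tissue_ids:
        entry = {"id": tid}
        base_path = os.path.join(outdir, f"{exp.compound}_{tid}_baseline.csv")
        _io.write_recording_csv(exp.recordings[(tid, "baseline")], base_path)
        entry["baseline"] = os.path.basename(base_path)
        entry["doses"] = {}
        for dose in exp.doses:
            p = os.path.join(outdir, f"{exp.compound}_{tid}_d{dose:g}.csv")
            _io.write_recording_csv(exp.recordings[(tid, dose)], p)
            entry["doses"][float(dose)] = os.path.basename(p)
        tissues.append(entry)
    manifest = {
        "dose_unit": "uM",
        "compounds": [{
            "name": exp.compound,
            "vehicle": False,
            "c_max_uM": c_max,
            "f_etpc_uM": f_etpc,
            "tissues": tissues,
        }],
    }
    path = os.path.join(outdir, "manifest.yaml")
    with open(path, "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)
    return path
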
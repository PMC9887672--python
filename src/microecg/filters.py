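"""Zero-phase preprocessing filters.

Both filters run forward-backward (``sosfiltfilt``) with reflect padding so
the fiducial timing of the field potential is not shifted: depolarization
spikes stay where they are and only the targeted bands are removed.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .errors import ConfigurationError, InputError
from .recording import FPRecording


def _zero_phase(sos: np.ndarray, x: np.ndarray,
                sampling_rate: float) -> np.ndarray:
    # odd (anti-symmetric) signal extension, which continues oscillatory
    # content smoothly across the boundary; narrow-band sections (high-Q
    # notches, sub-Hz band edges) ring for a sizeable fraction of a second,
    # so the pad is sized in time, not taps
    padlen = int(round(2.0 * sampling_rate))
    if x.shape[-1] <= padlen:
        padlen = x.shape[-1] - 1
    ntaps = 2 * sos.shape[0] * 3
    if x.shape[-1] <= ntaps:
        raise InputError(
            f"recording of {x.shape[-1]} samples is shorter than the filter "
            f"warm-up ({ntaps} samples)"
        )
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def notch_sos(sampling_rate: float, config: AnalysisConfig) -> np.ndarray:
    """Cascaded second-order IIR notches at the base frequency and harmonics."""
    nyq = sampling_rate / 2.0
    freqs = config.notch_frequencies(sampling_rate)
    if not freqs:
        raise ConfigurationError("no notch frequency below Nyquist")
    sections = []
    for f in freqs:
        if f >= nyq:
            raise ConfigurationError(
                f"notch harmonic {f} Hz is not below Nyquist {nyq} Hz"
            )
        b, a = signal.iirnotch(f, Q=config.notch_q, fs=sampling_rate)
        sections.append(signal.tf2sos(b, a))
    return np.vstack(sections)


def notch_filter(recording: FPRecording, config: AnalysisConfig) -> FPRecording:
    """Remove powerline interference (base frequency and harmonics), zero phase."""
    sos = notch_sos(recording.sampling_rate, config)
    return recording.with_samples(
        _zero_phase(sos, recording.samples, recording.sampling_rate))


def bandpass_sos(sampling_rate: float, config: AnalysisConfig) -> np.ndarray:
    lo, hi = config.prefilter_band
    nyq = sampling_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ConfigurationError(
            f"band {config.prefilter_band} inconsistent with sampling rate "
            f"{sampling_rate} Hz"
        )
    return signal.butter(config.prefilter_order, [lo, hi], btype="bandpass",
                         fs=sampling_rate, output="sos")


def bandpass_prefilter(recording: FPRecording, config: AnalysisConfig) -> FPRecording:
    """Butterworth band-pass (default 0.67-100 Hz, order 3), zero phase."""
    sos = bandpass_sos(recording.sampling_rate, config)
    return recording.with_samples(
        _zero_phase(sos, recording.samples, recording.sampling_rate))


def preprocess(recording: FPRecording, config: AnalysisConfig) -> FPRecording:
    """Apply the enabled zero-phase filters in the documented order."""
    config.validate_against_rate(recording.sampling_rate)
    out = recording
    if config.prefilter_enabled:
        out = bandpass_prefilter(out, config)
    if config.notch_enabled:
        out = notch_filter(out, config)
    return out
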
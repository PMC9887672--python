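"""Analysis configuration and the dose-response threshold grid.

All times are in seconds, voltages in microvolts and frequencies in hertz;
sample indices are 0-based.  Defaults correspond to the operator settings a
typical spontaneously beating cardiac microtissue needs: a depolarization
search window of 0.5 s starting 75 ms before each detected spike and a
repolarization window of 0.7 s starting 100 ms after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

FPD_MODE_ONSET = "onset-to-peak"
FPD_MODE_PEAK = "peak-to-peak"


@dataclass
class AnalysisConfig:
    """Tunable parameters of the semi-automatic field-potential analysis.

    Parameters
    ----------
    voltage_threshold_fraction : float
        Fraction of the highest integrated-energy value a candidate spike
        must reach to be accepted (default 0.70).
    depol_window, repol_window : float
        Lengths (s) of the depolarization and repolarization analysis
        windows.
    depol_start_offset, repol_start_offset : float
        Start of each window relative to the detected depolarization peak
        (s); the depolarization window conventionally starts 75 ms *before*
        the peak.
    notch_enabled : bool
        Apply a zero-phase powerline notch (base frequency and all requested
        harmonics) before template averaging.
    prefilter_enabled : bool
        Apply the zero-phase Butterworth band-pass (0.67-100 Hz, order 3)
        before beat detection.
    refractory : float
        Minimum spacing between accepted depolarizations (s).
    fpd_mode : str
        ``"onset-to-peak"`` measures the field-potential duration from the
        depolarization onset (10 %-of-peak crossing) to the repolarization
        extremum; ``"peak-to-peak"`` measures it from the depolarization
        extremum instead.
    arrhythmia_k : float
        Residual excursions beyond ``k`` robust standard deviations (MAD
        scaled by 1.4826) outside the annotated beat windows are reported as
        irregular events.
    cessation_floor_bpm : float
        Detected rates below this floor flag a cessation of spontaneous
        beating (default 6 beats/min).
    """

    voltage_threshold_fraction: float = 0.70
    depol_window: float = 0.5
    repol_window: float = 0.7
    depol_start_offset: float = -0.075
    repol_start_offset: float = 0.1

    notch_enabled: bool = False
    notch_base_freq: float = 50.0
    notch_harmonics: tuple[int, ...] | None = None  # None -> all below Nyquist
    notch_q: float = 30.0

    prefilter_enabled: bool = False
    prefilter_band: tuple[float, float] = (0.67, 100.0)
    prefilter_order: int = 3

    refractory: float = 0.25
    integration_window: float = 0.08
    onset_fraction: float = 0.10
    fpd_mode: str = FPD_MODE_ONSET

    max_align_iterations: int = 10
    align_tolerance: int = 1  # samples
    max_align_shift: float = 0.05  # s, half-width of the correlation search

    arrhythmia_k: float = 5.0
    cessation_floor_bpm: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.voltage_threshold_fraction <= 1.0:
            raise ConfigurationError(
                "voltage_threshold_fraction must be in (0, 1], got "
                f"{self.voltage_threshold_fraction}"
            )
        for name in ("depol_window", "repol_window", "refractory",
                     "integration_window", "max_align_shift"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        lo, hi = self.prefilter_band
        if not 0 < lo < hi:
            raise ConfigurationError(
                f"prefilter band must satisfy 0 < low < high, got {self.prefilter_band}"
            )
        if self.notch_q <= 0 or self.notch_base_freq <= 0:
            raise ConfigurationError("notch frequency and Q must be > 0")
        if self.fpd_mode not in (FPD_MODE_ONSET, FPD_MODE_PEAK):
            raise ConfigurationError(f"unknown fpd_mode {self.fpd_mode!r}")
        if self.max_align_iterations < 1 or self.align_tolerance < 0:
            raise ConfigurationError("alignment iteration parameters invalid")
        if self.arrhythmia_k <= 0 or self.cessation_floor_bpm <= 0:
            raise ConfigurationError("arrhythmia_k and cessation_floor_bpm must be > 0")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    @classmethod
    def for_geometry(cls, bp_mean: float, fpd_mean: float,
                     **overrides) -> "AnalysisConfig":
        """Window settings adapted to an expected beat geometry.

        Mirrors what an operator does from visual inspection: the
        repolarization window must contain the repolarization wave (expected
        around ``fpd_mean`` after the spike) yet stay clear of the next
        beat, and the alignment search range shrinks with the free gap so
        cross-correlation cannot lock onto a neighbouring depolarization.
        """
        repol_end = min(fpd_mean + 0.2, bp_mean - 0.15)
        repol_win = max(0.25, repol_end - 0.1)
        depol_win = min(0.5, max(0.2, bp_mean * 0.4))
        shift = float(min(0.05, max(0.01, (bp_mean - fpd_mean - 0.2) / 2)))
        params = dict(depol_window=depol_win, repol_window=repol_win,
                      max_align_shift=shift)
        params.update(overrides)
        return cls(**params)

    def validate_against_rate(self, sampling_rate: float) -> None:
        """Checks that depend on the recording's sampling rate."""
        nyq = sampling_rate / 2.0
        lo, hi = self.prefilter_band
        if self.prefilter_enabled and hi >= nyq:
            raise ConfigurationError(
                f"prefilter upper edge {hi} Hz is not below Nyquist {nyq} Hz"
            )
        if self.notch_enabled:
            for f in self.notch_frequencies(sampling_rate):
                if f >= nyq:
                    raise ConfigurationError(
                        f"notch harmonic {f} Hz is not below Nyquist {nyq} Hz"
                    )

    def notch_frequencies(self, sampling_rate: float) -> list[float]:
        """Notch base frequency plus harmonics, in Hz.

        With ``notch_harmonics=None`` every multiple of the base frequency
        below Nyquist is removed; an explicit tuple of harmonic numbers
        (1 = fundamental) is honoured verbatim and validated later.
        """
        if self.notch_harmonics is not None:
            return [k * self.notch_base_freq for k in self.notch_harmonics]
        nyq = sampling_rate / 2.0
        freqs = []
        k = 1
        while k * self.notch_base_freq < nyq * 0.999:
            freqs.append(k * self.notch_base_freq)
            k += 1
        return freqs


@dataclass(frozen=True)
class ThresholdSet:
    """Percent-change thresholds on the Fridericia-corrected FPD.

    LOW/MID/HIGH are the working cut-offs (10/15/20 %); INF and SUP are the
    extreme limits used only to close the ROC sweep (5 and 50 %).
    """

    INF: float = 5.0
    LOW: float = 10.0
    MID: float = 15.0
    HIGH: float = 20.0
    SUP: float = 50.0

    def __post_init__(self) -> None:
        if not self.INF < self.LOW < self.MID < self.HIGH < self.SUP:
            raise ConfigurationError(
                "thresholds must satisfy INF < LOW < MID < HIGH < SUP"
            )

    def as_dict(self) -> dict[str, float]:
        return {"INF": self.INF, "LOW": self.LOW, "MID": self.MID,
                "HIGH": self.HIGH, "SUP": self.SUP}

    def working(self) -> dict[str, float]:
        """The three thresholds used for compound calls."""
        return {"LOW": self.LOW, "MID": self.MID, "HIGH": self.HIGH}
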
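"""The in-memory container for multichannel field-potential recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class FPRecording:
    """A sampled extracellular field-potential recording.

    Voltages are stored in microvolts as a ``(n_channels, n_samples)`` array.
    A microtissue measurement typically carries two simultaneous channels,
    one per electrode, of which the cleaner one is analyzed.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise InputError("samples must be 1-D or (n_channels, n_samples)")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InputError("recording must contain at least one channel and one sample")
        if self.sampling_rate <= 0:
            raise InputError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.samples = arr
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i + 1}" for i in range(arr.shape[0])]
        if len(self.channel_ids) != arr.shape[0]:
            raise InputError(
                f"{len(self.channel_ids)} channel ids for {arr.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        try:
            idx = self.channel_ids.index(channel_id)
        except ValueError:
            raise InputError(
                f"unknown channel {channel_id!r}; have {self.channel_ids}"
            ) from None
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray) -> "FPRecording":
        """A copy of this recording carrying new sample values."""
        return FPRecording(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            channel_ids=list(self.channel_ids),
            metadata=dict(self.metadata),
        )
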
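"""Core containers: a multichannel EEG block and a frequency-band definition."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """A channels x samples block of EEG in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values in microvolts.
    sample_rate : float
        Sampling frequency in Hz.
    channel_labels : sequence of str
        Ordered channel names, 10-20 convention where applicable.
    state_tag : str
        Free-form condition label (e.g. ``rest_before``, ``task``).
    """

    data: np.ndarray
    sample_rate: float
    channel_labels: tuple[str, ...]
    state_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def with_data(self, data: np.ndarray, state_tag: str | None = None) -> "Recording":
        """Copy of this recording with new sample values (same rate/labels)."""
        return replace(
            self,
            data=data,
            state_tag=self.state_tag if state_tag is None else state_tag,
        )


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, e.g. mu = [8, 13) Hz, beta = [13, 30] Hz.

    The shared 13 Hz boundary is attributed to beta; band-pass filter
    transition bands make the distinction soft in practice.
    """

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band edges [{self.low_hz}, {self.high_hz}]")

    def validate_against_rate(self, sample_rate: float) -> None:
        if self.high_hz >= sample_rate / 2:
            raise ValueError(
                f"band edge {self.high_hz} Hz at or above Nyquist "
                f"({sample_rate / 2} Hz)"
            )


MU = BandDefinition("mu", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
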
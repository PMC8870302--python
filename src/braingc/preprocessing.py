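"""Signal conditioning: band-pass filtering, common-average re-reference,
amplitude artifact rejection, and random fixed-length segmentation.

The pipeline order is fixed: broadband filter -> re-reference -> artifact
mask -> band split -> segmentation. All steps are deterministic given the
input and the segmentation seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .recording import BandDefinition, Recording

__all__ = [
    "SegmentSet",
    "bandpass",
    "rereference_common_average",
    "mark_artifacts",
    "clean_windows",
    "segment_random",
    "slice_windows",
]

DEFAULT_ARTIFACT_UV = 50.0
DEFAULT_GUARD_S = 0.2


@dataclass
class SegmentSet:
    """Equal-length artifact-free slices of one recording in one band."""

    segments: list[Recording]
    band: BandDefinition | None
    source_state: str
    seed: int
    window_starts: tuple[int, ...]

    def __post_init__(self) -> None:
        lengths = {s.n_samples for s in self.segments}
        if len(lengths) > 1:
            raise ValueError("segments must all have equal length")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return self.segments[0].channel_labels


def bandpass(
    rec: Recording, low_hz: float, high_hz: float, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward, order per pass).

    Zero-phase filtering avoids the group delay that would corrupt lagged
    autoregressive fits downstream.
    """
    nyq = rec.sample_rate / 2
    if not (0 < low_hz < high_hz):
        raise ValueError(f"invalid band [{low_hz}, {high_hz}] Hz")
    if high_hz >= nyq:
        raise ValueError(f"band edge {high_hz} Hz at or above Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(filtered)


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels (common average)."""
    if rec.n_channels < 2:
        raise ValueError("common-average re-reference requires >= 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def mark_artifacts(
    rec: Recording,
    amplitude_uv: float = DEFAULT_ARTIFACT_UV,
    guard_s: float = DEFAULT_GUARD_S,
) -> np.ndarray:
    """Boolean per-sample mask: True where any channel exceeds the amplitude
    threshold, dilated by +/- ``guard_s`` to exclude filter ringing."""
    if amplitude_uv <= 0:
        raise ValueError("amplitude threshold must be positive")
    hit = np.any(np.abs(rec.data) > amplitude_uv, axis=0)
    guard = int(round(guard_s * rec.sample_rate))
    if guard > 0 and hit.any():
        hit = ndimage.binary_dilation(hit, structure=np.ones(2 * guard + 1, dtype=bool))
    return hit


def clean_windows(mask: np.ndarray, window_len: int) -> np.ndarray:
    """Start indices at which a window of ``window_len`` samples is artifact-free."""
    n = mask.size
    if window_len > n:
        return np.empty(0, dtype=int)
    csum = np.concatenate([[0], np.cumsum(mask.astype(int))])
    counts = csum[window_len:] - csum[:-window_len]
    return np.nonzero(counts == 0)[0]


def segment_random(
    rec: Recording,
    mask: np.ndarray,
    n_segments: int,
    duration_s: float,
    seed: int,
) -> SegmentSet:
    """Randomly place ``n_segments`` non-overlapping artifact-free windows.

    Placement is uniform over admissible window sets within each clean run
    and deterministic given the seed. Raises when the clean spans cannot hold
    the requested windows, reporting the available clean duration.
    """
    window = int(round(duration_s * rec.sample_rate))
    if window < 1 or n_segments < 1:
        raise ValueError("need positive segment count and duration")
    mask = np.asarray(mask, dtype=bool)
    if mask.size != rec.n_samples:
        raise ValueError("mask length must match recording length")

    # Maximal clean runs and their window capacity.
    runs: list[tuple[int, int]] = []  # (start, length)
    in_run = False
    start = 0
    for i, bad in enumerate(np.concatenate([mask, [True]])):
        if not bad and not in_run:
            in_run, start = True, i
        elif bad and in_run:
            in_run = False
            runs.append((start, i - start))
    capacities = [length // window for _, length in runs]
    clean_s = sum(length for _, length in runs) / rec.sample_rate
    if sum(capacities) < n_segments:
        raise ValueError(
            f"cannot place {n_segments} x {duration_s:g} s windows: only "
            f"{clean_s:g} s of artifact-free data "
            f"(capacity {sum(capacities)} windows)"
        )

    rng = np.random.default_rng(seed)
    # Allocate windows to runs proportionally to remaining capacity.
    alloc = [0] * len(runs)
    remaining = list(capacities)
    for _ in range(n_segments):
        weights = np.array(remaining, dtype=float)
        k = int(rng.choice(len(runs), p=weights / weights.sum()))
        alloc[k] += 1
        remaining[k] -= 1

    starts: list[int] = []
    for (run_start, run_len), k in zip(runs, alloc):
        if k == 0:
            continue
        slack = run_len - k * window
        gaps = np.sort(rng.integers(0, slack + 1, size=k))
        for j in range(k):
            starts.append(run_start + gaps[j] + j * window)
    starts.sort()

    return slice_windows(rec, tuple(starts), window, band=None, seed=seed)


def slice_windows(
    rec: Recording,
    starts: tuple[int, ...],
    window_len: int,
    band: BandDefinition | None = None,
    seed: int = 0,
) -> SegmentSet:
    """Cut a SegmentSet at the given start samples (shared across bands so
    mu/beta comparisons rest on identical data support)."""
    segments = [
        rec.with_data(rec.data[:, s : s + window_len]) for s in starts
    ]
    return SegmentSet(
        segments=segments,
        band=band,
        source_state=rec.state_tag,
        seed=seed,
        window_starts=tuple(int(s) for s in starts),
    )
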
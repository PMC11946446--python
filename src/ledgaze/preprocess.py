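"""Trimming, segmentation, Butterworth band-pass filtering and z-scoring.

The raw 16 s recording is trimmed of its 3 s beep pads, leaving the 10 s
task block (2560 x 14 at 256 Hz), which is cut into five 3 s analysis
windows (768 samples) with equally spaced starts.  Filtering happens per
segment: a causal fifth-order Butterworth 1-15 Hz path feeds the LED gate,
and a zero-phase (forward-backward) 1-45 Hz path feeds the trajectory
classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .simulate import Recording, RecordingMeta

__all__ = [
    "Segment",
    "FilterSpec",
    "STAGE1_FILTER",
    "STAGE2_FILTER",
    "trim_beeps",
    "segment_recording",
    "bandpass",
    "zscore",
]

#: Analysis window length in seconds.
WINDOW_S = 3.0

#: Number of windows cut from a 10 s task block.
WINDOWS_PER_BLOCK = 5


@dataclass
class Segment:
    """One 3 s analysis window with provenance back to its recording."""

    samples: np.ndarray  # (768, C) microvolts
    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    meta: RecordingMeta
    window_index: int
    start_sample: int

    def channel(self, name: str) -> np.ndarray:
        from .channels import channel_index

        return self.samples[:, channel_index(name, self.channel_names)]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification."""

    low_hz: float
    high_hz: float
    order: int = 5
    mode: str = "causal"  # or "zero_phase"

    def __post_init__(self) -> None:
        if not 0.0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.mode not in ("causal", "zero_phase"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    def sos(self, fs: float):
        if self.high_hz >= fs / 2.0:
            raise ValueError(
                f"high edge {self.high_hz} Hz is not below Nyquist ({fs / 2.0} Hz)"
            )
        return _signal.butter(
            self.order, (self.low_hz, self.high_hz), btype="bandpass", fs=fs, output="sos"
        )


#: Gate path: single-pass 1-15 Hz.
STAGE1_FILTER = FilterSpec(1.0, 15.0, 5, "causal")
#: Trajectory path: forward-backward 1-45 Hz.
STAGE2_FILTER = FilterSpec(1.0, 45.0, 5, "zero_phase")


def trim_beeps(recording: Recording, pad_s: float = 3.0) -> Recording:
    """Drop ``pad_s`` seconds from both ends, keeping the central task block."""
    pad = int(round(pad_s * recording.sampling_rate_hz))
    if recording.n_samples < 2 * pad + 1:
        raise ValueError(
            f"recording of {recording.n_samples} samples too short to trim "
            f"{pad} samples from each end"
        )
    if pad == 0:
        return recording
    return Recording(
        recording.samples[pad:-pad],
        recording.sampling_rate_hz,
        recording.channel_names,
        recording.meta,
    )


def segment_recording(recording: Recording, window_s: float = WINDOW_S,
                      n_windows: int = WINDOWS_PER_BLOCK) -> list[Segment]:
    """Cut a trimmed task block into ``n_windows`` equally spaced windows.

    For the canonical 10 s block at 256 Hz this yields five 768-sample
    windows starting at samples {0, 448, 896, 1344, 1792}.  Shorter blocks
    yield proportionally fewer windows; a block shorter than one window
    yields an empty list with a warning.
    """
    fs = recording.sampling_rate_hz
    wlen = int(round(window_s * fs))
    n = recording.n_samples
    if n < wlen:
        warnings.warn(
            f"task block of {n} samples shorter than one {wlen}-sample window",
            stacklevel=2,
        )
        return []
    span = n - wlen
    if span == 0:
        n_windows = 1
    else:
        # keep the canonical hop (span / (n_windows - 1) for a full block),
        # trimming the window count proportionally for short blocks
        full_span = int(round((10.0 - window_s) * fs))
        hop = full_span / (WINDOWS_PER_BLOCK - 1)
        n_windows = min(n_windows, int(span / hop) + 1)
    starts = np.linspace(0, span, n_windows).round().astype(int) if n_windows > 1 else [0]
    return [
        Segment(
            samples=recording.samples[s : s + wlen],
            sampling_rate_hz=fs,
            channel_names=recording.channel_names,
            meta=recording.meta,
            window_index=i,
            start_sample=int(s),
        )
        for i, s in enumerate(starts)
    ]


def bandpass(segment: Segment, spec: FilterSpec) -> Segment:
    """Apply the band-pass filter per channel, causal or zero-phase."""
    sos = spec.sos(segment.sampling_rate_hz)
    if spec.mode == "zero_phase":
        filtered = _signal.sosfiltfilt(sos, segment.samples, axis=0)
    else:
        filtered = _signal.sosfilt(sos, segment.samples, axis=0)
    return Segment(
        samples=np.ascontiguousarray(filtered),
        sampling_rate_hz=segment.sampling_rate_hz,
        channel_names=segment.channel_names,
        meta=segment.meta,
        window_index=segment.window_index,
        start_sample=segment.start_sample,
    )


def zscore(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standardize to zero mean and unit standard deviation.

    Zero-variance input maps to all zeros (with a warning) rather than
    raising, so degenerate synthetic fixtures do not abort a batch run.
    """
    x = np.asarray(values, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=0, keepdims=True)
    zero = sd == 0.0
    if np.any(zero):
        warnings.warn("zero-variance input to zscore; returning zeros", stacklevel=2)
    sd = np.where(zero, 1.0, sd)
    out = (x - mu) / sd
    return np.where(np.broadcast_to(zero, out.shape), 0.0, out)
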
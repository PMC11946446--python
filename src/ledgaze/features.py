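"""Welch PSD estimation and the five-band, eight-statistic feature bank.

A 768-sample segment is turned into a one-sided Welch PSD using a 637-sample
Hamming window with 636-sample overlap (132 averaged periodograms, frequency
resolution 256/637 ~ 0.402 Hz).  The PSD is sliced into the five classical
EEG bands and eight statistics are computed per band:

    kurtosis, mean, skewness, trapz, entropy, variance, mobility, complexity

giving 40 features per channel and 160 over the four active channels.
Feature ids are 1-based with the layout

    id = 40 * (channel_rank - 1) + 8 * (band_rank - 1) + statistic_rank

with channels ordered (AF3, F7, F8, AF4), bands delta..gamma, and statistics
as listed above; e.g. id 42 is (F7, delta, mean) and id 93 is
(F8, theta, entropy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .channels import ACTIVE_CHANNELS
from .preprocess import Segment

__all__ = [
    "WelchConfig",
    "PSDSpectrum",
    "BandDefinition",
    "BANDS",
    "STATISTICS",
    "welch_psd",
    "band_slice",
    "band_trapz",
    "band_features",
    "feature_vector",
    "feature_id",
    "describe_feature",
    "feature_index_map",
]


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings (window length, overlap, window function)."""

    window_len: int = 637
    noverlap: int = 636
    window_fn: str = "hamming"
    nfft: int | None = None  # defaults to window_len: no zero padding
    fs: float = 256.0

    def __post_init__(self) -> None:
        if not 0 <= self.noverlap < self.window_len:
            raise ValueError("need 0 <= noverlap < window_len")

    @property
    def resolved_nfft(self) -> int:
        return self.window_len if self.nfft is None else self.nfft

    @property
    def delta_f(self) -> float:
        return self.fs / self.resolved_nfft

    def n_windows(self, n_samples: int) -> int:
        return (n_samples - self.window_len) // (self.window_len - self.noverlap) + 1


DEFAULT_WELCH = WelchConfig()


@dataclass(frozen=True)
class PSDSpectrum:
    """One-sided PSD: frequency grid (Hz) and power density values."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs_hz.ndim != 1 or self.power.shape[0] != self.freqs_hz.shape[0]:
            raise ValueError("frequency and power grids must match along axis 0")

    @property
    def delta_f(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [lo, hi); ``closed_right`` includes hi."""

    name: str
    lo_hz: float
    hi_hz: float
    closed_right: bool = False


#: The five classical EEG bands; contiguous, non-overlapping, with the upper
#: (gamma) band closing at 45 Hz inclusive.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0, closed_right=True),
)

#: Statistic order within a band; fixed by the feature-id layout.
STATISTICS: tuple[str, ...] = (
    "kurtosis", "mean", "skewness", "trapz", "entropy",
    "variance", "mobility", "complexity",
)


def welch_psd(x: np.ndarray, cfg: WelchConfig = DEFAULT_WELCH) -> PSDSpectrum:
    """Welch PSD of a 1-D channel (or each column of a 2-D array).

    Averaged modified periodograms of overlapping Hamming-windowed blocks,
    no detrending, one-sided density scaling.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < cfg.window_len:
        raise ValueError(
            f"need at least window_len={cfg.window_len} samples, got {x.shape[0]}"
        )
    freqs, power = _signal.welch(
        x,
        fs=cfg.fs,
        window=cfg.window_fn,
        nperseg=cfg.window_len,
        noverlap=cfg.noverlap,
        nfft=cfg.resolved_nfft,
        detrend=False,
        scaling="density",
        axis=0,
    )
    return PSDSpectrum(freqs_hz=freqs, power=power)


def band_slice(psd: PSDSpectrum, band: BandDefinition) -> PSDSpectrum:
    """Restrict a PSD to one band (half-open; gamma closes at 45 inclusive)."""
    f = psd.freqs_hz
    mask = (f >= band.lo_hz) & ((f <= band.hi_hz) if band.closed_right else (f < band.hi_hz))
    if not mask.any():
        raise ValueError(f"band {band.name} [{band.lo_hz}, {band.hi_hz}) contains no bins")
    return PSDSpectrum(freqs_hz=f[mask], power=psd.power[mask])


def band_trapz(psd: PSDSpectrum) -> float:
    """Band power by the composite trapezoid rule over the PSD bins."""
    if psd.freqs_hz.size < 2:
        warnings.warn("single-bin band slice; trapezoid area is zero", stacklevel=2)
        return 0.0
    return float(np.trapezoid(psd.power, psd.freqs_hz))


def _hjorth(y: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility and complexity of a value sequence.

    mobility = sqrt(var(dy) / var(y)); complexity = mobility(dy) / mobility(y).
    Degenerate (constant) sequences map to zero.
    """
    var0 = float(np.var(y))
    if var0 == 0.0:
        return 0.0, 0.0
    dy = np.diff(y)
    var1 = float(np.var(dy))
    mobility = np.sqrt(var1 / var0)
    if var1 == 0.0:
        return float(mobility), 0.0
    ddy = np.diff(dy)
    var2 = float(np.var(ddy))
    complexity = np.sqrt(var2 / var1) / mobility
    return float(mobility), float(complexity)


def _shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy (natural log) of the slice normalized to sum one."""
    total = p.sum()
    if total <= 0.0:
        return 0.0
    q = p / total
    q = q[q > 0.0]
    return float(-(q * np.log(q)).sum())


def band_features(psd_slice: PSDSpectrum) -> np.ndarray:
    """The eight per-band statistics, in :data:`STATISTICS` order.

    Sample statistics (mean, variance, skewness, excess kurtosis) are taken
    over the band's PSD values; trapz integrates the band; entropy is the
    Shannon entropy of the normalized slice; mobility/complexity are Hjorth
    parameters of the PSD value sequence.
    """
    y = psd_slice.power
    mean = float(y.mean())
    var = float(y.var())
    if var == 0.0:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(_stats.skew(y))
        kurt = float(_stats.kurtosis(y))  # excess kurtosis
    trapz = band_trapz(psd_slice) if y.size >= 2 else 0.0
    entropy = _shannon_entropy(y)
    mobility, complexity = _hjorth(y)
    return np.array([kurt, mean, skew, trapz, entropy, var, mobility, complexity])


def feature_vector(
    segment: Segment,
    active_channels: tuple[str, ...] = ACTIVE_CHANNELS,
    cfg: WelchConfig = DEFAULT_WELCH,
) -> np.ndarray:
    """Concatenated per-channel, per-band feature bank for one segment.

    Length is ``40 * len(active_channels)`` in the documented id layout.
    """
    missing = [c for c in active_channels if c not in segment.channel_names]
    if missing:
        raise ValueError(f"segment is missing channels {missing}")
    cols = [segment.channel(c) for c in active_channels]
    psd = welch_psd(np.column_stack(cols), cfg)
    out = np.empty(len(active_channels) * len(BANDS) * len(STATISTICS))
    i = 0
    for ch in range(len(active_channels)):
        ch_psd = PSDSpectrum(psd.freqs_hz, psd.power[:, ch])
        for band in BANDS:
            out[i : i + len(STATISTICS)] = band_features(band_slice(ch_psd, band))
            i += len(STATISTICS)
    return out


def feature_id(channel: str, band: str, statistic: str,
               active_channels: tuple[str, ...] = ACTIVE_CHANNELS) -> int:
    """1-based feature id for (channel, band, statistic)."""
    ch_rank = active_channels.index(channel) + 1
    band_rank = [b.name for b in BANDS].index(band) + 1
    stat_rank = STATISTICS.index(statistic) + 1
    return 40 * (ch_rank - 1) + 8 * (band_rank - 1) + stat_rank


def describe_feature(fid: int,
                     active_channels: tuple[str, ...] = ACTIVE_CHANNELS
                     ) -> tuple[str, str, str]:
    """Inverse of :func:`feature_id`: (channel, band, statistic) for an id."""
    if not 1 <= fid <= 40 * len(active_channels):
        raise ValueError(f"feature id {fid} out of range 1..{40 * len(active_channels)}")
    z = fid - 1
    return (
        active_channels[z // 40],
        BANDS[(z % 40) // 8].name,
        STATISTICS[z % 8],
    )


def feature_index_map(active_channels: tuple[str, ...] = ACTIVE_CHANNELS) -> dict[int, dict]:
    """id -> {channel, band, statistic} for serializing alongside tables."""
    return {
        fid: dict(zip(("channel", "band", "statistic"), describe_feature(fid, active_channels)))
        for fid in range(1, 40 * len(active_channels) + 1)
    }
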
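"""Synthetic EEG/EOG cohort generator.

Emulates the study design the analysis pipeline assumes: 10 subjects, each
recorded 80 times for 16 s (3 s beep pad + 10 s task + 3 s beep pad) at
256 Hz on a 14-channel montage.  A recording is the sum of

* 1/f^alpha background EEG noise with a white floor,
* an electrooculographic (EOG) artifact during the task window, produced by
  the corneoretinal dipole as the eyes track a ball moving along one of four
  trajectories at one cycle per second, and
* when the LED is on, a 7 Hz steady-state visual evoked potential (SSVEP)
  with harmonics, strongest on the occipital channels and present at reduced
  weight frontally.

Identical configuration (including seed) yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
from scipy import signal as _signal

from .channels import ACTIVE_CHANNELS, CHANNELS, LEFT_CHANNELS, OCCIPITAL_CHANNELS

__all__ = [
    "ScreenGeometry",
    "TrajectorySpec",
    "SimulationConfig",
    "RecordingMeta",
    "Recording",
    "TRAJECTORY_NAMES",
    "gaze_angles",
    "trajectory_angle_series",
    "synth_eog",
    "synth_recording",
    "synth_cohort",
    "iter_cohort",
]


# --------------------------------------------------------------------------
# geometry and trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenGeometry:
    """Stimulus screen extent and viewing distance, in centimetres."""

    width_cm: float = 61.0
    height_cm: float = 34.0
    distance_cm: float = 120.0

    def __post_init__(self) -> None:
        if self.width_cm < 0 or self.height_cm < 0:
            raise ValueError("screen extents must be non-negative")
        if self.distance_cm <= 0:
            raise ValueError("viewing distance must be strictly positive")


def gaze_angles(geometry: ScreenGeometry) -> tuple[float, float]:
    """Full horizontal and vertical gaze angles subtended by the screen.

    Each full angle is ``2 * arctan((extent / 2) / distance)``, returned in
    degrees rounded to 0.1.  The default geometry (61 x 34 cm at 120 cm)
    gives (28.5, 16.1).
    """
    def full_angle(extent_cm: float) -> float:
        return round(math.degrees(2.0 * math.atan2(extent_cm / 2.0, geometry.distance_cm)), 1)

    return full_angle(geometry.width_cm), full_angle(geometry.height_cm)


#: Peak gaze deflection (x_deg, y_deg) per trajectory.  The horizontal and
#: vertical peaks are half the full screen angles of the default geometry.
#: left_cross is the right_cross pattern with the horizontal axis negated.
_TRAJECTORY_PEAKS: dict[str, tuple[float, float]] = {
    "right_left": (14.2, 0.0),
    "up_down": (0.0, 8.1),
    "right_cross": (14.2, 8.1),
    "left_cross": (-14.2, 8.1),
}

TRAJECTORY_NAMES: tuple[str, ...] = tuple(_TRAJECTORY_PEAKS)


@dataclass(frozen=True)
class TrajectorySpec:
    """One ball trajectory: sinusoidal gaze sweep with the given axis peaks."""

    name: str
    x_peak_deg: float
    y_peak_deg: float
    cycle_rate_hz: float = 1.0

    @classmethod
    def from_name(cls, name: str, cycle_rate_hz: float = 1.0) -> "TrajectorySpec":
        try:
            x_peak, y_peak = _TRAJECTORY_PEAKS[name]
        except KeyError:
            raise ValueError(
                f"unknown trajectory {name!r}; expected one of {TRAJECTORY_NAMES}"
            ) from None
        return cls(name=name, x_peak_deg=x_peak, y_peak_deg=y_peak, cycle_rate_hz=cycle_rate_hz)


def trajectory_angle_series(
    spec: TrajectorySpec, duration_s: float, fs: float
) -> np.ndarray:
    """Gaze angle time series for one trajectory.

    Returns an ``(n, 2)`` array of (x_deg, y_deg).  The eyes sweep the
    trajectory sinusoidally, completing ``cycle_rate_hz`` full cycles per
    second; both axes move in phase, so the extrema reach exactly the
    trajectory's peak angles.
    """
    n = duration_s * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration_s * fs must be an integer sample count")
    t = np.arange(int(round(n))) / fs
    phase = np.sin(2.0 * np.pi * spec.cycle_rate_hz * t)
    return np.column_stack([spec.x_peak_deg * phase, spec.y_peak_deg * phase])


# --------------------------------------------------------------------------
# EOG artifact projection
# --------------------------------------------------------------------------

def _dipole_weights(
    channel_names: Iterable[str], leakage: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel weights (wx, wy) of the corneoretinal dipole projection.

    The cornea is positively charged relative to the retina, so a rightward
    gaze drives right-frontal electrodes (F8, AF4) positive and left-frontal
    electrodes (AF3, F7) negative; vertical gaze drives all frontal
    electrodes with a common sign.  Non-frontal channels receive the same
    pattern attenuated by ``leakage``.
    """
    wx, wy = [], []
    for name in channel_names:
        if name in ACTIVE_CHANNELS:
            wx.append(1.0 if name in ("F8", "AF4") else -1.0)
            wy.append(1.0)
        else:
            wx.append(leakage if name not in LEFT_CHANNELS else -leakage)
            wy.append(leakage)
    return np.asarray(wx), np.asarray(wy)


def synth_eog(
    angle_series: np.ndarray,
    gain_uv_per_deg: float,
    channel_names: tuple[str, ...] = CHANNELS,
    *,
    leakage: float = 0.1,
    smoothing_s: float = 0.05,
    fs: float = 256.0,
) -> np.ndarray:
    """Project a gaze-angle series into a per-channel EOG artifact matrix.

    ``angle_series`` is ``(n, 2)`` in degrees; the result is ``(n, C)`` in
    microvolts: ``gain * (wx * x + wy * y)`` per channel, convolved with a
    ``smoothing_s``-long Hann kernel so deflection edges have saccade-like
    rise times rather than instantaneous steps.
    """
    if gain_uv_per_deg < 0:
        raise ValueError("EOG gain must be non-negative")
    angles = np.asarray(angle_series, dtype=float)
    if angles.ndim != 2 or angles.shape[1] != 2:
        raise ValueError("angle_series must have shape (n, 2)")
    wx, wy = _dipole_weights(channel_names, leakage)
    art = gain_uv_per_deg * (np.outer(angles[:, 0], wx) + np.outer(angles[:, 1], wy))
    klen = max(int(round(smoothing_s * fs)), 1)
    if klen > 1:
        kernel = np.hanning(klen + 2)[1:-1]
        kernel /= kernel.sum()
        art = _signal.fftconvolve(art, kernel[:, None], mode="same", axes=0)
    return art


# --------------------------------------------------------------------------
# full recordings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one synthetic recording.

    Amplitudes are in microvolts.  ``ssvep_channel_weights`` maps a channel
    group to the relative SSVEP strength it receives: the response is
    occipital, but a reduced frontal weight is injected so that the published
    frontal-channel gate is exercisable.  Defaults were calibrated once so
    that band amplitudes are EEG-plausible and the two classification stages
    are separable at realistic (not trivial) margins.
    """

    sampling_rate_hz: float = 256.0
    channel_names: tuple[str, ...] = CHANNELS
    led_on: bool = True
    trajectory: TrajectorySpec = field(
        default_factory=lambda: TrajectorySpec.from_name("right_left")
    )
    ssvep_freq_hz: float = 7.0
    ssvep_amp_uv: float = 20.0
    ssvep_harmonic_weights: tuple[float, ...] = (1.0, 0.25)
    ssvep_frontal_weight: float = 0.4
    eog_gain_uv_per_deg: float = 10.0
    eog_leakage: float = 0.1
    noise_spectral_exponent: float = 1.5
    noise_amp_uv: float = 15.0
    noise_white_fraction: float = 0.1
    beep_pad_s: float = 3.0
    task_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ssvep_amp_uv < 0 or self.noise_amp_uv < 0 or self.eog_gain_uv_per_deg < 0:
            raise ValueError("amplitudes must be non-negative")
        n = self.task_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("task_s * sampling_rate_hz must be an integer sample count")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def total_s(self) -> float:
        return 2.0 * self.beep_pad_s + self.task_s


@dataclass(frozen=True)
class RecordingMeta:
    subject_id: int
    led_on: bool
    trajectory: str
    repetition: int
    seed: int | None = None


@dataclass
class Recording:
    """One labelled multichannel recording (time x channel, microvolts)."""

    samples: np.ndarray
    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    meta: RecordingMeta

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def channel(self, name: str) -> np.ndarray:
        from .channels import channel_index

        return self.samples[:, channel_index(name, self.channel_names)]


def _colored_noise(
    rng: np.random.Generator,
    n: int,
    n_channels: int,
    fs: float,
    exponent: float,
    amp_uv: float,
    white_fraction: float,
) -> np.ndarray:
    """Gaussian noise with PSD ~ 1/f^exponent plus a white floor, scaled so
    every channel has standard deviation ``amp_uv``."""
    white = rng.standard_normal((n, n_channels))
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.empty_like(f)
    shape[0] = 0.0  # no DC
    shape[1:] = np.sqrt(f[1:] ** (-exponent) + white_fraction)
    out = np.fft.irfft(spec * shape[:, None], n=n, axis=0)
    sd = out.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    return out * (amp_uv / sd)


def _ssvep_channel_vector(config: SimulationConfig) -> np.ndarray:
    w = np.zeros(config.n_channels)
    for i, name in enumerate(config.channel_names):
        if name in OCCIPITAL_CHANNELS:
            w[i] = 1.0
        elif name in ACTIVE_CHANNELS:
            w[i] = config.ssvep_frontal_weight
    return w


def synth_recording(config: SimulationConfig) -> Recording:
    """Generate one full recording (beep pad + task + beep pad).

    The beep pads carry background noise only; the EOG artifact and, for
    LED-on recordings, the SSVEP occupy the central task window.
    """
    fs = config.sampling_rate_hz
    rng = np.random.default_rng(config.seed)
    n_total = int(round(config.total_s * fs))
    n_task = int(round(config.task_s * fs))
    pad = int(round(config.beep_pad_s * fs))

    samples = _colored_noise(
        rng,
        n_total,
        config.n_channels,
        fs,
        config.noise_spectral_exponent,
        config.noise_amp_uv,
        config.noise_white_fraction,
    )

    angles = trajectory_angle_series(config.trajectory, config.task_s, fs)
    samples[pad : pad + n_task] += synth_eog(
        angles,
        config.eog_gain_uv_per_deg,
        config.channel_names,
        leakage=config.eog_leakage,
        fs=fs,
    )

    if config.led_on and config.ssvep_amp_uv > 0:
        t = np.arange(n_task) / fs
        wave = np.zeros(n_task)
        for h, weight in enumerate(config.ssvep_harmonic_weights, start=1):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave += weight * np.sin(2.0 * np.pi * h * config.ssvep_freq_hz * t + phase)
        ssvep = config.ssvep_amp_uv * np.outer(wave, _ssvep_channel_vector(config))
        samples[pad : pad + n_task] += ssvep

    meta = RecordingMeta(
        subject_id=0,
        led_on=config.led_on,
        trajectory=config.trajectory.name,
        repetition=0,
        seed=config.seed,
    )
    return Recording(samples, fs, config.channel_names, meta)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def iter_cohort(
    n_subjects: int = 10,
    reps_per_class: int = 10,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
    subject_jitter: float = 0.2,
) -> Iterator[Recording]:
    """Lazily generate the full cohort.

    For each subject: every trajectory x LED condition x repetition, i.e.
    ``n_subjects * 4 * 2 * reps_per_class`` recordings (800 at defaults).
    Per-subject multiplicative jitter (up to ``subject_jitter``, seeded) on
    the EOG gain, SSVEP amplitude and noise amplitude makes per-subject
    evaluation non-degenerate.
    """
    if n_subjects <= 0 or reps_per_class <= 0:
        raise ValueError("cohort counts must be positive")
    base = base_config if base_config is not None else SimulationConfig()
    master = np.random.default_rng(seed)
    for subject in range(1, n_subjects + 1):
        jitter = master.uniform(1.0 - subject_jitter, 1.0 + subject_jitter, size=3)
        gain = base.eog_gain_uv_per_deg * jitter[0]
        ssvep = base.ssvep_amp_uv * jitter[1]
        noise = base.noise_amp_uv * jitter[2]
        for traj_name in TRAJECTORY_NAMES:
            for led_on in (True, False):
                for rep in range(1, reps_per_class + 1):
                    rec_seed = int(master.integers(0, 2**31 - 1))
                    cfg = replace(
                        base,
                        led_on=led_on,
                        trajectory=TrajectorySpec.from_name(
                            traj_name, base.trajectory.cycle_rate_hz
                        ),
                        eog_gain_uv_per_deg=gain,
                        ssvep_amp_uv=ssvep,
                        noise_amp_uv=noise,
                        seed=rec_seed,
                    )
                    rec = synth_recording(cfg)
                    rec.meta = RecordingMeta(
                        subject_id=subject,
                        led_on=led_on,
                        trajectory=traj_name,
                        repetition=rep,
                        seed=rec_seed,
                    )
                    yield rec


def synth_cohort(
    n_subjects: int = 10,
    reps_per_class: int = 10,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
) -> list[Recording]:
    """Materialized cohort; see :func:`iter_cohort`."""
    return list(iter_cohort(n_subjects, reps_per_class, base_config, seed))
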
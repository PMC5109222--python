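"""Synthetic HD-sEMG generator.

Surface EMG at a single channel resembles a zero-mean band-limited random
process whose standard deviation tracks local motor-unit activity.  The
generator builds, for each (subject, gesture), a non-negative per-pixel
amplitude field on the electrode grid and modulates band-limited Gaussian
noise with it, optionally adding a common floor noise, 50 Hz interference
and a motor-unit action-potential (MUAP) train mode for realism studies.
Every draw is fully determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .grid import ElectrodeGrid, Recording
from .preprocess import ConfigurationError

__all__ = ["SyntheticSpec", "GestureMap", "make_maps", "synthesize", "muap_train"]

#: Nominal analogue band of the acquisition chain at 1000 Hz sampling.
NOMINAL_BAND = (20.0, 380.0)
NOMINAL_FS = 1000.0

#: Peak amplitude (mV) of a gesture map; keeps +-4 sd within +-2.5 mV.
DEFAULT_PEAK_MV = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the synthetic HD-sEMG generator."""

    grid: ElectrodeGrid
    n_gestures: int = 4
    n_subjects: int = 1
    trials_per_gesture: int = 10
    fs: float = 1000.0
    duration: float = 0.5
    map_model: str = "gaussian_blobs"  # {"gaussian_blobs", "muap_train"}
    n_blobs: int = 3
    blob_width: tuple[float, float] = (1.0, 3.0)  # pixels (sd range)
    firing_rate: tuple[float, float] = (8.0, 25.0)  # Hz, muap_train mode
    waveform_width: float = 0.005  # s, muap_train mode
    snr: float = 5.0
    powerline_amp: float = 0.0
    subject_jitter: float = 0.05
    peak_mv: float = DEFAULT_PEAK_MV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gestures < 2:
            raise ValueError("need at least two gestures")
        if self.duration * self.fs < 1:
            raise ValueError("duration * fs must be at least one frame")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.map_model not in ("gaussian_blobs", "muap_train"):
            raise ValueError(f"unknown map_model {self.map_model!r}")

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.duration * self.fs))

    def band(self) -> tuple[float, float]:
        """Process band: 20-380 Hz at fs >= 1000, proportionally scaled below.

        Rates under 100 Hz cannot carry a useful EMG-like band and are
        rejected.
        """
        if self.fs < 100.0:
            raise ConfigurationError(
                f"fs={self.fs} Hz is too low for the generator (minimum 100 Hz)"
            )
        if self.fs >= NOMINAL_FS:
            lo, hi = NOMINAL_BAND
        else:
            lo = NOMINAL_BAND[0] * self.fs / NOMINAL_FS
            hi = NOMINAL_BAND[1] * self.fs / NOMINAL_FS
        if self.fs < 2 * hi:
            raise ConfigurationError(
                f"fs={self.fs} Hz cannot carry a band up to {hi} Hz"
            )
        return lo, hi


@dataclass(frozen=True)
class GestureMap:
    """Non-negative per-pixel amplitude field (mV) for one (subject, gesture)."""

    amplitude: np.ndarray
    subject: int
    gesture: int

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=np.float64)
        if amp.ndim != 2 or amp.size == 0:
            raise ValueError("amplitude must be a non-empty 2-D field")
        if amp.min() < 0:
            raise ValueError("amplitude field must be non-negative")
        object.__setattr__(self, "amplitude", amp)


def _blob_field(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    rows, cols = spec.grid.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    out = np.zeros((rows, cols))
    for _ in range(spec.n_blobs):
        r0 = rng.uniform(0, rows - 1)
        c0 = rng.uniform(0, cols - 1)
        w = rng.uniform(*spec.blob_width)
        out += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * w**2))
    return out


def make_maps(spec: SyntheticSpec) -> dict[tuple[int, int], GestureMap]:
    """Draw one amplitude field per (subject, gesture).

    Each gesture's field is an independent sum of ``n_blobs`` Gaussian
    blobs, scaled to a common peak amplitude; subjects share the gesture
    field up to multiplicative jitter, mimicking anatomy variation.
    """
    rng = np.random.default_rng(spec.seed)
    base: dict[int, np.ndarray] = {}
    for g in range(spec.n_gestures):
        field_ = _blob_field(rng, spec)
        if spec.n_blobs > 0 and field_.max() > 0:
            field_ = field_ * (spec.peak_mv / field_.max())
        base[g] = field_
    maps: dict[tuple[int, int], GestureMap] = {}
    for s in range(spec.n_subjects):
        for g in range(spec.n_gestures):
            jitter = 1.0 + spec.subject_jitter * rng.standard_normal(spec.grid.shape)
            amp = np.maximum(base[g] * jitter, 0.0)
            maps[(s, g)] = GestureMap(amp, subject=s, gesture=g)
    return maps


def _band_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited by a 2nd-order Butterworth."""
    b, a = sps.butter(2, list(band), btype="bandpass", fs=fs)
    white = rng.standard_normal(shape)
    filtered = sps.lfilter(b, a, white, axis=-1)
    # Noise gain from the impulse response renormalizes to unit variance.
    impulse = np.zeros(4096)
    impulse[0] = 1.0
    gain = np.sqrt(np.sum(sps.lfilter(b, a, impulse) ** 2))
    return filtered / gain


def synthesize(
    spec: SyntheticSpec, maps: dict[tuple[int, int], GestureMap] | None = None
) -> list[Recording]:
    """Generate labelled recordings, one per (subject, gesture, trial).

    Channel (r, c) at time t carries
    ``M_g(r, c) * e(r, c, t) + sigma0 * n(r, c, t) + a * sin(2 pi 50 t + phi)``
    where ``e`` and ``n`` are independent zero-mean unit-variance Gaussian
    processes band-limited to the spec band and ``sigma0 = peak_mv / snr``.
    Trials are numbered from 1.
    """
    if maps is None:
        maps = make_maps(spec)
    band = spec.band()
    sigma0 = spec.peak_mv / spec.snr
    n_frames = spec.frames_per_trial
    t = np.arange(n_frames) / spec.fs
    rng = np.random.default_rng([spec.seed, 1])
    out: list[Recording] = []
    for s in range(spec.n_subjects):
        for g in range(spec.n_gestures):
            amp = maps[(s, g)].amplitude
            amp_ch = spec.grid.gather(amp)  # (n_channels,)
            for trial in range(1, spec.trials_per_gesture + 1):
                e = _band_noise(rng, (spec.grid.n_channels, n_frames), spec.fs, band)
                n = _band_noise(rng, (spec.grid.n_channels, n_frames), spec.fs, band)
                x = amp_ch[:, None] * e + sigma0 * n
                if spec.powerline_amp > 0:
                    phi = rng.uniform(0, 2 * np.pi)
                    x = x + spec.powerline_amp * np.sin(2 * np.pi * 50.0 * t + phi)
                out.append(
                    Recording(x, fs=spec.fs, subject=s, gesture=g, trial=trial)
                )
    return out


def _biphasic_waveform(fs: float, width: float) -> np.ndarray:
    """Zero-mean biphasic MUAP waveform (Gaussian first derivative)."""
    half = max(int(round(3 * width * fs)), 2)
    tt = (np.arange(-half, half + 1)) / fs
    w = -tt / width**2 * np.exp(-(tt**2) / (2 * width**2))
    peak = np.abs(w).max()
    return w / peak if peak > 0 else w


def superpose_train(
    kernel_ch: np.ndarray, spike_frames: np.ndarray, wave: np.ndarray, n_frames: int
) -> np.ndarray:
    """Superpose one unit's waveform at the given discharge frames.

    Returns a ``(n_channels, n_frames)`` signal: the outer product of the
    spatial kernel with the spike train convolved with the waveform.
    """
    spikes = np.zeros(n_frames)
    if len(spike_frames):
        np.add.at(spikes, np.asarray(spike_frames, dtype=np.intp), 1.0)
    half = (len(wave) - 1) // 2
    train = np.convolve(spikes, wave)[half : half + n_frames]
    return kernel_ch[:, None] * train[None, :]


def muap_train(
    spec: SyntheticSpec, maps: dict[tuple[int, int], GestureMap] | None = None
) -> list[Recording]:
    """Physiological mode: superposition of motor-unit action-potential trains.

    Per gesture, each Gaussian blob of the amplitude field acts as one motor
    unit with a grid-localized spatial kernel; the unit fires as a Poisson
    renewal process at a rate drawn uniformly from ``spec.firing_rate`` and
    each discharge adds a biphasic waveform scaled by the kernel.
    """
    if spec.map_model != "muap_train":
        raise ValueError("spec.map_model must be 'muap_train'")
    rows, cols = spec.grid.shape
    n_frames = spec.frames_per_trial
    wave = _biphasic_waveform(spec.fs, spec.waveform_width)
    rng = np.random.default_rng([spec.seed, 2])
    rr, cc = np.mgrid[0:rows, 0:cols]
    out: list[Recording] = []
    for s in range(spec.n_subjects):
        for g in range(spec.n_gestures):
            units = []
            for _ in range(max(spec.n_blobs, 0)):
                r0 = rng.uniform(0, rows - 1)
                c0 = rng.uniform(0, cols - 1)
                w = rng.uniform(*spec.blob_width)
                kernel = spec.peak_mv * np.exp(
                    -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * w**2)
                )
                rate = rng.uniform(*spec.firing_rate)
                units.append((spec.grid.gather(kernel), rate))
            for trial in range(1, spec.trials_per_gesture + 1):
                x = np.zeros((spec.grid.n_channels, n_frames))
                for kernel_ch, rate in units:
                    times = np.empty(0, dtype=np.intp)
                    if rate > 0:
                        n_spk = rng.poisson(rate * spec.duration)
                        times = rng.uniform(0, n_frames, size=n_spk).astype(np.intp)
                    x += superpose_train(kernel_ch, times, wave, n_frames)
                out.append(
                    Recording(x, fs=spec.fs, subject=s, gesture=g, trial=trial)
                )
    return out


def generate(spec: SyntheticSpec) -> list[Recording]:
    """Dispatch on ``spec.map_model``."""
    if spec.map_model == "muap_train":
        return muap_train(spec)
    return synthesize(spec)
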
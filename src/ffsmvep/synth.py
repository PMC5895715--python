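"""Synthetic multichannel EEG with steady-state evoked responses.

Emulates the statistical structure of occipital EEG during periodic visual
stimulation so the preprocessing, decoding and speller stages can be
exercised without recorded data:

* a steady-state response locked to the stimulation frequency, built from a
  configurable harmonic-amplitude profile — fundamental-dominant for motion
  (SSMVEP) stimulation, harmonic-rich for luminance-flicker (SSVEP)
  stimulation;
* a 150 ms visual-pathway latency before the response appears;
* a saturating (logarithmic) dependence of response amplitude on stimulus
  contrast;
* occipital topography via per-channel gains (Oz strongest);
* background activity: 1/f ("pink") noise, alpha-band (10 Hz) activity,
  50 Hz mains interference, and broadband white noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ResponseProfile",
    "NoiseModel",
    "MultichannelRecording",
    "SyntheticSessionConfig",
    "SSMVEP_PROFILE",
    "SSVEP_PROFILE",
    "DEFAULT_CHANNELS",
    "DEFAULT_CHANNEL_GAINS",
    "pink_noise",
    "contrast_response",
    "generate_epoch",
    "generate_session",
]

#: Occipital/parieto-occipital montage used for decoding.
DEFAULT_CHANNELS: tuple[str, ...] = ("Oz", "O1", "O2", "PO1", "POz", "PO2")
#: Relative response gain per channel; Oz carries the strongest response.
DEFAULT_CHANNEL_GAINS: tuple[float, ...] = (1.0, 0.8, 0.8, 0.7, 0.9, 0.7)


@dataclass(frozen=True)
class ResponseProfile:
    """Harmonic structure of the steady-state response.

    ``harmonic_amplitudes[h-1]`` is the amplitude (uV) of harmonic ``h`` of
    the stimulation frequency.  Motion stimulation concentrates energy at
    the fundamental; flicker stimulation excites harmonics up to the fifth.
    """

    harmonic_amplitudes: tuple[float, ...]
    latency_s: float = 0.150
    phase_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.harmonic_amplitudes) < 1:
            raise ValueError("at least one harmonic amplitude required")
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be >= 0")
        if self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")
        if self.phase_offsets is not None and len(self.phase_offsets) != len(
            self.harmonic_amplitudes
        ):
            raise ValueError("phase_offsets length must match harmonic_amplitudes")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonic_amplitudes)

    def phases(self) -> np.ndarray:
        if self.phase_offsets is None:
            return np.zeros(self.n_harmonics)
        return np.asarray(self.phase_offsets, dtype=float)


#: Fundamental-dominant profile (motion checkerboard stimulation).
SSMVEP_PROFILE = ResponseProfile(harmonic_amplitudes=(1.0, 0.15, 0.05))
#: Harmonic-rich profile (luminance flicker stimulation, 5 harmonics).
SSVEP_PROFILE = ResponseProfile(harmonic_amplitudes=(1.0, 0.5, 0.25, 0.12, 0.06))


@dataclass(frozen=True)
class NoiseModel:
    """Amplitudes (uV RMS scales) of the background components.

    Alpha-band activity is modelled as narrowband noise (white noise
    band-passed around ``alpha_freq_hz``), not a pure sinusoid: real alpha
    waxes and wanes and is not phase-locked over seconds.
    """

    pink_scale: float = 1.0
    alpha_amplitude: float = 0.8
    mains_amplitude: float = 0.5
    white_scale: float = 0.5
    alpha_freq_hz: float = 10.0
    alpha_bandwidth_hz: float = 4.0
    mains_freq_hz: float = 50.0

    def __post_init__(self) -> None:
        for name in ("pink_scale", "alpha_amplitude", "mains_amplitude", "white_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, factor: float) -> "NoiseModel":
        """All stochastic/background amplitudes multiplied by ``factor``."""
        return replace(
            self,
            pink_scale=self.pink_scale * factor,
            alpha_amplitude=self.alpha_amplitude * factor,
            mains_amplitude=self.mains_amplitude * factor,
            white_scale=self.white_scale * factor,
        )


NOISELESS = NoiseModel(pink_scale=0.0, alpha_amplitude=0.0, mains_amplitude=0.0, white_scale=0.0)


@dataclass
class MultichannelRecording:
    """samples x channels EEG matrix with sampling rate and event onsets."""

    data: np.ndarray  # (n_samples, n_channels), uV
    fs_hz: float = 1200.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    onsets: list[tuple[int, float]] = field(default_factory=list)  # (sample, freq_hz)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[1]} channels but "
                f"{len(self.channel_labels)} labels given"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass(frozen=True)
class SyntheticSessionConfig:
    """Everything needed to synthesize one trial or a whole session."""

    profile: ResponseProfile = SSMVEP_PROFILE
    noise: NoiseModel = NoiseModel()
    channel_gains: tuple[float, ...] = DEFAULT_CHANNEL_GAINS
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    contrast: float = 1.0
    trial_duration_s: float = 5.0
    fs_hz: float = 1200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_gains) != len(self.channel_labels):
            raise ValueError("channel_gains length must equal channel count")
        if not 0 <= self.contrast <= 1:
            raise ValueError("contrast must lie in [0, 1]")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be > 0")


def pink_noise(n_samples: int, fs_hz: float, seed=None) -> np.ndarray:
    """1/f-amplitude ("pink") noise, unit standard deviation.

    Synthesized by shaping the spectrum of white Gaussian noise with a
    1/sqrt(f) amplitude profile (power falls as 1/f, i.e. log-log PSD slope
    about -1 over the EEG band).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # drop DC
    x = np.fft.irfft(spec * shaping, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def contrast_response(c: float, knee: float = 0.25, c0: float = 8e-4) -> float:
    """Saturating (logarithmic) amplitude multiplier for stimulus contrast.

    ``log(1 + c/c0) / log(1 + 1/c0)``: 0 at c = 0, 1 at c = 1, monotone,
    and already >= 0.8 of its maximum at the saturation knee c = 0.25 —
    the response grows steeply at low contrast and flattens beyond the knee.
    """
    if not 0 <= c <= 1:
        raise ValueError("contrast must lie in [0, 1]")
    if knee <= 0:
        raise ValueError("knee must be > 0")
    return float(np.log1p(c / c0) / np.log1p(1.0 / c0))


def _alpha_band_noise(
    n_samples: int, fs_hz: float, centre_hz: float, bandwidth_hz: float, rng
) -> np.ndarray:
    """Unit-SD narrowband noise centred on the alpha peak."""
    from scipy import signal as sps

    low = max(centre_hz - bandwidth_hz / 2.0, 0.1)
    high = centre_hz + bandwidth_hz / 2.0
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs_hz, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / sd if sd > 0 else x


def _response_waveform(
    config: SyntheticSessionConfig, f_stim_hz: float, n_samples: int
) -> np.ndarray:
    """Noise-free single-channel response (unit gain) with latency."""
    t = np.arange(n_samples) / config.fs_hz
    profile = config.profile
    amps = np.asarray(profile.harmonic_amplitudes, dtype=float)
    phases = profile.phases()
    x = np.zeros(n_samples)
    active = t >= profile.latency_s
    tau = t[active] - profile.latency_s
    for h, (a, phi) in enumerate(zip(amps, phases), start=1):
        x[active] += a * np.sin(2.0 * np.pi * h * f_stim_hz * tau + phi)
    return contrast_response(config.contrast) * x


def generate_epoch(
    config: SyntheticSessionConfig, f_stim_hz: float, seed=None
) -> MultichannelRecording:
    """Synthesize one stimulation trial.

    Each channel carries ``gain * contrast_response(c) * sum_h a_h
    sin(2 pi h f (t - latency) + phi_h)`` for t >= latency, plus independent
    pink and white noise, alpha-band activity with a random phase per
    channel, and common-phase mains interference.
    """
    if f_stim_hz <= 0:
        raise ValueError("f_stim_hz must be > 0")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = round(config.trial_duration_s * config.fs_hz)
    t = np.arange(n) / config.fs_hz

    response = _response_waveform(config, f_stim_hz, n)
    gains = np.asarray(config.channel_gains, dtype=float)
    data = np.outer(response, gains)

    noise = config.noise
    mains_phase = rng.uniform(0, 2 * np.pi)
    for ch in range(len(gains)):
        if noise.pink_scale > 0:
            data[:, ch] += noise.pink_scale * pink_noise(n, config.fs_hz, rng)
        if noise.alpha_amplitude > 0:
            data[:, ch] += noise.alpha_amplitude * _alpha_band_noise(
                n, config.fs_hz, noise.alpha_freq_hz, noise.alpha_bandwidth_hz, rng
            )
        if noise.mains_amplitude > 0:
            data[:, ch] += noise.mains_amplitude * np.sin(
                2 * np.pi * noise.mains_freq_hz * t + mains_phase
            )
        if noise.white_scale > 0:
            data[:, ch] += noise.white_scale * rng.standard_normal(n)

    return MultichannelRecording(
        data=data,
        fs_hz=config.fs_hz,
        channel_labels=config.channel_labels,
        onsets=[(0, f_stim_hz)],
    )


def generate_session(
    config: SyntheticSessionConfig,
    frequency_list,
    trials_per_freq: int = 1,
    seed=None,
) -> list[tuple[MultichannelRecording, float]]:
    """Synthesize ``trials_per_freq`` trials at each requested frequency.

    Per-trial seeds are spawned deterministically from the master seed, so a
    session is byte-identical on rerun and trials are mutually independent.
    """
    freqs = list(frequency_list)
    if not freqs:
        raise ValueError("frequency_list must be non-empty")
    if seed is None:
        seed = config.seed
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(freqs) * trials_per_freq)
    out: list[tuple[MultichannelRecording, float]] = []
    k = 0
    for _ in range(trials_per_freq):
        for f in freqs:
            out.append((generate_epoch(config, f, seed=children[k]), f))
            k += 1
    return out
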
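"""Filtering, epoching, segment averaging, and amplitude spectra.

The processing chain applied to every EEG epoch before decoding or
characterization:

1. zero-phase band-pass (Butterworth, 2-100 Hz by default) and band-stop
   notch (48-52 Hz) filtering;
2. epoch extraction with a 150 ms visual-latency shift after each stimulus
   onset;
3. averaging of non-overlapping segments whose length matches the
   stimulation period, which suppresses background activity while the
   phase-locked response survives;
4. Hamming-windowed single-sided amplitude spectra with coherent-gain
   correction, so a unit sinusoid at a bin centre reads amplitude 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import MultichannelRecording

__all__ = [
    "FilterSpec",
    "Spectrum",
    "BANDPASS_2_100",
    "BANDPASS_2_22",
    "NOTCH_48_52",
    "bandpass_filter",
    "notch_filter",
    "extract_epochs",
    "segment_average",
    "amplitude_spectrum",
    "snr",
]


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "bandpass" | "notch"
    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "notch"):
            raise ValueError("kind must be 'bandpass' or 'notch'")
        if not self.low_hz < self.high_hz:
            raise ValueError("low_hz must be < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")


#: Standard wide-band preset for time-frequency analysis and decoding.
BANDPASS_2_100 = FilterSpec("bandpass", 2.0, 100.0)
#: Narrow preset used for the contrast-response analysis.
BANDPASS_2_22 = FilterSpec("bandpass", 2.0, 22.0)
#: Mains-interference notch.
NOTCH_48_52 = FilterSpec("notch", 48.0, 52.0)


@dataclass
class Spectrum:
    """Single-sided amplitude spectrum."""

    freqs_hz: np.ndarray
    amplitudes: np.ndarray

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def amplitude_at(self, f_hz: float) -> float:
        """Amplitude of the bin nearest ``f_hz``."""
        return float(self.amplitudes[int(np.argmin(np.abs(self.freqs_hz - f_hz)))])

    def peak_freq(self, ignore_dc: bool = True) -> float:
        amps = self.amplitudes.copy()
        if ignore_dc:
            amps[0] = 0.0
        return float(self.freqs_hz[int(np.argmax(amps))])


def _sos(spec: FilterSpec, fs_hz: float) -> np.ndarray:
    if spec.high_hz >= fs_hz / 2:
        raise ValueError(
            f"corner frequency {spec.high_hz} Hz >= Nyquist ({fs_hz / 2} Hz)"
        )
    btype = "bandpass" if spec.kind == "bandpass" else "bandstop"
    return sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype=btype, fs=fs_hz, output="sos"
    )


def _filtfilt(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return sps.sosfiltfilt(sos, x, axis=0)


def bandpass_filter(x, fs_hz: float, spec: FilterSpec = BANDPASS_2_100) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the sample axis (axis 0)."""
    if spec.kind != "bandpass":
        raise ValueError("bandpass_filter requires a bandpass FilterSpec")
    return _filtfilt(x, _sos(spec, fs_hz))


def notch_filter(x, fs_hz: float, low_hz: float = 48.0, high_hz: float = 52.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-stop (mains notch) along axis 0."""
    return _filtfilt(x, _sos(FilterSpec("notch", low_hz, high_hz, order), fs_hz))


def extract_epochs(
    rec: MultichannelRecording,
    duration_s: float,
    latency_s: float = 0.150,
) -> list[tuple[np.ndarray, float]]:
    """Cut one epoch per onset, shifted by the visual-pathway latency.

    Epoch k spans samples ``[onset + round(latency * fs), ... + round(
    duration * fs))``; the stimulation-frequency label rides along.
    """
    shift = round(latency_s * rec.fs_hz)
    length = round(duration_s * rec.fs_hz)
    epochs: list[tuple[np.ndarray, float]] = []
    for onset, label in rec.onsets:
        start = onset + shift
        stop = start + length
        if start < 0 or stop > rec.n_samples:
            raise ValueError(
                f"epoch at onset {onset} (samples {start}:{stop}) falls outside "
                f"the {rec.n_samples}-sample recording"
            )
        epochs.append((rec.data[start:stop], label))
    return epochs


def segment_average(epoch: np.ndarray, segment_len_samples: int) -> np.ndarray:
    """Average non-overlapping segments; the trailing remainder is discarded.

    With segment length equal to an integer number of stimulation periods,
    the phase-locked response adds coherently while background activity
    averages down as 1/sqrt(n_segments).
    """
    if segment_len_samples <= 0:
        raise ValueError("segment_len_samples must be > 0")
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[0]
    m = n // segment_len_samples
    if m < 1:
        raise ValueError("epoch shorter than one segment")
    trimmed = epoch[: m * segment_len_samples]
    segments = trimmed.reshape(m, segment_len_samples, *epoch.shape[1:])
    return segments.mean(axis=0)


def amplitude_spectrum(x, fs_hz: float) -> Spectrum:
    """Hamming-windowed single-sided amplitude spectrum of one channel.

    Scaled by 2 / sum(window) (coherent-gain correction) so a unit sinusoid
    centred on a bin reads ~1; the DC bin is not doubled.
    """
    x = np.asarray(x, dtype=float).squeeze()
    if x.ndim != 1:
        raise ValueError("amplitude_spectrum expects a single channel")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    window = np.hamming(n)
    spec = np.fft.rfft(x * window)
    amps = 2.0 * np.abs(spec) / window.sum()
    amps[0] /= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not mirrored
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    return Spectrum(freqs, amps)


def snr(spec: Spectrum, f0_hz: float, k_neighbors: int = 10) -> float:
    """Local spectral signal-to-noise ratio at ``f0_hz``.

    Amplitude of the bin nearest f0 divided by the mean amplitude of the
    ``k_neighbors`` nearest bins on each side (the f0 bin excluded).
    Returns ``inf`` when the neighbourhood is exactly zero.
    """
    i0 = int(np.argmin(np.abs(spec.freqs_hz - f0_hz)))
    lo = i0 - k_neighbors
    hi = i0 + k_neighbors
    if lo < 0 or hi >= len(spec.freqs_hz):
        raise ValueError(
            f"need {k_neighbors} bins on each side of {f0_hz} Hz within the spectrum"
        )
    neighbors = np.r_[spec.amplitudes[lo:i0], spec.amplitudes[i0 + 1 : hi + 1]]
    denom = neighbors.mean()
    if denom == 0:
        return float("inf")
    return float(spec.amplitudes[i0] / denom)
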
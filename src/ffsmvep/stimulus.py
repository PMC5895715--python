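"""Ring-shaped motion checkerboard stimulus: geometry, motion, rendering,
and refresh-rate discretization analysis.

The stimulus is an annulus of concentric rings of equal radial width, each
ring split into an even number of angular sectors that alternate between a
bright and a dark luminance.  Because bright and dark checks always cover
equal areas, the mean luminance of the pattern is constant while the texture
expands and contracts — the stimulation is *flicker-free*: it delivers pure
motion, not luminance modulation.

The radial oscillation is a raised-cosine displacement

    s(t) = (A / 2) * (1 - cos(2 pi f_cycle t)),

where ``f_cycle`` is the modulation (sinusoid) frequency.  The motion
direction reverses twice per modulation cycle, so the *motion reversal
frequency* — the frequency the visual system locks onto and the fundamental
of the evoked response — is ``f_reversal = 2 * f_cycle``.

A display presents this continuous motion as discrete frames: each frame
holds the displacement constant for one refresh interval (zero-order hold).
At low refresh rates the held signal departs from the ideal waveform and
leaks energy into spurious spectral components (perceived as motion blur);
the functions here quantify that departure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusGeometry",
    "MotionProfile",
    "FrameSequence",
    "StimulusSignal",
    "radial_displacement",
    "render_frame",
    "render_sequence",
    "sampled_motion_signal",
    "continuous_motion_signal",
    "michelson_contrast",
    "visual_angle_deg",
]


class InvalidProfileError(ValueError):
    """Raised for non-positive motion frequencies or amplitudes."""


@dataclass(frozen=True)
class StimulusGeometry:
    """Geometry and luminance of the ring-checkerboard pattern.

    Defaults follow the reference setup: 100 px outer / 20 px inner
    diameter, 8 rings of 16 sectors, full contrast, 0.31 mm pixels viewed
    from 800 mm.
    """

    outer_diameter_px: float = 100.0
    inner_diameter_px: float = 20.0
    n_rings: int = 8
    n_sectors: int = 16
    l_max: float = 1.0
    l_min: float = 0.0
    pixel_pitch_mm: float = 0.31
    viewing_distance_mm: float = 800.0

    def __post_init__(self) -> None:
        if not self.outer_diameter_px > self.inner_diameter_px > 0:
            raise ValueError(
                "require outer_diameter_px > inner_diameter_px > 0, got "
                f"{self.outer_diameter_px} / {self.inner_diameter_px}"
            )
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.n_sectors < 2 or self.n_sectors % 2:
            raise ValueError("n_sectors must be even and >= 2")
        if not (0 <= self.l_min < self.l_max <= 1):
            raise ValueError("luminances must satisfy 0 <= l_min < l_max <= 1")

    @property
    def outer_radius_px(self) -> float:
        return self.outer_diameter_px / 2.0

    @property
    def inner_radius_px(self) -> float:
        return self.inner_diameter_px / 2.0

    @property
    def annulus_width_px(self) -> float:
        return self.outer_radius_px - self.inner_radius_px

    @property
    def ring_width_px(self) -> float:
        """Radial width of one ring; identical for all rings by construction."""
        return self.annulus_width_px / self.n_rings

    @property
    def contrast(self) -> float:
        return michelson_contrast(self.l_max, self.l_min)


@dataclass(frozen=True)
class MotionProfile:
    """Sinusoidal expansion-contraction motion.

    ``reversal_freq_hz`` is the rate of motion-direction changes (the
    evoked-response fundamental); the driving sinusoid completes one cycle
    per *two* reversals, so ``cycle_freq_hz = reversal_freq_hz / 2``.
    """

    reversal_freq_hz: float
    amplitude_px: float = 10.0

    def __post_init__(self) -> None:
        if self.reversal_freq_hz <= 0:
            raise InvalidProfileError("reversal_freq_hz must be > 0")
        if self.amplitude_px <= 0:
            raise InvalidProfileError("amplitude_px must be > 0")

    @property
    def cycle_freq_hz(self) -> float:
        return self.reversal_freq_hz / 2.0


@dataclass
class StimulusSignal:
    """Uniformly sampled displacement (or theoretical) waveform."""

    t: np.ndarray
    values: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have identical shape")


@dataclass
class FrameSequence:
    """Rendered frame stack with the per-frame radial displacement."""

    refresh_rate_hz: float
    frames: np.ndarray  # (n_frames, H, W) luminance in [l_min, l_max]
    displacement_px: np.ndarray  # (n_frames,)
    duration_s: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def mean_luminance(self) -> np.ndarray:
        """Per-frame mean luminance over the whole grid."""
        return self.frames.mean(axis=(1, 2))


def radial_displacement(profile: MotionProfile, t) -> np.ndarray | float:
    """Signed radial displacement s(t) = (A/2)(1 - cos(2 pi f_cycle t)).

    Starts at rest (s(0) = 0), reaches the extremum ``amplitude_px`` at the
    middle of each modulation cycle, and changes direction at the reversal
    frequency (twice per cycle).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    s = 0.5 * profile.amplitude_px * (1.0 - np.cos(2.0 * np.pi * profile.cycle_freq_hz * t_arr))
    return s if t_arr.ndim else float(s)


def render_frame(
    geometry: StimulusGeometry,
    displacement_px: float = 0.0,
    resolution: int = 200,
) -> np.ndarray:
    """Render one checkerboard frame at a given radial displacement.

    Pixels outside the annulus take the background luminance ``l_min``.
    Inside, check parity is ``(ring_index + sector_index) mod 2`` with
    ``ring_index`` computed from the radially shifted, wrapped radius —
    the wrap-around makes rings that leave the annulus reappear at the
    other edge, so the pattern extent never changes.
    """
    n = int(resolution)
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    # map grid so the pattern radius spans the geometry's outer radius
    scale = geometry.outer_radius_px / (n / 2.0)
    x = (xx - c) * scale
    y = (c - yy) * scale  # +y up, angle counter-clockwise from +x
    r = np.hypot(x, y)
    theta = np.mod(np.arctan2(y, x), 2.0 * np.pi)

    inside = (r >= geometry.inner_radius_px) & (r <= geometry.outer_radius_px)
    rr = np.mod(r - geometry.inner_radius_px + displacement_px, geometry.annulus_width_px)
    ring_index = np.floor(rr / geometry.ring_width_px).astype(int)
    ring_index = np.clip(ring_index, 0, geometry.n_rings - 1)  # guard float edge
    sector_index = np.floor(theta * geometry.n_sectors / (2.0 * np.pi)).astype(int)
    sector_index = np.clip(sector_index, 0, geometry.n_sectors - 1)

    bright = (ring_index + sector_index) % 2 == 0
    frame = np.full((n, n), geometry.l_min, dtype=float)
    frame[inside & bright] = geometry.l_max
    return frame


def render_sequence(
    geometry: StimulusGeometry,
    profile: MotionProfile,
    refresh_rate_hz: float,
    duration_s: float,
    resolution: int = 200,
) -> FrameSequence:
    """Render the motion sequence frame by frame at a display refresh rate.

    Frame ``k`` is drawn at displacement ``s(k / refresh_rate_hz)``.  A
    refresh rate below twice the reversal frequency cannot represent the
    motion and triggers a warning.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if refresh_rate_hz <= 2.0 * profile.reversal_freq_hz:
        warnings.warn(
            f"refresh rate {refresh_rate_hz} Hz <= 2x reversal frequency "
            f"{profile.reversal_freq_hz} Hz: motion will be severely aliased",
            stacklevel=2,
        )
    n_frames = round(duration_s * refresh_rate_hz)
    t = np.arange(n_frames) / refresh_rate_hz
    disp = radial_displacement(profile, t)
    frames = np.stack([render_frame(geometry, d, resolution) for d in disp])
    return FrameSequence(refresh_rate_hz, frames, disp, duration_s)


def continuous_motion_signal(
    profile: MotionProfile, duration_s: float, eval_rate_hz: float = 7200.0
) -> StimulusSignal:
    """Theoretical (continuous) displacement waveform on a dense grid."""
    n = round(duration_s * eval_rate_hz)
    t = np.arange(n) / eval_rate_hz
    return StimulusSignal(t, radial_displacement(profile, t), eval_rate_hz)


def sampled_motion_signal(
    profile: MotionProfile,
    refresh_rate_hz: float,
    duration_s: float,
    eval_rate_hz: float = 7200.0,
) -> StimulusSignal:
    """Zero-order-hold discretization of the motion waveform.

    The displacement a display actually shows: within each refresh interval
    the value of the waveform at the start of the frame is held constant.
    Evaluated on a dense grid (``eval_rate_hz``) so that hold steps, RMS
    error against :func:`continuous_motion_signal` and image spectra can be
    measured on a common axis.
    """
    if refresh_rate_hz <= 0:
        raise ValueError("refresh_rate_hz must be > 0")
    n = round(duration_s * eval_rate_hz)
    t = np.arange(n) / eval_rate_hz
    frame_times = np.floor(t * refresh_rate_hz) / refresh_rate_hz
    return StimulusSignal(t, radial_displacement(profile, frame_times), eval_rate_hz)


def michelson_contrast(l_max: float, l_min: float) -> float:
    """Michelson contrast c = (l_max - l_min) / (l_max + l_min)."""
    if not (0 <= l_min <= l_max):
        raise ValueError("require 0 <= l_min <= l_max")
    if l_max + l_min == 0:
        raise ZeroDivisionError("contrast undefined: l_max + l_min = 0")
    return (l_max - l_min) / (l_max + l_min)


def visual_angle_deg(
    diameter_px: float,
    pixel_pitch_mm: float,
    viewing_distance_mm: float,
    pi: float = math.pi,
) -> float:
    """Small-angle visual extent in degrees.

    ``diameter_px * pixel_pitch_mm / viewing_distance_mm`` radians, converted
    with 180/pi.  ``pi`` is overridable to reproduce back-of-envelope
    calculations that use 3.14.
    """
    if diameter_px < 0 or pixel_pitch_mm <= 0 or viewing_distance_mm <= 0:
        raise ValueError("pitch and distance must be > 0, diameter >= 0")
    return diameter_px * pixel_pitch_mm / viewing_distance_mm * (180.0 / pi)
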
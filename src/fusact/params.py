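"""Acquisition, stimulus, hemodynamic and motion parameter objects.

These are small frozen dataclasses with eager validation; everything
downstream (the phantom generator, the Doppler core, the GLM) takes them
by value, so an invalid combination fails before any array work starts.

Units are SI throughout (Hz, s, m); presentation layers convert to
mm/µm where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionParams",
    "StimulusProtocol",
    "HRFParams",
    "MotionModel",
    "make_default_protocol",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Ultrafast plane-wave acquisition geometry and timing.

    The pulse repetition frequency is derived, never stored:
    ``prf = compound_frame_rate * n_angles * temporal_averaging_factor``
    (7 angles x triple averaging x 500 Hz = 10.5 kHz at the defaults).

    Parameters
    ----------
    center_frequency : float
        Transmit center frequency in Hz (default 7.8 MHz, the linear-array
        probe used for transcranial-window imaging).
    compound_frame_rate : float
        Rate of angle-compounded, temporally averaged frames in Hz.
    angles_deg : tuple of float
        Plane-wave steering angles in degrees.
    temporal_averaging_factor : int
        Number of consecutive compounded frames averaged together.
    frames_per_block : int
        Compounded frames per power-Doppler block (250 at 500 Hz -> 2 Hz).
    speed_of_sound : float
        Assumed tissue sound speed in m/s.
    pixel_spacing_z, pixel_spacing_x : float
        Image grid spacing in meters/pixel (depth, lateral).
    """

    center_frequency: float = 7.8e6
    compound_frame_rate: float = 500.0
    angles_deg: tuple = (-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0)
    temporal_averaging_factor: int = 3
    frames_per_block: int = 250
    speed_of_sound: float = 1540.0
    pixel_spacing_z: float = 100e-6
    pixel_spacing_x: float = 100e-6

    def __post_init__(self):
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be > 0")
        if self.compound_frame_rate <= 0:
            raise ValueError("compound_frame_rate must be > 0")
        if len(self.angles_deg) < 1:
            raise ValueError("need at least one transmit angle")
        if self.temporal_averaging_factor < 1:
            raise ValueError("temporal_averaging_factor must be >= 1")
        if self.frames_per_block < 2:
            raise ValueError("frames_per_block must be >= 2")
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be > 0")
        if self.pixel_spacing_z <= 0 or self.pixel_spacing_x <= 0:
            raise ValueError("pixel spacings must be > 0")
        object.__setattr__(self, "angles_deg", tuple(float(a) for a in self.angles_deg))

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def prf(self) -> float:
        """Pulse repetition frequency in Hz (derived product)."""
        return self.compound_frame_rate * self.n_angles * self.temporal_averaging_factor

    @property
    def block_rate(self) -> float:
        """Power-Doppler output rate in Hz (compound rate / block length)."""
        return self.compound_frame_rate / self.frames_per_block

    @property
    def max_unaliased_velocity(self) -> float:
        """Largest axial blood speed (m/s) whose Doppler shift stays below
        the slow-time Nyquist frequency ``compound_frame_rate / 2``.

        f_d = 2 v f_c / c  <  rate/2   =>   v < c * rate / (4 f_c)
        """
        return self.speed_of_sound * self.compound_frame_rate / (4.0 * self.center_frequency)

    def doppler_frequency(self, axial_velocity: float) -> float:
        """Slow-time Doppler shift 2 v f_c / c in Hz."""
        return 2.0 * axial_velocity * self.center_frequency / self.speed_of_sound

    def replace(self, **kw) -> "AcquisitionParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class StimulusProtocol:
    """Block-design stimulation timing in seconds.

    ``onsets``/``durations`` are paired; the first onset cannot precede the
    end of the baseline rest period.
    """

    baseline_duration: float
    onsets: tuple
    durations: tuple
    total_duration: float

    def __post_init__(self):
        onsets = tuple(float(o) for o in self.onsets)
        durations = tuple(float(d) for d in self.durations)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if self.baseline_duration < 0:
            raise ValueError("baseline_duration must be >= 0")
        if len(onsets) != len(durations):
            raise ValueError("onsets and durations must have equal length")
        if any(d <= 0 for d in durations):
            raise ValueError("stimulus durations must be > 0")
        if any(b >= a for a, b in zip(onsets[1:], onsets[:-1])):
            raise ValueError("onsets must be strictly increasing")
        if onsets and onsets[0] < self.baseline_duration:
            raise ValueError("first onset precedes end of baseline period")
        for o, d in zip(onsets, durations):
            if o + d > self.total_duration + 1e-9:
                raise ValueError("stimulus extends past total_duration")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be > 0")

    @property
    def n_stimuli(self) -> int:
        return len(self.onsets)

    def boxcar(self, times: np.ndarray) -> np.ndarray:
        """Indicator of stimulation, sampled at ``times`` (s)."""
        times = np.asarray(times, dtype=float)
        out = np.zeros(times.shape)
        for o, d in zip(self.onsets, self.durations):
            out[(times >= o) & (times < o + d)] = 1.0
        return out

    def to_dict(self) -> dict:
        return {
            "baseline_duration": self.baseline_duration,
            "onsets": list(self.onsets),
            "durations": list(self.durations),
            "total_duration": self.total_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            baseline_duration=d["baseline_duration"],
            onsets=tuple(d["onsets"]),
            durations=tuple(d["durations"]),
            total_duration=d["total_duration"],
        )


def make_default_protocol(
    baseline: float = 20.0,
    n_stimuli: int = 3,
    stim_duration: float = 5.0,
    rest_duration: float = 20.0,
) -> StimulusProtocol:
    """Auditory block design: 20 s baseline, then three 5-s stimuli each
    followed by 20 s of rest (onsets 20, 45, 70 s; 95 s total)."""
    onsets = tuple(baseline + i * (stim_duration + rest_duration) for i in range(n_stimuli))
    durations = (stim_duration,) * n_stimuli
    total = (onsets[-1] + stim_duration + rest_duration) if onsets else baseline
    return StimulusProtocol(
        baseline_duration=baseline, onsets=onsets, durations=durations, total_duration=total
    )


@dataclass(frozen=True)
class HRFParams:
    """Delayed-gamma hemodynamic response parameters.

    h(t) = ((t - delta)/tau)^(n-1) * exp(-(t - delta)/tau) for t >= delta,
    0 before; unit peak at t = delta + (n - 1) * tau (2.9 s at defaults).
    """

    tau: float = 0.7
    delta: float = 1.5
    n: float = 3.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def peak_time(self) -> float:
        """Analytic argmax of the kernel: delta + (n - 1) * tau."""
        return self.delta + (self.n - 1.0) * self.tau


@dataclass(frozen=True)
class MotionModel:
    """Frame-to-frame motion applied by the phantom generator.

    kind
        "none", "rigid" (one global translation trajectory) or
        "smooth-nonrigid" (a smooth spatial displacement pattern scaled by
        a slow temporal waveform). Displacements are in pixels; the first
        frame is always at zero displacement.
    amplitude_px
        Maximum displacement magnitude.
    temporal_freq_hz
        Characteristic rate of the motion waveform (respiratory-scale
        scalp/tissue drift).
    spatial_scale_px
        Correlation length of the nonrigid displacement pattern.
    """

    kind: str = "smooth-nonrigid"
    amplitude_px: float = 1.0
    temporal_freq_hz: float = 0.3
    spatial_scale_px: float = 16.0

    def __post_init__(self):
        if self.kind not in ("none", "rigid", "smooth-nonrigid"):
            raise ValueError("kind must be none|rigid|smooth-nonrigid")
        if self.amplitude_px < 0:
            raise ValueError("amplitude_px must be >= 0")
        if self.temporal_freq_hz <= 0 or self.spatial_scale_px <= 0:
            raise ValueError("motion scales must be > 0")
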
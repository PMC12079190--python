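"""Seeded ultrafast-Doppler phantom for the auditory fUS experiment.

Generates per-angle (or pre-compounded) complex frame sequences containing:

* tissue clutter — high-amplitude, temporally low-rank (rank <= 3 before
  motion): a static amplitude map plus two small spatially patterned,
  slowly varying modulation terms;
* blood signal — per-pixel Doppler carrier exp(i 2*pi*f_d t) with
  f_d = 2 v f_c / c on the post-averaging (compound-rate) slow-time clock,
  multiplied by a unit-power complex AR(1) speckle envelope that models
  blood decorrelation (set ``speckle_correlation=None`` for a fully
  coherent vessel, the configuration used by analytic Doppler tests);
* stimulus-locked fractional CBV increases: amplitude scales by
  sqrt(1 + dCBV(t)) on activated pixels so power Doppler scales by
  exactly 1 + dCBV(t), with dCBV = effect_size * (boxcar (*) HRF,
  peak-normalized);
* additive complex white noise; and
* optional rigid or smooth-nonrigid frame-to-frame motion.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .doppler import AngleFrameSequence, CompoundedSequence
from .params import AcquisitionParams, HRFParams, MotionModel, StimulusProtocol

__all__ = [
    "VesselSegment",
    "PhantomScene",
    "make_phantom",
    "simulate_angle_frames",
    "simulate_compounded",
    "simulate_roi_timecourse",
    "cbv_response",
]

log = logging.getLogger(__name__)

# Frames assembled per chunk (fixed: part of the deterministic RNG stream).
_CHUNK = 4096
# Rate (Hz) at which motion displacement fields are refreshed; motion is
# ~0.3 Hz so piecewise-constant displacement between 20 Hz updates is
# indistinguishable at the pixel scale.
_MOTION_SAMPLE_HZ = 20.0


@dataclass(frozen=True)
class VesselSegment:
    """One vessel: a connected boolean mask, a slow-time axial velocity
    (m/s, positive toward the probe) and a per-pixel blood amplitude."""

    mask: np.ndarray
    axial_velocity: float
    blood_amplitude: float

    def __post_init__(self):
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if self.blood_amplitude < 0:
            raise ValueError("blood_amplitude must be >= 0")


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth description of a simulated imaging plane.

    ``tissue_mod_rel`` sets the relative size of the two time-varying
    tissue components (total tissue rank <= 3), ``speckle_correlation``
    the lag-1 correlation of the blood speckle envelope at the compound
    frame clock (None => coherent blood, no speckle).
    """

    grid_shape: tuple
    tissue_amplitude: np.ndarray
    vessel_segments: tuple
    activation_mask: np.ndarray
    effect_size: float
    noise_sigma: float
    speckle_correlation: float | None = 0.2
    tissue_mod_rel: float = 0.02

    def __post_init__(self):
        nz, nx = self.grid_shape
        if self.tissue_amplitude.shape != (nz, nx):
            raise ValueError("tissue_amplitude does not match grid_shape")
        if np.any(self.tissue_amplitude < 0):
            raise ValueError("tissue_amplitude must be nonnegative")
        if self.activation_mask.shape != (nz, nx):
            raise ValueError("activation_mask does not match grid_shape")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for v in self.vessel_segments:
            if v.mask.shape != (nz, nx):
                raise ValueError("vessel mask does not match grid_shape")
        union = self.vessel_union
        if np.any(self.activation_mask & ~union):
            raise ValueError("activation_mask must be a subset of the vessel union")

    @property
    def vessel_union(self) -> np.ndarray:
        union = np.zeros(self.grid_shape, dtype=bool)
        for v in self.vessel_segments:
            union |= v.mask
        return union

    def validate_velocities(self, acq: AcquisitionParams) -> None:
        """Reject vessels whose Doppler shift would alias on the
        compound-rate slow-time clock."""
        vmax = acq.max_unaliased_velocity
        for v in self.vessel_segments:
            if abs(v.axial_velocity) >= vmax:
                raise ValueError(
                    f"axial velocity {v.axial_velocity:g} m/s aliases: "
                    f"|v| must be < {vmax:g} m/s at "
                    f"{acq.compound_frame_rate:g} Hz / {acq.center_frequency:g} Hz"
                )


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-std smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def _draw_vessel_mask(rng: np.random.Generator, shape, width_px: float) -> np.ndarray:
    """Rasterize a gently curved tube crossing the interior of the grid."""
    nz, nx = shape
    theta = rng.uniform(0, np.pi)
    d = np.array([math.cos(theta), math.sin(theta)])
    center = np.array([rng.uniform(0.25 * nz, 0.75 * nz), rng.uniform(0.25 * nx, 0.75 * nx)])
    perp = np.array([-d[1], d[0]])
    # finite segment (not a full-grid chord): several disjoint vessels
    # must fit in one plane
    half_len = rng.uniform(0.22, 0.38) * max(nz, nx)
    t = np.arange(-half_len, half_len, 0.25)
    wiggle_amp = rng.uniform(0.0, 0.06) * max(nz, nx)
    wiggle_freq = rng.uniform(0.5, 1.5) / max(nz, nx)
    phase = rng.uniform(0, 2 * np.pi)
    pts = (
        center[None, :]
        + t[:, None] * d[None, :]
        + (wiggle_amp * np.sin(2 * np.pi * wiggle_freq * t + phase))[:, None] * perp[None, :]
    )
    raster = np.zeros(shape, dtype=bool)
    iz = np.round(pts[:, 0]).astype(int)
    ix = np.round(pts[:, 1]).astype(int)
    ok = (iz >= 0) & (iz < nz) & (ix >= 0) & (ix < nx)
    raster[iz[ok], ix[ok]] = True
    if not raster.any():
        # Degenerate draw (path missed the grid); fall back to a centered line.
        raster[nz // 2, :] = True
    dist = ndimage.distance_transform_edt(~raster)
    return dist <= width_px / 2.0


def make_phantom(
    grid_shape=(64, 64),
    n_vessels: int = 2,
    effect_size: float = 0.10,
    seed: int = 0,
    *,
    acq: AcquisitionParams | None = None,
    tissue_amplitude: float = 30.0,
    blood_amplitude: float = 0.15,
    noise_sigma: float = 0.1,
    speckle_correlation: float | None = 0.2,
    vessel_width_px=(4.0, 8.0),
    velocity_range=(5e-3, 15e-3),
) -> PhantomScene:
    """Build a seeded scene: smooth tissue map, ``n_vessels`` connected
    tube-shaped vessels, and an activation mask on the first vessel.

    Velocities are drawn from ``velocity_range`` (m/s) and checked against
    the slow-time aliasing bound of ``acq`` (defaults: 7.8 MHz / 500 Hz,
    bound ~24.7 mm/s).
    """
    nz, nx = grid_shape
    if nz < 16 or nx < 16:
        raise ValueError("grid_shape must be at least 16x16")
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)

    tissue = tissue_amplitude * (1.0 + 0.2 * _smooth_field(rng, grid_shape, 8.0))
    tissue = np.clip(tissue, 0.1 * tissue_amplitude, None)

    vessels = []
    union = np.zeros(grid_shape, dtype=bool)
    for _ in range(n_vessels):
        width = rng.uniform(*vessel_width_px)
        # keep vessels disjoint (>= 4 px apart) so reactive/nonreactive
        # ground truth is unambiguous; accept overlap only if the grid is
        # too crowded to place another separated vessel
        for _attempt in range(50):
            mask = _draw_vessel_mask(rng, grid_shape, width)
            if not (ndimage.binary_dilation(mask, iterations=4) & union).any():
                break
        else:
            log.warning("could not place a separated vessel; accepting overlap")
        union |= mask
        v = rng.uniform(*velocity_range) * rng.choice([-1.0, 1.0])
        vessels.append(VesselSegment(mask=mask, axial_velocity=float(v), blood_amplitude=blood_amplitude))

    if n_vessels >= 1 and effect_size > 0:
        activation = vessels[0].mask.copy()
    else:
        activation = np.zeros(grid_shape, dtype=bool)

    scene = PhantomScene(
        grid_shape=(nz, nx),
        tissue_amplitude=tissue,
        vessel_segments=tuple(vessels),
        activation_mask=activation,
        effect_size=float(effect_size),
        noise_sigma=float(noise_sigma),
        speckle_correlation=speckle_correlation,
    )
    scene.validate_velocities(acq)
    return scene


def cbv_response(protocol: StimulusProtocol, hrf: HRFParams, times: np.ndarray) -> np.ndarray:
    """Peak-normalized boxcar (*) gamma-HRF response sampled at ``times``.

    Returns zeros for a protocol without stimuli.
    """
    from .activation import gamma_hrf  # local import to avoid a cycle

    times = np.asarray(times, dtype=float)
    if len(protocol.onsets) == 0:
        return np.zeros_like(times)
    if times.size < 2:
        return protocol.boxcar(times)
    dt = float(np.median(np.diff(times)))
    kernel = gamma_hrf(hrf, dt=dt, duration=max(15.0, hrf.peak_time * 3))
    box = protocol.boxcar(times)
    resp = signal.fftconvolve(box, kernel)[: times.size]
    # FFT round-off leaves ~1e-17 residue where the response is exactly 0
    resp[np.abs(resp) < 1e-12 * max(resp.max(), 1.0)] = 0.0
    np.clip(resp, 0.0, None, out=resp)
    peak = resp.max()
    return resp / peak if peak > 0 else resp


# ---------------------------------------------------------------------------
# motion


def _motion_waveform(rng: np.random.Generator, times: np.ndarray, freq: float) -> np.ndarray:
    """Smooth scalar waveform, zero at t=0, max |.| == 1."""
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    f2 = freq * rng.uniform(1.3, 2.1)
    s = np.sin(2 * np.pi * freq * times + p1) + 0.5 * np.sin(2 * np.pi * f2 * times + p2)
    s = s - s[0]
    m = np.abs(s).max()
    return s / m if m > 0 else s


def _motion_fields(rng, motion: MotionModel, shape):
    """Static unit displacement pattern (2, nz, nx); scaled by the waveform."""
    nz, nx = shape
    if motion.kind == "rigid":
        direction = rng.standard_normal(2)
        direction /= np.linalg.norm(direction)
        fields = np.broadcast_to(direction[:, None, None], (2, nz, nx)).copy()
    else:  # smooth-nonrigid
        fields = np.stack(
            [_smooth_field(rng, shape, motion.spatial_scale_px) for _ in range(2)]
        )
        mag = np.sqrt((fields**2).sum(axis=0)).max()
        if mag > 0:
            fields /= mag
    return fields


def _bilinear_warp(frames2d: np.ndarray, disp, shape) -> np.ndarray:
    """Warp a batch of flattened frames by a displacement field (pixels).

    Output(z, x) = Input(z - dz, x - dx) with edge clamping, so positive
    displacement moves content toward increasing indices.
    """
    nz, nx = shape
    dz, dx = disp
    zz, xx = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
    src_z = np.clip(zz - dz, 0, nz - 1)
    src_x = np.clip(xx - dx, 0, nx - 1)
    z0 = np.floor(src_z).astype(int)
    x0 = np.floor(src_x).astype(int)
    z1 = np.minimum(z0 + 1, nz - 1)
    x1 = np.minimum(x0 + 1, nx - 1)
    wz = (src_z - z0).astype(frames2d.real.dtype)
    wx = (src_x - x0).astype(frames2d.real.dtype)
    i00 = (z0 * nx + x0).ravel()
    i01 = (z0 * nx + x1).ravel()
    i10 = (z1 * nx + x0).ravel()
    i11 = (z1 * nx + x1).ravel()
    wz = wz.ravel()
    wx = wx.ravel()
    return (
        frames2d[:, i00] * ((1 - wz) * (1 - wx))
        + frames2d[:, i01] * ((1 - wz) * wx)
        + frames2d[:, i10] * (wz * (1 - wx))
        + frames2d[:, i11] * (wz * wx)
    )


# ---------------------------------------------------------------------------
# signal assembly


class _SlowTimeModel:
    """Deterministic-plus-speckle noiseless signal on the compound clock."""

    def __init__(self, scene, protocol, acq, hrf, motion, rng, n_frames, dtype):
        nz, nx = scene.grid_shape
        self.shape = (nz, nx)
        self.npix = nz * nx
        self.n = n_frames
        self.dtype = dtype
        rate = acq.compound_frame_rate
        self.times = np.arange(n_frames) / rate

        # tissue: rank <= 3 (static map + two patterned slow modulations)
        g1 = _low_pass_series(rng, n_frames, rate, cutoff_hz=0.5)
        g2 = _low_pass_series(rng, n_frames, rate, cutoff_hz=0.5)
        p1 = _smooth_field(rng, (nz, nx), 8.0)
        p2 = _smooth_field(rng, (nz, nx), 8.0)
        amp = scene.tissue_mod_rel
        self.tissue_g = np.stack(
            [np.ones(n_frames), amp * g1, amp * g2], axis=1
        ).astype(np.float32)
        self.tissue_m = np.stack(
            [scene.tissue_amplitude, scene.tissue_amplitude * p1, scene.tissue_amplitude * p2]
        ).reshape(3, -1).astype(np.float32)

        # motion (set up first: vessels need the displacement schedule)
        self.motion = motion
        if motion is not None and motion.kind != "none" and motion.amplitude_px > 0:
            self.mfields = _motion_fields(rng, motion, (nz, nx))
            seg = np.floor(self.times * _MOTION_SAMPLE_HZ).astype(int)
            seg_times = np.unique(seg) / _MOTION_SAMPLE_HZ
            wave = _motion_waveform(rng, seg_times, motion.temporal_freq_hz)
            self.seg_of_frame = np.searchsorted(np.unique(seg), seg)
            self.seg_amp = motion.amplitude_px * wave
            dilate_px = int(np.ceil(motion.amplitude_px)) + 1
        else:
            self.mfields = None
            dilate_px = 0

        # vessels: indices, carrier frequency, phase, speckle, CBV scaling.
        # Motion displaces each vessel's amplitude envelope (the geometry);
        # the speckle process stays attached to the blood — interpolating a
        # spatially white speckle field would spuriously destroy its power.
        resp = cbv_response(protocol, hrf, self.times)
        self.vessel_cols = []
        for v in scene.vessel_segments:
            if dilate_px:
                support = ndimage.binary_dilation(v.mask, iterations=dilate_px)
            else:
                support = v.mask
            idx = np.flatnonzero(support.ravel())
            mask_float = v.mask.astype(np.float64).ravel()[None, :]
            fd = acq.doppler_frequency(v.axial_velocity)
            carrier = np.exp(2j * np.pi * fd * self.times).astype(np.complex64)
            phases = np.exp(2j * np.pi * rng.uniform(size=idx.size)).astype(np.complex64)
            if scene.speckle_correlation is None:
                speckle = None
            else:
                rho = float(scene.speckle_correlation)
                s = np.float32(np.sqrt(0.5))
                eps = np.empty((n_frames, idx.size), dtype=np.complex64)
                eps.real = rng.standard_normal((n_frames, idx.size), dtype=np.float32) * s
                eps.imag = rng.standard_normal((n_frames, idx.size), dtype=np.float32) * s
                if rho > 0:
                    speckle = signal.lfilter(
                        [np.sqrt(1 - rho**2)], [1.0, -rho], eps, axis=0
                    )
                    # stationary start
                    speckle[0] = eps[0]
                    speckle = speckle.astype(np.complex64)
                else:
                    speckle = eps
            # activated columns: the whole vessel when the activation mask
            # covers it (the default), else the (dilated) activation subset
            if np.array_equal(scene.activation_mask & v.mask, v.mask):
                act = np.ones(idx.size, dtype=bool)
            else:
                act_map = scene.activation_mask
                if dilate_px:
                    act_map = ndimage.binary_dilation(act_map & v.mask, iterations=dilate_px)
                act = act_map.ravel()[idx]
            gain = np.ones((n_frames, idx.size), dtype=np.float32)
            if act.any() and scene.effect_size > 0:
                gain[:, act] = np.sqrt(
                    1.0 + scene.effect_size * resp, dtype=np.float64
                ).astype(np.float32)[:, None]
            self.vessel_cols.append(
                dict(idx=idx, amp=v.blood_amplitude, carrier=carrier, phases=phases,
                     speckle=speckle, gain=gain, mask_float=mask_float,
                     envelope_cache={})
            )

    def _vessel_envelope(self, v: dict, seg: int) -> np.ndarray:
        """sqrt of the motion-displaced vessel volume fraction per pixel
        (power Doppler tracks blood volume, so amplitude goes as sqrt)."""
        if self.mfields is None:
            env = v["mask_float"][0, v["idx"]]
        else:
            cached = v["envelope_cache"].get(seg)
            if cached is not None:
                return cached
            disp = self.seg_amp[seg] * self.mfields
            warped = _bilinear_warp(v["mask_float"], disp, self.shape)[0, v["idx"]]
            env = np.sqrt(np.clip(warped, 0.0, 1.0))
            v["envelope_cache"][seg] = env.astype(np.float32)
            return v["envelope_cache"][seg]
        return np.sqrt(env).astype(np.float32)

    def noiseless(self, lo: int, hi: int) -> np.ndarray:
        """Flattened noiseless frames [lo, hi) as (m, npix) complex."""
        out = (self.tissue_g[lo:hi] @ self.tissue_m).astype(self.dtype)
        # tissue moves by resampling (smooth field: interpolation-safe)
        if self.mfields is not None:
            segs = self.seg_of_frame[lo:hi]
            for s in np.unique(segs):
                rows = np.flatnonzero(segs == s)
                disp = self.seg_amp[s] * self.mfields
                out[rows] = _bilinear_warp(out[rows], disp, self.shape)
        for v in self.vessel_cols:
            sig = (v["amp"] * v["gain"][lo:hi]) * v["carrier"][lo:hi, None]
            sig = sig * v["phases"][None, :]
            if v["speckle"] is not None:
                sig = sig * v["speckle"][lo:hi]
            if self.mfields is None:
                env = self._vessel_envelope(v, -1)[None, :]
                sig = sig * env
            else:
                segs = self.seg_of_frame[lo:hi]
                for s in np.unique(segs):
                    rows = np.flatnonzero(segs == s)
                    sig[rows] *= self._vessel_envelope(v, s)[None, :]
            out[:, v["idx"]] += sig.astype(self.dtype)
        return out


def _low_pass_series(rng, n, rate, cutoff_hz=0.5):
    """Unit-std slowly varying series (Gaussian-smoothed white noise)."""
    sigma = rate / (2 * np.pi * cutoff_hz)
    s = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma, mode="reflect")
    sd = s.std()
    return s / sd if sd > 0 else s


def _check_duration(protocol: StimulusProtocol, acq: AcquisitionParams) -> int:
    n = int(np.floor(protocol.total_duration * acq.compound_frame_rate))
    if n < acq.frames_per_block:
        raise ValueError(
            "protocol/acquisition duration mismatch: "
            f"{protocol.total_duration} s yields {n} compounded frames "
            f"< one block ({acq.frames_per_block})"
        )
    return n


def simulate_compounded(
    scene: PhantomScene,
    protocol: StimulusProtocol,
    acq: AcquisitionParams | None = None,
    hrf: HRFParams | None = None,
    motion: MotionModel | None = None,
    seed: int = 0,
    dtype=np.complex64,
) -> CompoundedSequence:
    """Simulate directly at the compound frame rate (post compounding and
    temporal averaging).

    The phantom's deterministic signal is constant across angles and
    within each averaging group (the Doppler clock is the 500 Hz compound
    clock), so this is exactly the angle-resolved simulation followed by
    compounding and averaging, with noise std ``noise_sigma /
    sqrt(n_angles * temporal_averaging_factor)``. Use this path for
    full-protocol runs; :func:`simulate_angle_frames` for exact per-angle
    output on short sequences.
    """
    acq = acq or AcquisitionParams()
    hrf = hrf or HRFParams()
    if motion is None:
        motion = MotionModel()
    scene.validate_velocities(acq)
    n = _check_duration(protocol, acq)
    rng = np.random.default_rng(seed)
    model = _SlowTimeModel(scene, protocol, acq, hrf, motion, rng, n, dtype)
    sigma_eff = scene.noise_sigma / math.sqrt(acq.n_angles * acq.temporal_averaging_factor)
    nz, nx = scene.grid_shape
    frames = np.empty((n, nz * nx), dtype=dtype)
    fdtype = np.float32 if dtype == np.complex64 else np.float64
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        block = model.noiseless(lo, hi)
        if sigma_eff > 0:
            s = fdtype(sigma_eff / np.sqrt(2.0))
            noise = np.empty((hi - lo, nz * nx), dtype=dtype)
            noise.real = rng.standard_normal((hi - lo, nz * nx), dtype=fdtype) * s
            noise.imag = rng.standard_normal((hi - lo, nz * nx), dtype=fdtype) * s
            block = block + noise
        frames[lo:hi] = block
    return CompoundedSequence(frames=frames.reshape(n, nz, nx), acq=acq)


def simulate_angle_frames(
    scene: PhantomScene,
    protocol: StimulusProtocol,
    acq: AcquisitionParams | None = None,
    hrf: HRFParams | None = None,
    motion: MotionModel | None = None,
    seed: int = 0,
    dtype=np.complex64,
) -> AngleFrameSequence:
    """Per-angle complex frames at the pre-averaging rate
    (``compound_frame_rate * temporal_averaging_factor`` frame times, each
    with ``n_angles`` angle frames).

    The deterministic signal is held on the compound clock; independent
    complex white noise (std ``noise_sigma``) is added to every
    (frame, angle) pair. Memory grows as angles x averaging x duration —
    intended for short sequences (unit tests, single-block quality runs).
    """
    acq = acq or AcquisitionParams()
    hrf = hrf or HRFParams()
    if motion is None:
        motion = MotionModel()
    scene.validate_velocities(acq)
    n500 = _check_duration(protocol, acq)
    fac = acq.temporal_averaging_factor
    na = acq.n_angles
    nz, nx = scene.grid_shape
    rng = np.random.default_rng(seed)
    model = _SlowTimeModel(scene, protocol, acq, hrf, motion, rng, n500, dtype)
    n_pre = n500 * fac
    frames = np.empty((n_pre, na, nz * nx), dtype=dtype)
    fdtype = np.float32 if dtype == np.complex64 else np.float64
    for lo in range(0, n500, _CHUNK):
        hi = min(lo + _CHUNK, n500)
        det = model.noiseless(lo, hi)  # (m, npix)
        rep = np.repeat(det, fac, axis=0)[:, None, :]  # (m*fac, 1, npix)
        m_pre = (hi - lo) * fac
        blk = np.broadcast_to(rep, (m_pre, na, nz * nx)).copy()
        if scene.noise_sigma > 0:
            s = fdtype(scene.noise_sigma / np.sqrt(2.0))
            noise = np.empty((m_pre, na, nz * nx), dtype=dtype)
            noise.real = rng.standard_normal((m_pre, na, nz * nx), dtype=fdtype) * s
            noise.imag = rng.standard_normal((m_pre, na, nz * nx), dtype=fdtype) * s
            blk += noise
        frames[lo * fac : hi * fac] = blk
    return AngleFrameSequence(frames=frames.reshape(n_pre, na, nz, nx), acq=acq)


def simulate_roi_timecourse(
    protocol: StimulusProtocol,
    block_rate: float = 2.0,
    effect_percent: float = 10.0,
    noise_sd_percent: float = 0.5,
    lag_s: float | None = None,
    seed: int = 0,
    shape: str = "step",
    hrf: HRFParams | None = None,
):
    """ROI-scale percent-change time course with an injected response.

    ``shape="step"`` adds exactly ``effect_percent`` inside each
    hemodynamically lagged stimulation window (the estimand of
    :func:`fusact.roi.stim_response_stats`); ``shape="hrf"`` adds the
    peak-normalized convolved response instead. Noise is white Gaussian at
    the ROI-averaged power-Doppler fluctuation scale (default 0.5 %/block,
    the scale of the default 64x64 phantom's vessel-ROI average).

    Returns ``(times, tc)`` with block-center timestamps in seconds.
    """
    hrf = hrf or HRFParams()
    if lag_s is None:
        lag_s = hrf.peak_time
    rng = np.random.default_rng(seed)
    n = int(round(protocol.total_duration * block_rate))
    times = (np.arange(n) + 0.5) / block_rate
    tc = rng.standard_normal(n) * noise_sd_percent
    if shape == "step":
        for o, d in zip(protocol.onsets, protocol.durations):
            tc[(times >= o + lag_s) & (times < o + d + lag_s)] += effect_percent
    elif shape == "hrf":
        tc += effect_percent * cbv_response(protocol, hrf, times)
    else:
        raise ValueError("shape must be 'step' or 'hrf'")
    return times, tc
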
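"""Conditioning of the power-Doppler series before statistics.

Fixed stage order (logged in the output metadata): motion correction ->
spatial Gaussian smoothing (sigma = 1 px) -> voxel normalization
(percent change from the prestimulus baseline by default) -> temporal
moving average (5 points).

Motion correction is subpixel translation registration by phase
cross-correlation — a documented simplification of clinical nonrigid
schemes; externally computed displacements can be injected through
``MotionCorrector(displacements=...)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from sklearn.base import BaseEstimator, TransformerMixin

from .doppler import PowerDopplerSeries
from .params import StimulusProtocol

__all__ = [
    "NormalizedSeries",
    "MotionCorrector",
    "correct_motion",
    "spatial_smooth",
    "normalize_voxels",
    "temporal_smooth",
    "preprocess_series",
]

log = logging.getLogger(__name__)


@dataclass
class NormalizedSeries:
    """Voxel-normalized series (percent change or zero-mean units).

    ``valid_mask`` marks voxels with a usable (positive) reference mean;
    invalid voxels are excluded from the GLM and ROI statistics.
    """

    values: np.ndarray
    block_rate: float
    block_timestamps: np.ndarray
    normalization_mode: str
    reference_window: tuple
    valid_mask: np.ndarray
    pixel_spacing_z: float = 1.0
    pixel_spacing_x: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[1:]


class MotionCorrector(TransformerMixin, BaseEstimator):
    """Frame-to-reference subpixel translation registration.

    ``fit`` estimates per-frame (dz, dx) displacements against the
    reference frame by upsampled phase cross-correlation;
    ``transform`` resamples each frame back by the negated displacement
    (bilinear, reflective edges). Estimated displacements are stored in
    ``displacements_`` (n_frames, 2), in pixels.
    """

    def __init__(self, reference_index: int = 0, upsample_factor: int = 20,
                 displacements=None):
        self.reference_index = reference_index
        self.upsample_factor = upsample_factor
        self.displacements = displacements

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[0] < 2:
            raise ValueError("expected (time, z, x) with >= 2 frames")
        if self.displacements is not None:
            d = np.asarray(self.displacements, dtype=float)
            if d.shape != (X.shape[0], 2):
                raise ValueError("displacements must be (n_frames, 2)")
            self.displacements_ = d
            return self
        ref = X[self.reference_index]
        disp = np.zeros((X.shape[0], 2))
        if not np.any(ref):
            log.warning("motion reference frame is all zero; identity transform")
            self.displacements_ = disp
            return self
        for i, frame in enumerate(X):
            if i == self.reference_index:
                continue
            if not np.any(frame):
                log.warning("frame %d is all zero; identity transform", i)
                continue
            shift, _, _ = phase_cross_correlation(
                ref, frame, upsample_factor=self.upsample_factor, normalization=None
            )
            disp[i] = -shift  # frame content sits at +disp relative to ref
        self.displacements_ = disp
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "displacements_")
        X = np.asarray(X)
        out = np.empty_like(X, dtype=float)
        for i, frame in enumerate(X):
            dz, dx = self.displacements_[i]
            if dz == 0 and dx == 0:
                out[i] = frame
            else:
                out[i] = ndimage.shift(frame, (-dz, -dx), order=1, mode="reflect")
        return np.clip(out, 0, None)


def correct_motion(pd_series: PowerDopplerSeries, reference_index: int = 0):
    """Register every PD frame to the reference frame.

    Returns ``(corrected_series, log)`` where the log is a DataFrame of
    per-frame estimated displacements in pixels.
    """
    mc = MotionCorrector(reference_index=reference_index).fit(pd_series.images)
    corrected = mc.transform(pd_series.images)
    log_df = pd_dataframe(mc.displacements_)
    prov = dict(pd_series.provenance)
    prov["motion_correction"] = {
        "method": "phase_cross_correlation_translation",
        "reference_index": reference_index,
        "max_displacement_px": float(np.abs(mc.displacements_).max()),
    }
    out = PowerDopplerSeries(
        images=corrected,
        block_rate=pd_series.block_rate,
        block_timestamps=pd_series.block_timestamps,
        pixel_spacing_z=pd_series.pixel_spacing_z,
        pixel_spacing_x=pd_series.pixel_spacing_x,
        provenance=prov,
    )
    return out, log_df


def pd_dataframe(displacements: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": np.arange(displacements.shape[0]),
            "dz": displacements[:, 0],
            "dx": displacements[:, 1],
        }
    )


def spatial_smooth(series: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Per-frame 2-D Gaussian smoothing (sigma in pixels, reflective
    boundary); sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    series = np.asarray(series)
    if sigma == 0:
        return series
    return ndimage.gaussian_filter(
        series.astype(float), sigma=(0, sigma, sigma), mode="reflect"
    )


def normalize_voxels(
    series: np.ndarray,
    mode: str = "percent_change",
    reference_window: tuple | None = None,
) -> tuple:
    """Remove each voxel's reference-window mean.

    percent_change: 100 * (x - mu_ref) / mu_ref; demean: x - mu_ref.
    ``reference_window`` is a half-open (start, stop) block-index pair;
    None uses the whole series. Voxels with non-positive reference mean in
    percent mode are flagged invalid (NaN output) rather than divided.

    Returns ``(values, valid_mask)``.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if reference_window is None:
        reference_window = (0, n)
    lo, hi = reference_window
    if not (0 <= lo < hi <= n):
        raise ValueError("empty or out-of-range reference window")
    mu = series[lo:hi].mean(axis=0)
    if mode == "percent_change":
        valid = mu > 0
        out = np.full_like(series, np.nan)
        out[:, valid] = 100.0 * (series[:, valid] - mu[valid]) / mu[valid]
        n_bad = int((~valid).sum())
        if n_bad:
            log.warning("normalize_voxels: %d voxel(s) with non-positive reference mean", n_bad)
    elif mode == "demean":
        valid = np.ones(series.shape[1:], dtype=bool)
        out = series - mu
    else:
        raise ValueError("mode must be 'percent_change' or 'demean'")
    return out, valid


def temporal_smooth(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average along the time axis; edges use shrinking
    windows; window = 1 is the identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    series = np.asarray(series, dtype=float)
    if window == 1:
        return series
    kernel = np.ones(window)
    num = ndimage.convolve1d(series, kernel, axis=0, mode="constant", cval=0.0)
    counts = ndimage.convolve1d(
        np.ones(series.shape[0]), kernel, mode="constant", cval=0.0
    )
    shape = (-1,) + (1,) * (series.ndim - 1)
    return num / counts.reshape(shape)


def smoothing_matrix(n: int, window: int) -> np.ndarray:
    """Explicit (n x n) matrix of :func:`temporal_smooth` (shrinking-edge
    moving average) for known-filter GLM variance correction."""
    K = np.zeros((n, n))
    h = window // 2
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        K[i, lo:hi] = 1.0 / (hi - lo)
    return K


def preprocess_series(
    pd_series: PowerDopplerSeries,
    protocol: StimulusProtocol | None = None,
    *,
    motion: bool = True,
    sigma: float = 1.0,
    window: int = 5,
    mode: str = "percent_change",
    reference: str = "baseline",
) -> NormalizedSeries:
    """Run the full conditioning chain in the fixed order
    motion -> spatial smooth -> normalize -> temporal smooth.

    ``reference="baseline"`` uses the prestimulus blocks of ``protocol``
    as the normalization window; ``"full"`` uses the whole series.
    """
    steps = []
    series = pd_series.images
    if motion:
        corrected, disp_log = correct_motion(pd_series)
        series = corrected.images
        steps.append("motion")
    else:
        disp_log = None
    series = spatial_smooth(series, sigma=sigma)
    steps.append(f"spatial_smooth(sigma={sigma})")

    if reference == "baseline":
        if protocol is None:
            raise ValueError("baseline reference requires a protocol")
        n_base = int(
            np.searchsorted(pd_series.block_timestamps, protocol.baseline_duration)
        )
        if n_base < 1:
            raise ValueError("baseline window contains no blocks")
        ref_window = (0, n_base)
    elif reference == "full":
        ref_window = (0, series.shape[0])
    else:
        raise ValueError("reference must be 'baseline' or 'full'")
    conditioned_pd = series  # motion-corrected, spatially smoothed, raw units
    values, valid = normalize_voxels(series, mode=mode, reference_window=ref_window)
    steps.append(f"normalize({mode}, window={ref_window})")
    values = temporal_smooth(values, window=window)
    steps.append(f"temporal_smooth(window={window})")

    meta = {
        "pipeline": steps,
        "temporal_window": window,
        "spatial_sigma": sigma,
        "source_provenance": dict(pd_series.provenance),
        # kept for ROI statistics: spatial averaging must precede the
        # percent-change conversion (ratio of means, not mean of ratios)
        "conditioned_pd": conditioned_pd,
    }
    if disp_log is not None:
        meta["displacements"] = disp_log
    return NormalizedSeries(
        values=values,
        block_rate=pd_series.block_rate,
        block_timestamps=pd_series.block_timestamps,
        normalization_mode=mode,
        reference_window=ref_window,
        valid_mask=valid,
        pixel_spacing_z=pd_series.pixel_spacing_z,
        pixel_spacing_x=pd_series.pixel_spacing_x,
        meta=meta,
    )
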
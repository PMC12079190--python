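"""ROI-level time courses, baseline z-scores and stimulation-response
statistics.

ROIs are ~2 mm x 2 mm rectangles placed either by hand or automatically:
candidate windows over well-vascularized pixels (above a power-Doppler
intensity percentile), with "reactive" windows maximizing the mean GLM
t-score and "nonreactive" windows minimizing |t|.

The response statistic compares the spatially averaged percent-change
signal inside hemodynamically lagged stimulation windows (default lag =
the HRF peak time, 2.9 s) against the pooled rest samples, with a Welch
two-sided t-test. Both the headline P < 0.001 flag and the stricter
P < 1e-5 flag are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .activation import ActivationMap
from .params import HRFParams, StimulusProtocol
from .preprocess import NormalizedSeries

__all__ = [
    "ROISpec",
    "ROIResult",
    "extract_roi_timeseries",
    "roi_percent_timecourse",
    "zscore_timecourse",
    "stim_response_stats",
    "select_rois",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROISpec:
    """Rectangular ROI in physical units (meters), with half-open pixel
    bounds derived from the grid spacing."""

    z0: float
    x0: float
    height: float
    width: float
    label: str = "custom"

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI area must be > 0")

    def pixel_bounds(self, spacing_z: float, spacing_x: float, grid_shape) -> tuple:
        """(iz0, iz1, ix0, ix1), half-open, clipped to the grid."""
        iz0 = int(round(self.z0 / spacing_z))
        ix0 = int(round(self.x0 / spacing_x))
        iz1 = iz0 + max(1, int(round(self.height / spacing_z)))
        ix1 = ix0 + max(1, int(round(self.width / spacing_x)))
        nz, nx = grid_shape
        if iz0 < 0 or ix0 < 0 or iz1 > nz or ix1 > nx:
            raise ValueError("ROI exceeds the image grid")
        return iz0, iz1, ix0, ix1

    @classmethod
    def from_pixels(cls, iz0, ix0, h_px, w_px, spacing_z, spacing_x, label="custom"):
        return cls(
            z0=iz0 * spacing_z,
            x0=ix0 * spacing_x,
            height=h_px * spacing_z,
            width=w_px * spacing_x,
            label=label,
        )


@dataclass
class ROIResult:
    """Per-ROI stimulation-response summary (percent-change units)."""

    time_course: np.ndarray
    z_course: np.ndarray
    mean_diff_percent: float
    t_statistic: float
    p_value: float
    n_pre: int
    n_stim: int
    per_stimulus_means: tuple
    significant_p001: bool
    significant_p1e5: bool
    label: str = "custom"
    meta: dict = field(default_factory=dict)


def extract_roi_timeseries(series, roi: ROISpec) -> np.ndarray:
    """Unweighted spatial mean over the ROI per block frame.

    Accepts a :class:`NormalizedSeries` (invalid voxels excluded, count
    logged) or a plain (t, z, x) array.
    """
    if isinstance(series, NormalizedSeries):
        values = series.values
        valid = series.valid_mask
        sz, sx = series.pixel_spacing_z, series.pixel_spacing_x
    else:
        values = np.asarray(series, dtype=float)
        valid = np.ones(values.shape[1:], dtype=bool)
        sz = sx = 1.0
    iz0, iz1, ix0, ix1 = roi.pixel_bounds(sz, sx, values.shape[1:])
    patch = values[:, iz0:iz1, ix0:ix1]
    vpatch = valid[iz0:iz1, ix0:ix1]
    n_excluded = int((~vpatch).sum())
    if n_excluded:
        log.info("ROI %s: excluding %d invalid voxel(s)", roi.label, n_excluded)
    if not vpatch.any():
        raise ValueError("ROI is empty after excluding invalid voxels")
    return patch[:, vpatch].mean(axis=1)


def roi_percent_timecourse(norm: NormalizedSeries, roi: ROISpec) -> np.ndarray:
    """ROI percent-change time course: spatial averaging first, then the
    percent conversion against the baseline-window mean of the averaged
    signal (ratio of means).

    Averaging the per-voxel percent maps instead (mean of ratios) is
    badly behaved wherever sub-pixel vessel displacement sweeps blood
    across near-zero-baseline voxels, so ROI statistics always use this
    path. Requires the conditioned (motion-corrected, smoothed, raw-unit)
    series that :func:`fusact.preprocess.preprocess_series` stores in
    ``meta["conditioned_pd"]``.
    """
    conditioned = norm.meta.get("conditioned_pd")
    if conditioned is None:
        raise ValueError("series lacks the conditioned (raw-unit) stack")
    tc_raw = extract_roi_timeseries(
        NormalizedSeries(
            values=conditioned,
            block_rate=norm.block_rate,
            block_timestamps=norm.block_timestamps,
            normalization_mode="raw",
            reference_window=norm.reference_window,
            valid_mask=norm.valid_mask,
            pixel_spacing_z=norm.pixel_spacing_z,
            pixel_spacing_x=norm.pixel_spacing_x,
        ),
        roi,
    )
    lo, hi = norm.reference_window
    mu = tc_raw[lo:hi].mean()
    if mu <= 0:
        raise ValueError("non-positive ROI baseline mean")
    return 100.0 * (tc_raw - mu) / mu


def zscore_timecourse(tc: np.ndarray, baseline_window: tuple) -> np.ndarray:
    """Standard score against the prestimulus baseline:
    z(t) = (tc(t) - mu_base) / sigma_base with the sample (n-1) std."""
    tc = np.asarray(tc, dtype=float)
    lo, hi = baseline_window
    base = tc[lo:hi]
    if base.size < 2:
        raise ValueError("baseline window needs >= 2 samples")
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "zero baseline variance: check the noise floor / baseline window"
        )
    return (tc - base.mean()) / sd


def stim_response_stats(
    tc: np.ndarray,
    protocol: StimulusProtocol,
    block_rate: float,
    *,
    lag_s: float | None = None,
    hrf: HRFParams | None = None,
    rest_mode: str = "pooled",
    equal_var: bool = False,
    label: str = "custom",
) -> ROIResult:
    """Compare stimulation-window samples against rest.

    Stimulation samples are blocks whose center time falls in
    ``[onset + lag, onset + duration + lag)``; the default lag is the HRF
    peak time (delta + (n-1) tau = 2.9 s). Rest is every other sample
    (``rest_mode="pooled"``) or the prestimulus baseline only
    (``rest_mode="baseline"``). The test is two-sided Welch by default
    (``equal_var=True`` for the pooled Student variant).
    """
    tc = np.asarray(tc, dtype=float)
    hrf = hrf or HRFParams()
    if lag_s is None:
        lag_s = hrf.peak_time
    times = (np.arange(tc.size) + 0.5) / block_rate

    stim_mask = np.zeros(tc.size, dtype=bool)
    per_stim = []
    for o, d in zip(protocol.onsets, protocol.durations):
        w = (times >= o + lag_s) & (times < o + d + lag_s)
        stim_mask |= w
        per_stim.append(float(tc[w].mean()) if w.any() else np.nan)

    base_mask = times < protocol.baseline_duration
    if rest_mode == "pooled":
        rest_mask = ~stim_mask
    elif rest_mode == "baseline":
        rest_mask = base_mask & ~stim_mask
    else:
        raise ValueError("rest_mode must be 'pooled' or 'baseline'")

    if stim_mask.sum() < 2 or rest_mask.sum() < 2:
        raise ValueError("need >= 2 samples in both stimulation and rest windows")

    stim = tc[stim_mask]
    rest = tc[rest_mask]
    tstat, p = stats.ttest_ind(stim, rest, equal_var=equal_var)
    mean_diff = float(stim.mean() - rest.mean())

    if base_mask.sum() >= 2 and tc[base_mask].std(ddof=1) > 0:
        z = zscore_timecourse(tc, (0, int(base_mask.sum())))
    else:
        z = np.full_like(tc, np.nan)

    return ROIResult(
        time_course=tc,
        z_course=z,
        mean_diff_percent=mean_diff,
        t_statistic=float(tstat),
        p_value=float(p),
        n_pre=int(rest_mask.sum()),
        n_stim=int(stim_mask.sum()),
        per_stimulus_means=tuple(per_stim),
        significant_p001=bool(p < 1e-3),
        significant_p1e5=bool(p < 1e-5),
        label=label,
        meta={
            "lag_s": lag_s,
            "rest_mode": rest_mode,
            "test": "student" if equal_var else "welch",
        },
    )


def _window_means(image: np.ndarray, h: int, w: int) -> np.ndarray:
    """Mean of every h x w window; entry (i, j) = window with corner (i, j)."""
    s = np.cumsum(np.cumsum(np.pad(image, ((1, 0), (1, 0))), axis=0), axis=1)
    total = s[h:, w:] - s[:-h, w:] - s[h:, :-w] + s[:-h, :-w]
    return total / (h * w)


def select_rois(
    act: ActivationMap,
    pd_mean: np.ndarray,
    pixel_spacing_z: float,
    pixel_spacing_x: float,
    roi_size_mm: float = 2.0,
    n_each: int = 1,
    vascular_percentile: float = 70.0,
) -> list:
    """Automatic reactive/nonreactive ROI placement.

    Candidate windows are those whose mean power-Doppler intensity exceeds
    the given percentile of all window means (well-defined vasculature).
    Reactive ROIs maximize the window-mean t-score; nonreactive ROIs
    minimize the window mean of |t|. Selected windows never overlap; ties
    break deterministically by (z, x) corner order. With an all-zero
    t-map both sets fall back to vascular-intensity ordering (warned).
    """
    t_map = np.nan_to_num(act.t_score, nan=0.0)
    pd_mean = np.asarray(pd_mean, dtype=float)
    if t_map.shape != pd_mean.shape:
        raise ValueError("activation map and PD image are not aligned")
    h = max(1, int(round(roi_size_mm * 1e-3 / pixel_spacing_z)))
    w = max(1, int(round(roi_size_mm * 1e-3 / pixel_spacing_x)))
    nz, nx = pd_mean.shape
    if h > nz or w > nx:
        raise ValueError("ROI size exceeds the image")

    vasc = _window_means(pd_mean, h, w)
    thresh = np.percentile(vasc, vascular_percentile)
    candidates = vasc >= thresh
    if not candidates.any():
        raise ValueError("no candidate windows above the vascular threshold")

    # Vascularity-weighted window scores: the ROI time course is dominated
    # by the bright (vascular) pixels of the window, so an unweighted mean
    # of t over a mostly empty window misranks windows whose few bright
    # pixels are strongly (non)reactive.
    with np.errstate(invalid="ignore"):
        t_mean = _window_means(t_map * pd_mean, h, w) / np.maximum(vasc, 1e-300)
        abs_t_mean = _window_means(np.abs(t_map) * pd_mean, h, w) / np.maximum(vasc, 1e-300)

    degenerate = not np.any(t_map)
    if degenerate:
        log.warning("all-zero t-map: ROI selection falls back to vascular intensity")

    taken = np.zeros_like(candidates)

    def pick(score: np.ndarray, maximize: bool, label: str, count: int):
        out = []
        score = np.where(candidates, score, -np.inf if maximize else np.inf)
        order_key = -score if maximize else score
        # lexicographic (score, z, x) tie-break: stable sort on flat index
        flat_order = np.argsort(order_key.ravel(), kind="stable")
        for idx in flat_order:
            if len(out) >= count:
                break
            if not np.isfinite(order_key.ravel()[idx]):
                continue
            i, j = divmod(int(idx), score.shape[1])
            if taken[max(0, i - h + 1) : i + h, max(0, j - w + 1) : j + w].any():
                continue  # overlap with an already selected window
            taken[i, j] = True
            out.append(
                ROISpec.from_pixels(i, j, h, w, pixel_spacing_z, pixel_spacing_x, label)
            )
        if len(out) < count:
            log.warning("only %d/%d %s ROI(s) could be placed", len(out), count, label)
        return out

    if degenerate:
        reactive = pick(vasc, True, "reactive", n_each)
        nonreactive = pick(vasc, False, "nonreactive", n_each)
    else:
        reactive = pick(t_mean, True, "reactive", n_each)
        nonreactive = pick(abs_t_mean, False, "nonreactive", n_each)
    return reactive + nonreactive
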
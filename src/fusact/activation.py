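"""Voxelwise GLM activation mapping against a gamma hemodynamic response.

The normalized power-Doppler series is regressed voxel by voxel on the
HRF-convolved stimulus boxcar (ordinary least squares, two-sided Student-t
on the task coefficient), and the resulting p-map is thresholded at
q < 1e-3 after Benjamini–Hochberg false-discovery-rate correction.

The hemodynamic kernel is the delayed gamma

    h(t) = ((t - delta)/tau)^(n-1) * exp(-(t - delta)/tau),  t >= delta

with tau = 0.7 s, delta = 1.5 s, n = 3 by default (unit peak at
delta + (n-1)*tau = 2.9 s).

When the series has been moving-average smoothed by a known matrix K, the
t statistic uses the Worsley–Friston known-filter correction
(Var(beta_hat) under V = K K^T, Satterthwaite effective degrees of
freedom) so that null calibration survives the pipeline's own smoothing.
Noise autocorrelation beyond the self-applied filter is not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .params import HRFParams, StimulusProtocol
from .preprocess import NormalizedSeries, preprocess_series, smoothing_matrix

__all__ = [
    "gamma_hrf",
    "DesignMatrix",
    "build_design_matrix",
    "ActivationMap",
    "GLMActivation",
    "fit_glm",
    "fdr_correct",
    "activation_pipeline",
]

log = logging.getLogger(__name__)


def gamma_hrf(params: HRFParams, dt: float, duration: float = 15.0) -> np.ndarray:
    """Sample the delayed-gamma HRF on a grid of spacing ``dt`` (s),
    peak-normalized to 1. ``duration`` must cover the kernel support."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration <= params.delta:
        raise ValueError("duration does not cover the kernel onset delay")
    t = np.arange(0.0, duration + dt / 2, dt)
    shifted = (t - params.delta) / params.tau
    h = np.zeros_like(t)
    pos = shifted > 0
    h[pos] = shifted[pos] ** (params.n - 1.0) * np.exp(-shifted[pos])
    peak = h.max()
    if peak <= 0:
        raise ValueError("HRF kernel is identically zero on this grid")
    return h / peak


@dataclass
class DesignMatrix:
    """GLM design: column 0 is the task regressor, column 1 the intercept."""

    matrix: np.ndarray
    names: tuple
    block_rate: float

    def __post_init__(self):
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


def build_design_matrix(
    protocol: StimulusProtocol,
    kernel: np.ndarray,
    n_frames: int,
    block_rate: float,
    add_drift: bool = False,
) -> DesignMatrix:
    """Task regressor = stimulus boxcar convolved with ``kernel`` (sampled
    at ``block_rate``), peak-normalized; plus an intercept and an optional
    linear drift column."""
    if len(protocol.onsets) == 0:
        raise ValueError("protocol has no stimuli; the design would be rank deficient")
    times = (np.arange(n_frames) + 0.5) / block_rate
    if times[-1] < protocol.total_duration - 1.0 / block_rate:
        log.info(
            "design truncated: %d frames cover %.1f s of a %.1f s protocol",
            n_frames, times[-1], protocol.total_duration,
        )
    box = protocol.boxcar(times)
    task = np.convolve(box, np.asarray(kernel, dtype=float))[:n_frames]
    peak = task.max()
    if peak <= 0:
        raise ValueError("task regressor is identically zero (check timing)")
    task = task / peak
    cols = [task, np.ones(n_frames)]
    names = ["task", "intercept"]
    if add_drift:
        drift = np.linspace(-1, 1, n_frames)
        cols.append(drift)
        names.append("drift")
    return DesignMatrix(matrix=np.column_stack(cols), names=tuple(names), block_rate=block_rate)


@dataclass
class ActivationMap:
    """Voxelwise GLM output with full threshold provenance."""

    beta: np.ndarray
    t_score: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    mask: np.ndarray
    mask_uncorrected: np.ndarray
    dof: float
    threshold: dict
    design: DesignMatrix | None = None
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple:
        return self.beta.shape


def _glm_arrays(Y, X, temporal_filter=None):
    """Vectorized OLS of Y (nt, nvox) on X (nt, k); returns beta (k, nvox),
    t, p for the task column (index 0) and the effective dof."""
    nt, k = X.shape
    if nt <= k:
        raise ValueError("need more time points than regressors")
    pinvX = np.linalg.pinv(X)
    B = pinvX @ Y
    resid = Y - X @ B
    rss = np.sum(resid**2, axis=0)
    if temporal_filter is None:
        dof = nt - k
        sigma2 = rss / dof
        c = np.linalg.inv(X.T @ X)[0, 0]
    else:
        K = np.asarray(temporal_filter)
        V = K @ K.T
        R = np.eye(nt) - X @ pinvX
        RV = R @ V
        tr_rv = np.trace(RV)
        dof = tr_rv**2 / np.trace(RV @ RV)
        sigma2 = rss / tr_rv
        c = (pinvX @ V @ pinvX.T)[0, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[0] / np.sqrt(sigma2 * c)
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return B, t, p, float(dof)


class GLMActivation(BaseEstimator):
    """Voxelwise GLM estimator.

    fit(series, protocol) builds the design (gamma HRF at the series'
    block rate) and sets ``beta_``, ``t_``, ``p_``, ``q_``, ``mask_``,
    ``dof_`` and ``design_``. ``q`` is the FDR level; ``p_threshold``
    additionally records an uncorrected mask.
    """

    def __init__(self, hrf: HRFParams | None = None, q: float = 1e-3,
                 p_threshold: float = 1e-3, add_drift: bool = False,
                 positive_only: bool = False):
        self.hrf = hrf
        self.q = q
        self.p_threshold = p_threshold
        self.add_drift = add_drift
        self.positive_only = positive_only

    def fit(self, series: NormalizedSeries, protocol: StimulusProtocol):
        hrf = self.hrf or HRFParams()
        kernel = gamma_hrf(hrf, dt=1.0 / series.block_rate)
        design = build_design_matrix(
            protocol, kernel, series.n_blocks, series.block_rate, add_drift=self.add_drift
        )
        window = series.meta.get("temporal_window", 1)
        K = smoothing_matrix(series.n_blocks, window) if window > 1 else None
        amap = fit_glm(series, design, temporal_filter=K)
        q_map, mask = fdr_correct(amap.p_value, q=self.q)
        if self.positive_only:
            mask = mask & (amap.t_score > 0)
        self.beta_ = amap.beta
        self.t_ = amap.t_score
        self.p_ = amap.p_value
        self.q_ = q_map
        self.mask_ = mask
        self.dof_ = amap.dof
        self.design_ = design
        self.map_ = ActivationMap(
            beta=amap.beta,
            t_score=amap.t_score,
            p_value=amap.p_value,
            q_value=q_map,
            mask=mask,
            mask_uncorrected=amap.p_value < self.p_threshold,
            dof=amap.dof,
            threshold={
                "p_threshold": self.p_threshold,
                "q": self.q,
                "correction": "FDR (Benjamini-Hochberg)",
                "sidedness": "positive" if self.positive_only else "two-sided",
                "hrf": {"tau": hrf.tau, "delta": hrf.delta, "n": hrf.n},
            },
            design=design,
        )
        return self


def fit_glm(
    series,
    design: DesignMatrix,
    temporal_filter: np.ndarray | None = None,
) -> ActivationMap:
    """Per-voxel OLS of the series on the design matrix.

    ``series`` is a :class:`NormalizedSeries` or a plain (nt, ...) array.
    Voxels flagged invalid by preprocessing get NaN statistics. The t test
    on the task coefficient is two-sided; ``temporal_filter`` is the known
    smoothing matrix applied to the data, if any (see module docstring).
    """
    if isinstance(series, NormalizedSeries):
        values = series.values
        valid = series.valid_mask
    else:
        values = np.asarray(series, dtype=float)
        valid = np.ones(values.shape[1:], dtype=bool)
    nt = values.shape[0]
    if nt != design.n_frames:
        raise ValueError("series/design length mismatch")
    grid = values.shape[1:]
    Y = values.reshape(nt, -1)
    vflat = valid.ravel() & np.all(np.isfinite(Y), axis=0)
    X = design.matrix
    beta = np.full((X.shape[1],) + (Y.shape[1],), np.nan)
    t = np.full(Y.shape[1], np.nan)
    p = np.full(Y.shape[1], np.nan)
    if vflat.any():
        B, tv, pv, dof = _glm_arrays(Y[:, vflat], X, temporal_filter)
        beta[:, vflat] = B
        t[vflat] = tv
        p[vflat] = pv
    else:
        dof = float(nt - X.shape[1])
    q = np.full_like(p, np.nan)
    return ActivationMap(
        beta=beta[0].reshape(grid),
        t_score=t.reshape(grid),
        p_value=p.reshape(grid),
        q_value=q.reshape(grid),
        mask=np.zeros(grid, dtype=bool),
        mask_uncorrected=(p.reshape(grid) < 1e-3),
        dof=dof,
        threshold={"correction": "none (raw GLM)"},
        design=design,
        meta={"intercept": beta[1].reshape(grid) if beta.shape[0] > 1 else None},
    )


def fdr_correct(p_map: np.ndarray, q: float = 1e-3):
    """Benjamini–Hochberg step-up over valid (finite) p-values.

    Returns ``(q_value_map, mask)``; NaNs propagate and are never
    discoveries. The mask is ``q_value < q``.
    """
    p_map = np.asarray(p_map, dtype=float)
    flat = p_map.ravel()
    valid = np.isfinite(flat)
    if np.any((flat[valid] < 0) | (flat[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q_flat = np.full_like(flat, np.nan)
    if valid.any():
        _, q_adj, _, _ = multipletests(flat[valid], alpha=q, method="fdr_bh")
        q_flat[valid] = q_adj
    q_map = q_flat.reshape(p_map.shape)
    mask = np.zeros(p_map.shape, dtype=bool)
    mask[np.isfinite(q_map)] = q_map[np.isfinite(q_map)] < q
    return q_map, mask


def activation_pipeline(
    pd_series,
    protocol: StimulusProtocol,
    hrf: HRFParams | None = None,
    q: float = 1e-3,
    *,
    motion: bool = True,
    sigma: float = 1.0,
    window: int = 5,
    mode: str = "percent_change",
    positive_only: bool = False,
):
    """preprocess -> design -> GLM -> FDR, with provenance.

    Returns ``(ActivationMap, NormalizedSeries)`` so downstream ROI
    statistics can reuse the conditioned series.
    """
    series = preprocess_series(
        pd_series, protocol, motion=motion, sigma=sigma, window=window, mode=mode
    )
    est = GLMActivation(hrf=hrf, q=q, positive_only=positive_only).fit(series, protocol)
    amap = est.map_
    amap.meta["preprocessing"] = series.meta.get("pipeline")
    return amap, series
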
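"""Readers, writers, run configuration and end-to-end orchestration.

Complex frame stacks travel as NIfTI (or multi-page TIFF) with the real
and imaginary parts split along the last axis and a JSON sidecar carrying
the acquisition metadata; power-Doppler series and activation maps are
NIfTI volumes with JSON sidecars recording rates, thresholds and
provenance. Every run emits a provenance record (version, parameter hash,
seed); outputs are reproducible bit-for-bit from config + seed
(timestamps are excluded from the hash).

Array layouts on disk (NIfTI axis order):
  angle frames  (z, x, 1, time, 2*n_angles)  [re(a0), im(a0), re(a1), ...]
  compounded    (z, x, 1, time, 2)
  power Doppler (z, x, 1, block_time)
  activation    (z, x, 1, 5)                 [beta, t, p, q, mask]
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage

from . import __version__
from .activation import ActivationMap, activation_pipeline
from .doppler import AngleFrameSequence, CompoundedSequence, PowerDopplerSeries, doppler_movie
from .metrics import quality_report
from .params import AcquisitionParams, HRFParams, MotionModel, StimulusProtocol, make_default_protocol
from .phantom import make_phantom, simulate_angle_frames, simulate_compounded
from .roi import roi_percent_timecourse, select_rois, stim_response_stats

__all__ = [
    "write_frames",
    "read_frames",
    "write_pd_series",
    "read_pd_series",
    "write_activation_map",
    "read_activation_map",
    "write_singular_spectra",
    "save_activation_overlay",
    "save_roi_timecourses",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


def write_singular_spectra(path, pds: PowerDopplerSeries) -> None:
    """CSV of per-block singular-value spectra (requires a series built
    with ``doppler_movie(..., keep_spectra=True)``)."""
    import pandas as pd

    spectra = pds.provenance.get("singular_values")
    if spectra is None:
        raise ValueError("series has no stored spectra (use keep_spectra=True)")
    df = pd.DataFrame(
        np.asarray(spectra),
        index=pd.Index(range(len(spectra)), name="block"),
        columns=[f"s{i}" for i in range(np.asarray(spectra).shape[1])],
    )
    df.to_csv(path)


def save_activation_overlay(path, amap: ActivationMap, pd_mean: np.ndarray) -> None:
    """PNG report figure: thresholded t-scores over the dB power-Doppler
    background."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .doppler import to_db

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(to_db(pd_mean), cmap="gray", vmin=-40, vmax=0)
    t_masked = np.where(amap.mask, amap.t_score, np.nan)
    im = ax.imshow(t_masked, cmap="hot", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="t-score (FDR-thresholded)")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("z (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_roi_timecourses(path, traces: dict, protocol: StimulusProtocol) -> None:
    """PNG of ROI percent-change time courses with stimulation windows."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for label, (times, tc) in traces.items():
        ax.plot(times, tc, label=label)
    for o, d in zip(protocol.onsets, protocol.durations):
        ax.axvspan(o, o + d, color="0.85", zorder=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("CBV change (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def _acq_to_dict(acq: AcquisitionParams) -> dict:
    return {
        "center_frequency": acq.center_frequency,
        "compound_frame_rate": acq.compound_frame_rate,
        "angles_deg": list(acq.angles_deg),
        "temporal_averaging_factor": acq.temporal_averaging_factor,
        "frames_per_block": acq.frames_per_block,
        "speed_of_sound": acq.speed_of_sound,
        "pixel_spacing_z": acq.pixel_spacing_z,
        "pixel_spacing_x": acq.pixel_spacing_x,
    }


def _acq_from_dict(d: dict) -> AcquisitionParams:
    return AcquisitionParams(**{k: (tuple(v) if k == "angles_deg" else v) for k, v in d.items()})


def write_frames(path, seq) -> Path:
    """Write an AngleFrameSequence or CompoundedSequence with its JSON
    sidecar; returns the sidecar path."""
    path = Path(path)
    if isinstance(seq, AngleFrameSequence):
        kind = "angle_frames"
        f = seq.frames  # (t, a, z, x)
        nt, na, nz, nx = f.shape
        data = np.empty((nz, nx, 1, nt, 2 * na), dtype=np.float32)
        for a in range(na):
            data[:, :, 0, :, 2 * a] = np.moveaxis(f[:, a].real, 0, -1)
            data[:, :, 0, :, 2 * a + 1] = np.moveaxis(f[:, a].imag, 0, -1)
    elif isinstance(seq, CompoundedSequence):
        kind = "compounded"
        f = seq.frames  # (t, z, x)
        data = np.stack(
            [np.moveaxis(f.real, 0, -1), np.moveaxis(f.imag, 0, -1)], axis=-1
        )[:, :, None, :, :].astype(np.float32)
    else:
        raise TypeError("expected AngleFrameSequence or CompoundedSequence")
    meta = {"kind": kind, "acquisition": _acq_to_dict(seq.acq)}
    if path.name.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, data)
    else:
        img = nib.Nifti1Image(data, affine=np.eye(4))
        img.header.set_zooms(
            (seq.acq.pixel_spacing_z * 1e3, seq.acq.pixel_spacing_x * 1e3, 1.0, 1.0, 1.0)[: data.ndim]
        )
        nib.save(img, str(path))
    sc = _sidecar_path(path)
    sc.write_text(json.dumps(meta, indent=1))
    return sc


def read_frames(path):
    """Read a frame file written by :func:`write_frames`; dispatches on
    the sidecar ``kind`` to the angle-resolved or compounded branch."""
    path = Path(path)
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sc}")
    meta = json.loads(sc.read_text())
    acq = _acq_from_dict(meta["acquisition"])
    if path.name.endswith((".tif", ".tiff")):
        data = tifffile.imread(path)
    else:
        data = np.asarray(nib.load(str(path)).dataobj)
    if not np.all(np.isfinite(data)):
        raise ValueError("frame file contains non-finite values")
    kind = meta["kind"]
    if kind == "angle_frames":
        nz, nx, _, nt, twice_na = data.shape
        if twice_na != 2 * acq.n_angles:
            raise ValueError(
                f"sidecar lists {acq.n_angles} angles but file has {twice_na // 2}"
            )
        frames = np.empty((nt, acq.n_angles, nz, nx), dtype=np.complex64)
        for a in range(acq.n_angles):
            frames[:, a] = np.moveaxis(
                data[:, :, 0, :, 2 * a] + 1j * data[:, :, 0, :, 2 * a + 1], -1, 0
            )
        return AngleFrameSequence(frames=frames, acq=acq)
    if kind == "compounded":
        nz, nx, _, nt, two = data.shape
        if two != 2:
            raise ValueError("compounded file must split real/imag on the last axis")
        frames = np.moveaxis(data[:, :, 0, :, 0] + 1j * data[:, :, 0, :, 1], -1, 0)
        return CompoundedSequence(frames=frames.astype(np.complex64), acq=acq)
    raise ValueError(f"unknown frame kind {kind!r}")


def write_pd_series(path, pds: PowerDopplerSeries) -> Path:
    path = Path(path)
    data = np.moveaxis(pds.images, 0, -1)[:, :, None, :].astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms(
        (pds.pixel_spacing_z * 1e3, pds.pixel_spacing_x * 1e3, 1.0, 1.0 / pds.block_rate)
    )
    nib.save(img, str(path))
    prov = {k: v for k, v in pds.provenance.items() if not isinstance(v, np.ndarray)}
    meta = {
        "kind": "power_doppler",
        "block_rate": pds.block_rate,
        "block_timestamps": list(map(float, pds.block_timestamps)),
        "pixel_spacing_z": pds.pixel_spacing_z,
        "pixel_spacing_x": pds.pixel_spacing_x,
        "provenance": prov,
    }
    sc = _sidecar_path(path)
    sc.write_text(json.dumps(meta, indent=1))
    return sc


def read_pd_series(path) -> PowerDopplerSeries:
    path = Path(path)
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sc}")
    meta = json.loads(sc.read_text())
    data = np.asarray(nib.load(str(path)).dataobj)
    images = np.moveaxis(data[:, :, 0, :], -1, 0).astype(float)
    return PowerDopplerSeries(
        images=images,
        block_rate=meta["block_rate"],
        block_timestamps=np.asarray(meta["block_timestamps"]),
        pixel_spacing_z=meta["pixel_spacing_z"],
        pixel_spacing_x=meta["pixel_spacing_x"],
        provenance=meta.get("provenance", {}),
    )


def write_activation_map(path, amap: ActivationMap, spacing=(1e-4, 1e-4)) -> Path:
    path = Path(path)
    stack = np.stack(
        [amap.beta, amap.t_score, amap.p_value, amap.q_value, amap.mask.astype(float)],
        axis=-1,
    )[:, :, None, :].astype(np.float32)
    nib.save(nib.Nifti1Image(stack, affine=np.eye(4)), str(path))
    meta = {
        "kind": "activation_map",
        "volumes": ["beta", "t_score", "p_value", "q_value", "mask"],
        "dof": amap.dof,
        "threshold": amap.threshold,
        "pixel_spacing_z": spacing[0],
        "pixel_spacing_x": spacing[1],
    }
    sc = _sidecar_path(path)
    sc.write_text(json.dumps(meta, indent=1))
    return sc


def read_activation_map(path) -> ActivationMap:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = np.asarray(nib.load(str(path)).dataobj)[:, :, 0, :].astype(float)
    p = data[..., 2]
    return ActivationMap(
        beta=data[..., 0],
        t_score=data[..., 1],
        p_value=p,
        q_value=data[..., 3],
        mask=data[..., 4] > 0.5,
        mask_uncorrected=p < meta["threshold"].get("p_threshold", 1e-3),
        dof=meta["dof"],
        threshold=meta["threshold"],
    )


# ---------------------------------------------------------------------------
# run configuration


class RunConfig(BaseModel):
    """Validated end-to-end run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    out_dir: str = "fusact_run"
    grid_shape: tuple = (64, 64)
    n_vessels: int = 2
    effect_size: float = 0.10
    svd_fraction: float = 0.13
    spatial_sigma: float = 1.0
    temporal_window: int = 5
    q: float = 1e-3
    roi_size_mm: float = 2.0
    motion_kind: str = "smooth-nonrigid"
    motion_correction: bool = True
    protocol: dict = Field(default_factory=lambda: make_default_protocol().to_dict())
    hrf: dict = Field(default_factory=lambda: {"tau": 0.7, "delta": 1.5, "n": 3.0})
    acquisition: dict = Field(default_factory=dict)

    def parameter_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return RunConfig(**data)


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> doppler -> preprocess -> activation -> ROI -> metrics.

    Writes all intermediates plus ``roi_report.json``, ``quality.json``
    and ``provenance.json`` under ``config.out_dir``; returns the report
    bundle as a dict. Deterministic given the config (and its seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = StimulusProtocol.from_dict(config.protocol)
    hrf = HRFParams(**config.hrf)
    acq = _acq_from_dict({**_acq_to_dict(AcquisitionParams()), **config.acquisition})
    motion = MotionModel(kind=config.motion_kind)

    scene = make_phantom(
        tuple(config.grid_shape), config.n_vessels, config.effect_size,
        seed=config.seed, acq=acq,
    )
    seq = simulate_compounded(scene, protocol, acq, hrf, motion, seed=config.seed)
    pds = doppler_movie(seq, svd_fraction=config.svd_fraction)
    write_pd_series(out / "pd.nii.gz", pds)

    amap, norm = activation_pipeline(
        pds, protocol, hrf=hrf, q=config.q,
        motion=config.motion_correction,
        sigma=config.spatial_sigma, window=config.temporal_window,
    )
    write_activation_map(out / "activation.nii.gz", amap,
                         spacing=(acq.pixel_spacing_z, acq.pixel_spacing_x))

    rois = select_rois(
        amap, pds.mean_image(), acq.pixel_spacing_z, acq.pixel_spacing_x,
        roi_size_mm=config.roi_size_mm,
    )
    disp = norm.meta.get("displacements")
    if disp is not None:
        disp.to_csv(out / "displacements.csv", index=False)
    save_activation_overlay(out / "activation.png", amap, pds.mean_image())

    roi_stats = []
    traces = {}
    for roi in rois:
        tc = roi_percent_timecourse(norm, roi)
        traces[roi.label] = (norm.block_timestamps, tc)
        res = stim_response_stats(tc, protocol, pds.block_rate, hrf=hrf, label=roi.label)
        roi_stats.append(
            {
                "label": roi.label,
                "z0_m": roi.z0, "x0_m": roi.x0,
                "height_m": roi.height, "width_m": roi.width,
                "mean_diff_percent": res.mean_diff_percent,
                "t_statistic": res.t_statistic,
                "p_value": res.p_value,
                "significant_p001": res.significant_p001,
                "significant_p1e5": res.significant_p1e5,
                "n_stim": res.n_stim, "n_pre": res.n_pre,
                "per_stimulus_means": list(res.per_stimulus_means),
            }
        )

    vessel = scene.vessel_union
    background = ~ndimage.binary_dilation(vessel, iterations=3)
    qrep = quality_report(pds.mean_image(), vessel, background)

    report = {
        "n_blocks": pds.n_blocks,
        "block_rate_hz": pds.block_rate,
        "n_activated_voxels": int(amap.mask.sum()),
        "n_activated_uncorrected": int(amap.mask_uncorrected.sum()),
        "cnr_db": qrep.cnr_db,
        "cnr_definition": qrep.definitions["cnr"],
        "rois": roi_stats,
    }
    save_roi_timecourses(out / "roi_timecourses.png", traces, protocol)
    (out / "roi_report.json").write_text(json.dumps({"rois": roi_stats}, indent=1))
    import pandas as pd
    pd.DataFrame(roi_stats).to_csv(out / "roi_report.csv", index=False)
    (out / "quality.json").write_text(
        json.dumps({"cnr_db": qrep.cnr_db, "definitions": qrep.definitions}, indent=1)
    )
    provenance = {
        "version": __version__,
        "parameter_hash": config.parameter_hash(),
        "config": config.model_dump(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return report
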
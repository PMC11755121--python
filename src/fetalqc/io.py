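"""File formats, parcel extraction, and the synthetic fixture subject.

Conventions: NIfTI-1 for images (4-D BOLD, 3-D masks and integer label
parcellations), whitespace/TSV text for motion parameters and tabular
outputs, JSON sidecars for parameters and provenance. All world coordinates
are NIfTI affine millimetres; voxel indices are 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .motion import MotionTrace
from .qc_subject import ParcelTimeSeries
from .simulate import HRFParams, SimParams, _zscore_rows, \
    generate_neural_events, hrf_kernel

__all__ = [
    "read_motion_params",
    "write_motion_params",
    "read_parcel_timeseries",
    "write_parcel_timeseries",
    "write_sidecar",
    "extract_parcel_timeseries",
    "make_fixture_subject",
]


def read_motion_params(
    path, tr: float = 3.0, degrees: bool = True, center=None
) -> MotionTrace:
    """Read a T x 6 whitespace/TSV motion file (tx ty tz in mm, rx ry rz).

    ``degrees=False`` declares radian rotation columns, converted to the
    package's degree convention on load.
    """
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 columns, got {arr.shape[1]} in {path}")
    if not degrees:
        arr = arr.copy()
        arr[:, 3:] = np.rad2deg(arr[:, 3:])
    return MotionTrace(params=arr, tr=tr, center=center)


def write_motion_params(path, trace: MotionTrace) -> None:
    np.savetxt(path, trace.params, delimiter="\t", fmt="%.8g")


def read_parcel_timeseries(path, tr: float = 3.0) -> ParcelTimeSeries:
    """Read a regions x time TSV (row index = region id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ParcelTimeSeries(
        data=df.to_numpy(float), region_ids=list(df.index), tr=tr
    )


def write_parcel_timeseries(path, ts: ParcelTimeSeries) -> None:
    pd.DataFrame(
        ts.data, index=pd.Index(ts.region_ids, name="region")
    ).to_csv(path, sep="\t", float_format="%.10g")


def write_sidecar(path, payload: dict) -> None:
    """Write a JSON provenance sidecar (parameters, conventions, version)."""
    from . import __version__

    payload = {"fetalqc_version": __version__, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    return str(o)


def _as_img(img):
    return img if isinstance(img, nib.spatialimages.SpatialImage) else nib.load(str(img))


def extract_parcel_timeseries(
    bold, parcellation, tr: float | None = None, resample: bool = False
) -> ParcelTimeSeries:
    """Region-mean time series and centroids from a 4-D BOLD + label image.

    The label image must share the BOLD grid (affines equal to 1e-4);
    with ``resample=True`` a nearest-neighbour resampling of the labels
    onto the BOLD grid is applied instead of rejecting. Region centroids
    are mean voxel coordinates mapped to mm through the affine. Empty
    regions are excluded with a warning.
    """
    bold_img = _as_img(bold)
    lab_img = _as_img(parcellation)
    data = np.asarray(bold_img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("BOLD image must be 4-D")
    labels = np.asarray(lab_img.dataobj)
    if not np.allclose(bold_img.affine, lab_img.affine, atol=1e-4) or \
            labels.shape != data.shape[:3]:
        if not resample:
            raise ValueError(
                "label image grid/affine does not match the BOLD image; "
                "pass resample=True to allow nearest-neighbour resampling"
            )
        from scipy.ndimage import affine_transform

        M = np.linalg.inv(lab_img.affine) @ bold_img.affine
        labels = affine_transform(
            labels.astype(float), M[:3, :3], M[:3, 3],
            output_shape=data.shape[:3], order=0,
        )
    labels = np.rint(labels).astype(int)
    if labels.min() < 0:
        raise ValueError("label ids must be nonnegative (0 = background)")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    flat = labels.ravel()
    T = data.shape[-1]
    vox = data.reshape(-1, T)
    series, kept, centroids = [], [], []
    ijk = np.indices(labels.shape).reshape(3, -1).T  # voxel coords, grid order
    A = bold_img.affine
    for rid in ids:
        sel = flat == rid
        n = int(sel.sum())
        if n == 0:  # cannot occur for ids from unique; kept for resampled grids
            continue
        series.append(vox[sel].mean(axis=0))
        kept.append(int(rid))
        c_vox = ijk[sel].mean(axis=0)
        centroids.append(A[:3, :3] @ c_vox + A[:3, 3])
    dropped = set(int(i) for i in np.unique(np.asarray(lab_img.dataobj))) - set(kept) - {0}
    if dropped:
        warnings.warn(f"regions with no voxels on the BOLD grid excluded: {sorted(dropped)}",
                      UserWarning, stacklevel=2)
    if tr is None:
        zooms = bold_img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return ParcelTimeSeries(
        data=np.vstack(series), region_ids=kept,
        centroids=np.vstack(centroids), tr=tr,
    )


def make_fixture_subject(
    params: SimParams | None = None,
    seed: int | None = None,
    shape: tuple[int, int, int] = (20, 10, 6),
    n_regions: int = 10,
    contaminated_fraction: float = 0.5,
    voxel_mm: float = 2.0,
    voxel_noise_sd: float = 0.05,
    out_dir=None,
) -> dict:
    """Build a small fully synthetic subject for end-to-end pipeline tests.

    A (20, 10, 6) grid holds a 5 x 2 arrangement of cortical block regions
    in the lower z slabs, plus one WM and one CSF slab. Half of the regions
    (the "contaminated set") share the episodic motion noise generated by
    the observation model; ground-truth corrupted edges are the pairs within
    that set. The motion file encodes a pure x-translation random walk whose
    step sizes equal ``fd_true``, so RMS framewise displacement recovers the
    planted series exactly. Deterministic under ``seed``.

    The default profile emulates a severely moving fetus — motion noise at
    twice the signal amplitude, sustained movement episodes of a few minutes
    over a 15-minute acquisition (300 volumes at TR = 3 s) — so that the
    planted corrupted set is reliably recoverable by the sliding-window
    statistic; milder profiles can be passed explicitly via ``params``.

    Returns a dict with in-memory objects (``bold``, ``labels``, ``masks``,
    ``motion``, ``fd_true``, ``truth_edges``, ``timeseries``); when
    ``out_dir`` is given the standard files are also written (NIfTI, TSV,
    JSON sidecar) and their paths returned under ``paths``.
    """
    if params is None:
        params = SimParams(
            n_obs=300, snr_phys=0.5, snr_scan=3.0,
            envelope_cutoff_hz=0.005, seed=seed,
        )
    elif seed is not None:
        from dataclasses import replace

        params = replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)
    T_obs = params.n_obs
    kernel = hrf_kernel(HRFParams(), dt=1.0 / params.nu_g)

    # latent signals per region
    from scipy.signal import fftconvolve

    ev = generate_neural_events(params, rng, n_series=n_regions).events.astype(bool)
    if params.prune_rate > 0:
        ev = ev & (rng.random(ev.shape) >= params.prune_rate)
    latent = fftconvolve(ev.astype(float), kernel[None, :], axes=-1)[:, : params.n_latent]

    # shared episodic noise -> contaminated half of the regions
    from .simulate import _downsample, _phys_noise

    noise = _phys_noise(rng, 1, params)[0]
    sig_rms = latent.std(axis=-1).mean()
    phys = noise * (sig_rms / params.snr_phys)
    n_cont = max(2, int(round(contaminated_fraction * n_regions)))
    contaminated = np.arange(n_cont)
    lat_obs = latent.copy()
    lat_obs[contaminated] += phys
    ds = _downsample(lat_obs, params.d, params.downsample)
    ds_rms = _downsample(latent, params.d, params.downsample).std(axis=-1).mean()
    ds = ds + rng.standard_normal(ds.shape) * (ds_rms / params.snr_scan)
    region_ts = _zscore_rows(ds)
    fd_true = np.abs(_downsample(phys, params.d, params.downsample))

    # ground-truth corrupted pairs, keyed by region label (labels are 1-based)
    truth_edges = [
        (int(a) + 1, int(b) + 1)
        for i, a in enumerate(contaminated)
        for b in contaminated[i + 1 :]
    ]

    # geometry: 5 x 2 cortical blocks in z slabs 0..3, WM slab z=4, CSF z=5
    nx, ny, nz = shape
    bx, by = nx // 5, ny // 2
    labels = np.zeros(shape, dtype=np.int16)
    for r in range(n_regions):
        gx, gy = r % 5, r // 5
        labels[gx * bx : (gx + 1) * bx, gy * by : (gy + 1) * by, : nz - 2] = r + 1
    wm = np.zeros(shape, bool)
    wm[:, :, nz - 2] = True
    csf = np.zeros(shape, bool)
    csf[:, :, nz - 1] = True
    brain = (labels > 0) | wm | csf

    bold = np.zeros(shape + (T_obs,), dtype=np.float32)
    for r in range(n_regions):
        sel = labels == r + 1
        bold[sel] = region_ts[r] + voxel_noise_sd * rng.standard_normal(
            (int(sel.sum()), T_obs)
        )
    # WM carries the motion noise (so aCompCor-style regressors can find it);
    # CSF is unstructured
    wm_sig = _zscore_rows(_downsample(phys, params.d, params.downsample)[None])[0]
    bold[wm] = wm_sig + voxel_noise_sd * rng.standard_normal((int(wm.sum()), T_obs))
    bold[csf] = voxel_noise_sd * rng.standard_normal((int(csf.sum()), T_obs))

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    bold_img = nib.Nifti1Image(bold, affine)
    bold_img.header.set_zooms((voxel_mm,) * 3 + (params.tr,))
    labels_img = nib.Nifti1Image(labels, affine)
    masks = {
        "brain": nib.Nifti1Image(brain.astype(np.uint8), affine),
        "wm": nib.Nifti1Image(wm.astype(np.uint8), affine),
        "csf": nib.Nifti1Image(csf.astype(np.uint8), affine),
    }

    # motion parameters: x-translation random walk with |step| = fd_true
    mot = np.zeros((T_obs, 6))
    signs = np.where(rng.random(T_obs) < 0.5, -1.0, 1.0)
    mot[:, 0] = np.cumsum(fd_true * signs)
    motion = MotionTrace(params=mot, tr=params.tr)

    ts = extract_parcel_timeseries(bold_img, labels_img, tr=params.tr)
    out = {
        "bold": bold_img,
        "labels": labels_img,
        "masks": masks,
        "motion": motion,
        "fd_true": fd_true,
        # signed observed-rate motion-noise course (the true shared nuisance
        # source; regressing it out is the oracle denoising strategy)
        "noise_obs": _downsample(phys, params.d, params.downsample),
        "truth_edges": truth_edges,
        "timeseries": ts,
        "params": params,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, img in [("bold", bold_img), ("labels", labels_img)] + [
            (f"mask_{k}", v) for k, v in masks.items()
        ]:
            p = out_dir / f"{name}.nii"
            nib.save(img, p)
            paths[name] = p
        paths["motion"] = out_dir / "motion.tsv"
        write_motion_params(paths["motion"], motion)
        paths["fd_true"] = out_dir / "fd_true.tsv"
        np.savetxt(paths["fd_true"], fd_true, delimiter="\t", fmt="%.10g")
        paths["timeseries"] = out_dir / "timeseries.tsv"
        write_parcel_timeseries(paths["timeseries"], ts)
        paths["truth"] = out_dir / "truth.json"
        Path(paths["truth"]).write_text(
            json.dumps({"truth_edges": truth_edges, "params": asdict(params)},
                       default=_json_default, indent=2)
        )
        paths["sidecar"] = out_dir / "provenance.json"
        write_sidecar(paths["sidecar"], {"params": asdict(params), "seed": params.seed})
        out["paths"] = paths
    return out
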
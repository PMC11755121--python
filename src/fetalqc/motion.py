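"""Framewise displacement and censoring from rigid-body motion parameters.

Framewise displacement (FD) summarises volume-to-volume head movement from
the six realignment parameters (three translations in mm, three rotations in
degrees). Because the fetal brain grows substantially over gestation, the
brain radius used to convert rotations into millimetres cannot be assumed
fixed across subjects: it is estimated per subject by least-squares sphere
fitting to brain-surface coordinates, and FD is the root-mean-square
displacement of points on (or in) the fitted brain under the relative rigid
transform between consecutive volumes.

Censoring flags come from two sources: volumes whose in-mask voxel
intensities contain an excess of 3-SD outliers, and volumes whose FD exceeds
a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "MotionTrace",
    "SphereFit",
    "CensorMask",
    "fit_sphere",
    "fibonacci_sphere",
    "rigid_transforms",
    "fd_series",
    "fd_power",
    "intensity_outlier_flags",
    "fd_censor_flags",
]


@dataclass
class MotionTrace:
    """Per-volume rigid-body realignment parameters.

    ``params`` is ``(T, 6)``: tx, ty, tz in mm, then rx, ry, rz in degrees.
    Rotations follow the extrinsic x-y-z convention and are applied about
    ``center`` (defaults to the origin of the coordinate frame).
    """

    params: NDArray[np.float64]
    tr: float = 1.0
    center: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"params must be (T, 6), got {self.params.shape}")
        if self.params.shape[0] < 2:
            raise ValueError("need at least 2 volumes for FD")
        if np.isnan(self.params).any():
            raise ValueError("motion parameters contain NaNs")
        if np.abs(self.params[:, 3:]).max() > 180.0:
            warnings.warn(
                "rotations exceed 180 deg; check that columns 4-6 are degrees",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class SphereFit:
    """Least-squares sphere: center (mm), radius (mm), RMS radial residual."""

    center: NDArray[np.float64]
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class CensorMask:
    """Per-volume keep flags with the reason for each exclusion.

    ``reason`` holds one of ``"none"``, ``"intensity"``, ``"fd"`` or
    ``"intensity+fd"`` per volume.
    """

    keep: NDArray[np.bool_]
    reason: NDArray[np.str_]

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.reason = np.asarray(self.reason)
        if self.keep.shape != self.reason.shape:
            raise ValueError("keep and reason must have the same length")

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    def __and__(self, other: "CensorMask") -> "CensorMask":
        """Combine two masks: a volume is censored if either flags it."""
        keep = self.keep & other.keep
        reason = np.array(
            [
                "+".join(sorted({a, b} - {"none"})) or "none"
                for a, b in zip(self.reason, other.reason)
            ]
        )
        return CensorMask(keep=keep, reason=reason)


def fit_sphere(points: NDArray[np.float64]) -> SphereFit:
    """Algebraic least-squares sphere fit to an ``(n, 3)`` point cloud.

    Expanding ``|p - c|^2 = r^2`` gives the linear system
    ``[2p, 1] @ [c, r^2 - |c|^2] = |p|^2``, solved by ordinary least
    squares. Exact on noiseless spherical data.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    n = points.shape[0]
    if n < 4:
        raise ValueError(f"sphere fit needs >= 4 points, got {n}")
    A = np.column_stack([2.0 * points, np.ones(n)])
    if np.linalg.matrix_rank(A) < 4:
        raise ValueError("degenerate (coplanar or coincident) points: sphere underdetermined")
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit collapsed to non-positive radius")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(points - center, axis=1) - radius
    return SphereFit(center=center, radius=radius, rms_residual=float(np.sqrt(np.mean(resid**2))))


def fibonacci_sphere(n: int, sphere: SphereFit) -> NDArray[np.float64]:
    """``n`` near-uniform deterministic points on the fitted sphere surface."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    pts = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    return sphere.center + sphere.radius * pts


def _euler_xyz(rx: float, ry: float, rz: float) -> NDArray[np.float64]:
    """Rotation matrix for extrinsic rotations about fixed x, then y, then z axes."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rigid_transforms(trace: MotionTrace) -> NDArray[np.float64]:
    """Per-volume homogeneous 4x4 transforms from the six parameters.

    Rotations are applied about ``trace.center`` (origin by default), then
    the translation is added.
    """
    c = np.zeros(3) if trace.center is None else np.asarray(trace.center, float)
    out = np.empty((trace.n_volumes, 4, 4))
    for i, (tx, ty, tz, rx, ry, rz) in enumerate(trace.params):
        R = _euler_xyz(*np.deg2rad([rx, ry, rz]))
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c - R @ c + np.array([tx, ty, tz])
        out[i] = M
    return out


def fd_series(
    trace: MotionTrace,
    mask_coords: NDArray[np.float64] | None = None,
    sphere: SphereFit | None = None,
    n_surface_points: int = 1000,
) -> NDArray[np.float64]:
    """RMS framewise displacement over brain points, length ``T`` (leading 0).

    For each consecutive volume pair the relative rigid transform
    ``M_t @ inv(M_{t-1})`` is applied to the supplied voxel coordinates
    (``mask_coords``, in mm) or, when a :class:`SphereFit` is given, to
    points sampled on the fitted sphere surface; FD is the root mean square
    of the per-point displacement magnitudes. A leading zero aligns the
    series with the volumes.
    """
    if (mask_coords is None) == (sphere is None):
        raise ValueError("supply exactly one of mask_coords or sphere")
    if sphere is not None:
        pts = fibonacci_sphere(n_surface_points, sphere)
    else:
        pts = np.asarray(mask_coords, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("mask_coords must be (n, 3)")
    M = rigid_transforms(trace)
    ph = np.column_stack([pts, np.ones(len(pts))])
    fd = np.zeros(trace.n_volumes)
    for t in range(1, trace.n_volumes):
        rel = M[t] @ np.linalg.inv(M[t - 1])
        disp = ph @ rel.T - ph
        fd[t] = np.sqrt(np.mean((disp[:, :3] ** 2).sum(axis=1)))
    return fd


def fd_power(trace: MotionTrace, radius: float = 50.0) -> NDArray[np.float64]:
    """Sum-of-absolute-parameter FD: ``|dt|_1 + radius * |dtheta|_1`` (rad).

    The classical scrubbing definition, provided for comparison with the
    RMS-over-voxels default.
    """
    d = np.diff(trace.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + radius * np.abs(np.deg2rad(d[:, 3:])).sum(axis=1)
    return np.concatenate([[0.0], fd])


def intensity_outlier_flags(
    bold: NDArray[np.float64],
    brain_mask: NDArray[np.bool_],
    sd_threshold: float = 3.0,
    volume_fraction: float = 0.05,
) -> CensorMask:
    """Censor volumes with an excess of intensity-outlier voxels.

    A voxel is an outlier in a volume when its intensity deviates from the
    centre of the other in-mask voxels by more than ``sd_threshold``
    standard deviations. The centre and spread are estimated robustly
    (median and 1.4826 x MAD, as in AFNI's outlier count) so that the
    outliers themselves do not mask the detection. A volume is censored
    when more than ``volume_fraction`` of in-mask voxels are outliers.
    """
    bold = np.asarray(bold, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if bold.ndim != 4:
        raise ValueError("bold must be 4-D (x, y, z, t)")
    if mask.shape != bold.shape[:3]:
        raise ValueError("mask shape must match the spatial grid of bold")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("brain mask is empty")
    if n < 3:
        raise ValueError("brain mask too small for outlier statistics")
    v = bold[mask, :]  # (n_voxels, T)
    med = np.median(v, axis=0)
    sigma = 1.4826 * np.median(np.abs(v - med), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.abs(v - med) > sd_threshold * sigma
    out &= sigma > 0
    frac = out.mean(axis=0)
    keep = frac <= volume_fraction
    reason = np.where(keep, "none", "intensity")
    return CensorMask(keep=keep, reason=reason)


def fd_censor_flags(fd: NDArray[np.float64], threshold: float) -> CensorMask:
    """Censor volumes whose FD exceeds ``threshold`` (mm)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    fd = np.asarray(fd, dtype=float)
    keep = fd <= threshold
    return CensorMask(keep=keep, reason=np.where(keep, "none", "fd"))
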
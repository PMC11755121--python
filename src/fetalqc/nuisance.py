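"""Nuisance-regression strategies and temporal filtering for fMRI denoising.

Implements the confound families commonly benchmarked for motion artifact
removal: head-motion parameter regressors and their Volterra-style expansion
(6HMP / 24HMP), tissue-mean physiological regressors (2Phys / 8Phys), global
signal regression and its expansions (GSR / 2GSR / 4GSR), anatomical and
temporal CompCor (principal components of noise-tissue or high-variance
voxels), and an ANATICOR-style local white-matter regressor. Strategies are
declared in a registry of atomic builders; composite names such as
``"aCompCor+6HMP"`` are parsed by splitting on ``+``.

Order of operations for denoising: nuisance regression first, then
demeaning/detrending and discrete-cosine high-pass filtering (0.008 Hz
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from sklearn.base import BaseEstimator, TransformerMixin

from .motion import CensorMask, MotionTrace

__all__ = [
    "DesignMatrix",
    "STRATEGIES",
    "build_design",
    "regress_out",
    "highpass",
    "NuisanceRegressor",
]


@dataclass
class DesignMatrix:
    """Confound regressors: ``(T, k)`` matrix with column names.

    ``per_region`` columns (e.g. localWM) apply only to the matching region
    series; ``regressors`` then has shape ``(T, n_regions)`` and column
    ``i`` is used when cleaning region ``i`` (alongside any shared columns
    stacked in ``regressors``/``names`` of a second DesignMatrix).
    """

    regressors: NDArray[np.float64]
    names: list[str]
    strategy: str
    per_region: bool = False

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] != len(self.names):
            raise ValueError("names must match the number of columns")
        zero = np.all(self.regressors == 0, axis=0)
        if zero.any() and not self.per_region:
            bad = [n for n, z in zip(self.names, zero) if z]
            raise ValueError(f"constant-zero regressor columns: {bad}")

    @property
    def n_columns(self) -> int:
        return self.regressors.shape[1]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.regressors)) if self.n_columns else 0


def _derivative(x: NDArray) -> NDArray:
    """Backward difference with first element 0 (keeps length T)."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def _expand24(p: NDArray) -> NDArray:
    d = _derivative(p)
    return np.column_stack([p, d, p**2, d**2])


def _mean_ts(bold: NDArray, mask: NDArray) -> NDArray:
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("tissue mask is empty")
    return bold[mask, :].mean(axis=0)


def _pca_components(vox_ts: NDArray, k: int) -> NDArray:
    """Top-k principal component time courses of a (n_voxels, T) matrix."""
    X = vox_ts - vox_ts.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = X / sd
    # PCs over time: SVD of (T, n_voxels)
    U, s, _ = np.linalg.svd(X.T, full_matrices=False)
    k = min(k, (s > 1e-12).sum())
    return U[:, :k] * s[:k]


def _hmp6(inputs: dict) -> tuple[NDArray, list[str]]:
    p = inputs["motion"].params
    return p.copy(), ["tx", "ty", "tz", "rx", "ry", "rz"]


def _hmp24(inputs: dict) -> tuple[NDArray, list[str]]:
    p = inputs["motion"].params
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = base + [f"d_{n}" for n in base] + [f"{n}_sq" for n in base] + [f"d_{n}_sq" for n in base]
    return _expand24(p), names


def _phys2(inputs: dict) -> tuple[NDArray, list[str]]:
    b, m = inputs["bold"], inputs["masks"]
    cols = np.column_stack([_mean_ts(b, m["wm"]), _mean_ts(b, m["csf"])])
    return cols, ["wm_mean", "csf_mean"]


def _phys8(inputs: dict) -> tuple[NDArray, list[str]]:
    p, names = _phys2(inputs)
    d = _derivative(p)
    out = np.column_stack([p, d, p**2, d**2])
    names = names + [f"d_{n}" for n in names] + [f"{n}_sq" for n in names] + [f"d_{n}_sq" for n in names]
    return out, names


def _gsr(inputs: dict, n_terms: int = 1) -> tuple[NDArray, list[str]]:
    g = _mean_ts(inputs["bold"], inputs["masks"]["brain"])
    cols = [g]
    names = ["global"]
    if n_terms >= 2:
        cols.append(_derivative(g))
        names.append("d_global")
    if n_terms >= 4:
        cols.append(g**2)
        cols.append(_derivative(g) ** 2)
        names += ["global_sq", "d_global_sq"]
    return np.column_stack(cols), names


def _acompcor(inputs: dict) -> tuple[NDArray, list[str]]:
    b, m = inputs["bold"], inputs["masks"]
    noise_mask = np.asarray(m["wm"], bool) | np.asarray(m["csf"], bool)
    if noise_mask.sum() == 0:
        raise ValueError("WM+CSF mask is empty")
    k = inputs.get("n_compcor", 5)
    pcs = _pca_components(b[noise_mask, :], k)
    return pcs, [f"acompcor_{i}" for i in range(pcs.shape[1])]


def _tcompcor(inputs: dict) -> tuple[NDArray, list[str]]:
    b = inputs["bold"]
    brain = np.asarray(inputs["masks"]["brain"], bool)
    if brain.sum() == 0:
        raise ValueError("brain mask is empty")
    frac = inputs.get("tcompcor_fraction", 0.02)
    v = b[brain, :]
    sd = v.std(axis=1)
    n_top = max(1, int(np.ceil(frac * len(sd))))
    top = np.argsort(sd)[-n_top:]
    k = inputs.get("n_compcor", 5)
    pcs = _pca_components(v[top, :], k)
    return pcs, [f"tcompcor_{i}" for i in range(pcs.shape[1])]


def _localwm(inputs: dict) -> tuple[NDArray, list[str]]:
    """ANATICOR-style regressor: per-region mean of eroded-WM voxels within
    ``localwm_radius_mm`` (default 25) of the region centroid."""
    from scipy.ndimage import binary_erosion

    b = inputs["bold"]
    wm = np.asarray(inputs["masks"]["wm"], bool)
    centroids = inputs.get("centroids")
    voxel_mm = inputs.get("voxel_coords_mm")
    if centroids is None or voxel_mm is None:
        raise ValueError("localWM requires region centroids and voxel coordinates")
    radius = inputs.get("localwm_radius_mm", 25.0)
    wm_eroded = binary_erosion(wm)
    if wm_eroded.sum() == 0:
        wm_eroded = wm  # tiny masks: fall back to the uneroded mask
    coords = voxel_mm  # (X*Y*Z, 3) in grid order
    flat_wm = wm_eroded.ravel()
    wm_xyz = coords[flat_wm]
    wm_ts = b.reshape(-1, b.shape[-1])[flat_wm]
    cols = []
    for c in centroids:
        near = np.linalg.norm(wm_xyz - c, axis=1) <= radius
        cols.append(wm_ts[near].mean(axis=0) if near.any() else np.zeros(b.shape[-1]))
    out = np.column_stack(cols)
    return out, [f"localwm_region_{i}" for i in range(out.shape[1])]


STRATEGIES: dict[str, dict] = {
    "none": {"builders": [], "per_region": False},
    "6HMP": {"builders": [_hmp6], "per_region": False},
    "24HMP": {"builders": [_hmp24], "per_region": False},
    "2Phys": {"builders": [_phys2], "per_region": False},
    "8Phys": {"builders": [_phys8], "per_region": False},
    "GSR": {"builders": [lambda i: _gsr(i, 1)], "per_region": False},
    "2GSR": {"builders": [lambda i: _gsr(i, 2)], "per_region": False},
    "4GSR": {"builders": [lambda i: _gsr(i, 4)], "per_region": False},
    "aCompCor": {"builders": [_acompcor], "per_region": False},
    "tCompCor": {"builders": [_tcompcor], "per_region": False},
    "localWM": {"builders": [_localwm], "per_region": True},
}


def register_strategy(name: str, builder, per_region: bool = False) -> None:
    """Add an atomic strategy to the registry (used by config files)."""
    STRATEGIES[name] = {"builders": [builder], "per_region": per_region}


def build_design(
    strategy: str,
    inputs: dict,
) -> DesignMatrix:
    """Build the confound design matrix for a named strategy.

    ``strategy`` is an atomic registry name or a ``+``-joined composite
    (e.g. ``"aCompCor+6HMP"``, ``"4GSR+8Phys+24HMP"``). A trailing
    ``"+censor"`` component is accepted and ignored here (censoring is
    applied at regression time via a :class:`~fetalqc.motion.CensorMask`).

    ``inputs`` may provide: ``motion`` (:class:`MotionTrace`), ``bold``
    (4-D array), ``masks`` (dict with ``brain``/``wm``/``csf`` boolean
    arrays), ``centroids``/``voxel_coords_mm`` (for localWM), and the
    options ``n_compcor``, ``tcompcor_fraction``, ``localwm_radius_mm``.
    """
    parts = [p for p in strategy.split("+") if p != "censor"]
    unknown = [p for p in parts if p not in STRATEGIES]
    if unknown:
        raise ValueError(
            f"unknown strategy component(s) {unknown}; registered: {sorted(STRATEGIES)}"
        )
    cols, names = [], []
    per_region_cols = None
    per_region_names: list[str] = []
    for part in parts:
        for builder in STRATEGIES[part]["builders"]:
            c, n = builder(inputs)
            if STRATEGIES[part]["per_region"]:
                per_region_cols = c
                per_region_names = n
            else:
                cols.append(np.atleast_2d(c.T).T if c.ndim == 1 else c)
                names.extend(n)
    if per_region_cols is not None:
        if cols:
            raise ValueError(
                "localWM cannot be combined with shared regressors in a single "
                "DesignMatrix; build and apply them separately"
            )
        return DesignMatrix(per_region_cols, per_region_names, strategy, per_region=True)
    if not cols:
        T = _infer_T(inputs)
        return DesignMatrix(np.empty((T, 0)), [], strategy)
    M = np.column_stack(cols)
    # drop constant-zero columns (e.g. motionless axes) rather than carry
    # degenerate regressors
    nonzero = ~np.all(M == 0, axis=0)
    if not nonzero.all():
        dropped = [n for n, keep in zip(names, nonzero) if not keep]
        warnings.warn(f"dropping constant-zero regressors: {dropped}",
                      UserWarning, stacklevel=2)
        M = M[:, nonzero]
        names = [n for n, keep in zip(names, nonzero) if keep]
    return DesignMatrix(M, names, strategy)


def _infer_T(inputs: dict) -> int:
    if inputs.get("motion") is not None:
        return inputs["motion"].n_volumes
    if inputs.get("bold") is not None:
        return inputs["bold"].shape[-1]
    if inputs.get("n_timepoints") is not None:
        return int(inputs["n_timepoints"])
    raise ValueError("cannot infer series length for an empty design")


def regress_out(
    ts: NDArray[np.float64],
    design: DesignMatrix,
    censor: CensorMask | None = None,
) -> NDArray[np.float64]:
    """OLS residuals of ``ts`` against the design columns.

    ``ts`` is ``(T,)`` or ``(T, n_series)``. Censored frames are excluded
    from the fit and dropped from the output when a censor mask is given.
    The fit includes an implicit intercept (series and regressors are
    demeaned over the retained frames), so residuals are demeaned and
    uncorrelated with every design column on those frames.
    """
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    Y = ts[:, None] if one_d else ts
    T = Y.shape[0]
    X = design.regressors
    if X.shape[0] != T:
        raise ValueError(f"design has {X.shape[0]} rows, series has {T}")
    keep = np.ones(T, dtype=bool) if censor is None else censor.keep
    if keep.shape[0] != T:
        raise ValueError("censor mask length must match the series")
    n_keep = int(keep.sum())
    if design.per_region:
        if Y.shape[1] != X.shape[1]:
            raise ValueError(
                "per-region design needs one column per series "
                f"({X.shape[1]} columns, {Y.shape[1]} series)"
            )
        res = np.empty((n_keep, Y.shape[1]))
        for j in range(Y.shape[1]):
            col = X[keep, j : j + 1]
            yj = Y[keep, j] - Y[keep, j].mean()
            if not col.any():  # region with no local-WM voxels in range
                res[:, j] = yj
            else:
                colc = col - col.mean()
                beta, *_ = np.linalg.lstsq(colc, yj, rcond=None)
                res[:, j] = yj - (colc @ beta)
        out = res
    else:
        if X.shape[1] >= n_keep and X.shape[1] > 0:
            raise ValueError(
                f"{X.shape[1]} regressors but only {n_keep} retained frames"
            )
        Xk = X[keep]
        if X.shape[1] and np.linalg.matrix_rank(Xk) < X.shape[1]:
            warnings.warn(
                "rank-deficient design; fitting via pseudoinverse",
                UserWarning,
                stacklevel=2,
            )
        Yk = Y[keep] - Y[keep].mean(axis=0)
        if X.shape[1] == 0:
            out = Yk
        else:
            Xc = Xk - Xk.mean(axis=0)
            beta = np.linalg.pinv(Xc) @ Yk
            out = Yk - Xc @ beta
    if censor is None:
        pass  # all frames retained; output aligns with input
    return out[:, 0] if one_d else out


def dct_basis(T: int, tr: float, cutoff: float) -> NDArray[np.float64]:
    """Discrete-cosine drift basis: columns with frequency below ``cutoff``.

    Basis function k (k >= 1) is ``cos(pi * k * (2t + 1) / (2T))`` with
    frequency ``k / (2 * T * tr)`` Hz; the constant term is excluded.
    """
    K = int(np.floor(2.0 * T * tr * cutoff))
    t = np.arange(T)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * T)) for k in range(1, K + 1)]
    return np.column_stack(cols) if cols else np.empty((T, 0))


def highpass(
    ts: NDArray[np.float64], cutoff: float, tr: float
) -> NDArray[np.float64]:
    """Demean, linearly detrend, then DCT-basis high-pass filter.

    Drift components with frequency below ``cutoff`` Hz are regressed out
    using a discrete-cosine basis — deterministic and edge-safe for short
    series. ``cutoff`` must lie below the Nyquist frequency ``1/(2 tr)``.
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[0]
    if T < 3:
        raise ValueError("series too short to filter (need >= 3 samples)")
    if cutoff >= 0.5 / tr:
        raise ValueError(f"cutoff {cutoff} Hz is not below Nyquist {0.5 / tr:.4f} Hz")
    one_d = ts.ndim == 1
    Y = ts[:, None] if one_d else ts
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t - t.mean()])
    B = dct_basis(T, tr, cutoff)
    X = np.column_stack([X, B])
    beta = np.linalg.pinv(X) @ Y
    out = Y - X @ beta
    return out[:, 0] if one_d else out


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying a named denoising strategy.

    ``fit`` builds the confound design from the side inputs (motion trace,
    4-D BOLD, tissue masks); ``transform`` returns OLS residuals of the
    region-by-time input, optionally followed by high-pass filtering.

    Parameters
    ----------
    strategy : str
        Registry name, possibly composite (``"aCompCor+6HMP"``) and/or with
        a ``"+censor"`` suffix (censored frames are dropped).
    highpass_hz : float or None
        High-pass cutoff applied after regression (None to skip).
    tr : float
        Repetition time in seconds (needed for the high-pass filter).
    n_compcor : int
        Number of CompCor components.
    tcompcor_fraction : float
        Fraction of highest-temporal-variance voxels used by tCompCor.
    localwm_radius_mm : float
        Neighbourhood radius of the local white-matter regressor.
    """

    def __init__(
        self,
        strategy: str = "none",
        highpass_hz: float | None = 0.008,
        tr: float = 3.0,
        n_compcor: int = 5,
        tcompcor_fraction: float = 0.02,
        localwm_radius_mm: float = 25.0,
    ):
        self.strategy = strategy
        self.highpass_hz = highpass_hz
        self.tr = tr
        self.n_compcor = n_compcor
        self.tcompcor_fraction = tcompcor_fraction
        self.localwm_radius_mm = localwm_radius_mm

    def fit(self, X, y=None, *, motion=None, bold=None, masks=None,
            centroids=None, voxel_coords_mm=None, censor=None):
        """Build the design matrix. ``X`` is the (T, n_regions) series."""
        X = np.asarray(X, dtype=float)
        inputs = {
            "motion": motion,
            "bold": bold,
            "masks": masks,
            "centroids": centroids,
            "voxel_coords_mm": voxel_coords_mm,
            "n_compcor": self.n_compcor,
            "tcompcor_fraction": self.tcompcor_fraction,
            "localwm_radius_mm": self.localwm_radius_mm,
            "n_timepoints": X.shape[0] if X.ndim >= 1 else None,
        }
        self.design_ = build_design(self.strategy, inputs)
        self.censor_ = censor if "censor" in self.strategy.split("+") else None
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X):
        """Residualise and (optionally) high-pass the series."""
        res = regress_out(np.asarray(X, float), self.design_, self.censor_)
        if self.highpass_hz is not None:
            res = highpass(res, self.highpass_hz, self.tr)
        return res
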
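"""Subject-level detection of motion-corrupted functional connections.

For every pair of brain regions the method computes a *time-varying*
functional connectivity series (Pearson correlation within a sliding
window), the window-averaged framewise displacement over the same windows,
and the Pearson correlation ``r`` between the two resulting series. A
connection whose ``r`` is significant against a null model is flagged as
motion corrupted.

Two null models are available:

* ``parametric`` — the t statistic ``t = r * sqrt(L - 2) / sqrt(1 - r^2)``
  referred to a Student t distribution with ``L - 2`` degrees of freedom,
  where ``L`` is the number of window positions. Valid when the windowed
  samples are serially independent; with heavily overlapping windows it is
  anticonservative, so it is retained mainly for simulation work and for
  calibration checks on independent inputs.
* ``surrogate`` (default) — phase-randomisation: surrogate FD series are
  built from the amplitude spectrum of the real FD with uniformly random
  phases (Hermitian-symmetric, so surrogates are real and preserve the
  amplitude spectrum exactly), the full window-average-and-correlate
  procedure is rerun per surrogate, and a two-sided empirical p-value with
  add-one correction is returned. This null preserves the autocorrelation
  of the motion series and stays calibrated where the parametric test does
  not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats as _stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ParcelTimeSeries",
    "WindowSpec",
    "EdgeQC",
    "SubjectQCReport",
    "sliding_fc",
    "sliding_fd",
    "fcfd_test",
    "surrogate_null",
    "assess_subject",
    "SubjectMotionQC",
]


@dataclass
class ParcelTimeSeries:
    """Region-averaged BOLD series: ``data`` is ``(n_regions, T)``.

    ``centroids`` (n_regions, 3; mm, same space as the FD computation) are
    optional and enable distance-dependence summaries.
    """

    data: NDArray[np.float64]
    region_ids: list | None = None
    centroids: NDArray[np.float64] | None = None
    tr: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.region_ids is None:
            self.region_ids = list(range(self.data.shape[0]))
        if len(self.region_ids) != self.data.shape[0]:
            raise ValueError("region_ids must match the number of rows")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (self.data.shape[0], 3):
                raise ValueError("centroids must be (n_regions, 3)")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width and stride in TR units."""

    width_tr: int = 46
    stride: int = 1

    def __post_init__(self) -> None:
        if self.width_tr < 3:
            raise ValueError("window width must be >= 3 TR")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def n_windows(self, T: int) -> int:
        if self.width_tr > T:
            raise ValueError(f"window ({self.width_tr}) longer than series ({T})")
        return (T - self.width_tr) // self.stride + 1


@dataclass
class EdgeQC:
    """QC result for one region pair."""

    edge: tuple
    cc_series: NDArray[np.float64]
    fd_series_w: NDArray[np.float64]
    r: float
    t_stat: float
    p_param: float
    p_surr: float | None
    corrupted: bool
    distance: float | None = None


@dataclass
class SubjectQCReport:
    """Subject-level summary of motion-corrupted connections."""

    edges: list[EdgeQC]
    frac_corrupted: float
    median_abs_r: float
    distance_dependence_rho: float | None
    alpha: float
    correction: str
    n_undefined: int = 0
    fd_degenerate: bool = False
    region_counts: dict | None = None


def _window_view(x: NDArray, width: int, stride: int) -> NDArray:
    """(..., T) -> (..., L, width) sliding windows (copy-free)."""
    v = np.lib.stride_tricks.sliding_window_view(x, width, axis=-1)
    return v[..., ::stride, :]


def sliding_fc(
    x: NDArray[np.float64],
    y: NDArray[np.float64],
    win: WindowSpec = WindowSpec(),
) -> NDArray[np.float64]:
    """Windowed Pearson correlation of two series; length ``L`` output.

    Windows with zero within-window variance in either series yield NaN
    (propagated and excluded downstream with a count).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    win.n_windows(x.shape[0])  # validates width <= T
    xv = _window_view(x, win.width_tr, win.stride)
    yv = _window_view(y, win.width_tr, win.stride)
    xm = xv - xv.mean(axis=-1, keepdims=True)
    ym = yv - yv.mean(axis=-1, keepdims=True)
    num = (xm * ym).sum(axis=-1)
    den = np.sqrt((xm**2).sum(axis=-1) * (ym**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = num / den
    cc[den == 0] = np.nan
    return cc


def sliding_fd(
    fd: NDArray[np.float64], win: WindowSpec = WindowSpec()
) -> NDArray[np.float64]:
    """Window means of the FD series over the same sliding windows."""
    fd = np.asarray(fd, dtype=float)
    return _window_view(fd, win.width_tr, win.stride).mean(axis=-1)


def fcfd_test(
    cc_series: NDArray[np.float64], fd_series_w: NDArray[np.float64]
) -> tuple[float, float, float]:
    """Correlation between windowed FC and windowed FD with a parametric p.

    Returns ``(r, t, p)`` with ``t = r sqrt(L - 2) / sqrt(1 - r^2)`` and a
    two-sided p from Student's t with ``L - 2`` degrees of freedom, ``L``
    being the number of (finite) window positions. ``|r| = 1`` returns
    ``p = 0`` with an infinite t.
    """
    cc = np.asarray(cc_series, dtype=float)
    fdw = np.asarray(fd_series_w, dtype=float)
    if cc.shape != fdw.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(cc) & np.isfinite(fdw)
    cc, fdw = cc[ok], fdw[ok]
    L = cc.shape[0]
    if L < 4:
        raise ValueError(f"need >= 4 finite windows, got {L}")
    if cc.std() == 0 or fdw.std() == 0:
        return np.nan, np.nan, np.nan
    r = float(np.corrcoef(cc, fdw)[0, 1])
    df = L - 2
    if abs(r) >= 1.0:
        return float(np.sign(r)), float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * _stats.t.sf(abs(t), df)
    return r, float(t), float(p)


def phase_randomize(
    x: NDArray[np.float64], n_surrogates: int, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Surrogates preserving the amplitude spectrum of ``x`` exactly.

    Uniform random phases are imposed on the rFFT coefficients (DC — and
    Nyquist for even length — kept real), so each surrogate is a real
    series with the same amplitude spectrum as the input.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    amp = np.abs(np.fft.rfft(x))
    nf = amp.shape[-1]
    ph = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, nf))
    ph[:, 0] = 0.0
    if T % 2 == 0:
        ph[:, -1] = 0.0
    return np.fft.irfft(amp[None, :] * np.exp(1j * ph), T, axis=-1)


def surrogate_null(
    fd: NDArray[np.float64],
    cc_source: NDArray[np.float64],
    win: WindowSpec = WindowSpec(),
    n_surrogates: int = 1000,
    seed: int | np.random.Generator | None = None,
    randomize: str = "fd",
) -> tuple[NDArray[np.float64], float]:
    """Null distribution of the FC-FD correlation via phase randomisation.

    Each surrogate FD preserves the amplitude spectrum of the real FD; the
    entire procedure (window-averaging, correlating against the subject's
    windowed-FC series ``cc_source``) is rerun per surrogate. Returns the
    null ``r`` values and the two-sided add-one empirical p-value
    ``(1 + #{|r_null| >= |r_obs|}) / (n_surrogates + 1)``.

    ``randomize="both"`` additionally phase-randomises the windowed FC
    series (conditioning on neither observed series); the default
    randomises FD only.
    """
    if n_surrogates < 100:
        warnings.warn(
            "fewer than 100 surrogates gives an unstable null tail",
            UserWarning,
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fd = np.asarray(fd, dtype=float)
    cc = np.asarray(cc_source, dtype=float)
    fdw_obs = sliding_fd(fd, win)
    r_obs, _, _ = fcfd_test(cc, fdw_obs)
    surr = phase_randomize(fd, n_surrogates, rng)
    fdw = _window_view(surr, win.width_tr, win.stride).mean(axis=-1)
    if randomize == "both":
        cc_s = phase_randomize(cc, n_surrogates, rng)
    elif randomize == "fd":
        cc_s = np.broadcast_to(cc, (n_surrogates, cc.shape[0]))
    else:
        raise ValueError("randomize must be 'fd' or 'both'")
    r_null = _pearson_rows(cc_s, fdw)
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (n_surrogates + 1.0)
    return r_null, float(p)


def _pearson_rows(a: NDArray, b: NDArray) -> NDArray:
    """Row-wise Pearson correlation of two (n, L) arrays."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    den = np.sqrt((a**2).sum(axis=-1) * (b**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a * b).sum(axis=-1) / den


class SubjectMotionQC(BaseEstimator):
    """Estimator flagging motion-corrupted connections in one subject.

    Parameters
    ----------
    window : int
        Sliding-window width in TR (46 by default, i.e. 138 s at TR = 3 s;
        with 96 time points this yields L = 51 window positions).
    stride : int
        Window stride in TR.
    alpha : float
        Significance level.
    null_mode : str
        ``"surrogate"`` (default) or ``"parametric"``.
    n_surrogates : int
        Number of phase-randomised FD surrogates.
    correction : str
        ``"none"`` (default, matching uncorrected reporting) or ``"fdr"``
        (Benjamini-Hochberg).
    randomize : str
        Which series the surrogates randomise: ``"fd"`` or ``"both"``.
    random_state : int or None
        Seed for surrogate generation.

    Attributes
    ----------
    edges_ : pandas.DataFrame
        One row per region pair: region_i, region_j, distance_mm, r, t,
        p, corrupted.
    frac_corrupted_ : float
    median_abs_r_ : float
    distance_dependence_rho_ : float or None
        Spearman rank correlation between edge ``r`` values and
        inter-centroid Euclidean distance.
    region_counts_ : pandas.Series
        Number of significant edges incident to each region (uncertainty
        map values).
    """

    def __init__(
        self,
        window: int = 46,
        stride: int = 1,
        alpha: float = 0.05,
        null_mode: str = "surrogate",
        n_surrogates: int = 1000,
        correction: str = "none",
        randomize: str = "fd",
        random_state: int | None = None,
    ):
        self.window = window
        self.stride = stride
        self.alpha = alpha
        self.null_mode = null_mode
        self.n_surrogates = n_surrogates
        self.correction = correction
        self.randomize = randomize
        self.random_state = random_state

    def fit(self, X, y=None, *, fd=None, centroids=None, region_ids=None):
        """Assess every region pair of a subject.

        ``X`` is ``(T, n_regions)`` (sklearn sample-by-feature convention)
        or a :class:`ParcelTimeSeries`. ``fd`` is the length-T framewise
        displacement series (required).
        """
        if isinstance(X, ParcelTimeSeries):
            if centroids is None:
                centroids = X.centroids
            if region_ids is None:
                region_ids = X.region_ids
            data = X.data  # (n_regions, T)
        else:
            data = np.asarray(X, dtype=float).T
        if fd is None:
            raise ValueError("fd (framewise displacement series) is required")
        fd = np.asarray(fd, dtype=float)
        n_regions, T = data.shape
        if fd.shape[0] != T:
            raise ValueError(f"fd length {fd.shape[0]} != series length {T}")
        if region_ids is None:
            region_ids = list(range(n_regions))
        win = WindowSpec(self.window, self.stride)
        rng = np.random.default_rng(self.random_state)

        # exclude zero-variance regions up front
        sd = data.std(axis=1)
        self.excluded_regions_ = [region_ids[i] for i in np.flatnonzero(sd == 0)]
        active = np.flatnonzero(sd > 0)

        self.fd_degenerate_ = bool(np.ptp(fd) == 0)
        fdw = sliding_fd(fd, win)
        L = fdw.shape[0]

        # windowed FC for all edges, vectorised over edges
        ii, jj = np.triu_indices(len(active), k=1)
        gi, gj = active[ii], active[jj]
        xv = _window_view(data, win.width_tr, win.stride)  # (n_regions, L, w)
        xm = xv - xv.mean(axis=-1, keepdims=True)
        ss = np.sqrt((xm**2).sum(axis=-1))  # (n_regions, L)
        num = (xm[gi] * xm[gj]).sum(axis=-1)
        den = ss[gi] * ss[gj]
        with np.errstate(invalid="ignore", divide="ignore"):
            cc_all = num / den  # (n_edges, L)
        cc_all[den == 0] = np.nan

        undef_windows = int(np.isnan(cc_all).sum())
        r, t, p_param = _edgewise_parametric(cc_all, fdw)

        p_surr = None
        if self.null_mode == "surrogate" and not self.fd_degenerate_:
            p_surr = _edgewise_surrogate_p(
                fd, cc_all, r, win, self.n_surrogates, rng, self.randomize
            )
            p_used = p_surr
        else:
            p_used = p_param
        finite = np.isfinite(p_used)
        corrupted = np.zeros(len(r), dtype=bool)
        if self.fd_degenerate_:
            p_used = np.full(len(r), np.nan)
        elif self.correction == "fdr":
            if finite.any():
                corrupted[finite] = multipletests(
                    p_used[finite], alpha=self.alpha, method="fdr_bh"
                )[0]
        elif self.correction == "none":
            corrupted[finite] = p_used[finite] < self.alpha
        else:
            raise ValueError("correction must be 'none' or 'fdr'")

        dist = np.full(len(r), np.nan)
        if centroids is not None:
            centroids = np.asarray(centroids, dtype=float)
            dist = np.linalg.norm(centroids[gi] - centroids[gj], axis=1)

        self.edges_ = pd.DataFrame(
            {
                "region_i": [region_ids[k] for k in gi],
                "region_j": [region_ids[k] for k in gj],
                "distance_mm": dist,
                "r": r,
                "t": t,
                "p_param": p_param,
                "p": p_used,
                "corrupted": corrupted,
            }
        )
        self.cc_series_ = cc_all
        self.fd_series_w_ = fdw
        self.n_windows_ = L
        self.n_undefined_ = undef_windows
        n_def = int(np.isfinite(r).sum())
        self.frac_corrupted_ = float(corrupted.sum() / len(r)) if len(r) else np.nan
        self.median_abs_r_ = float(np.nanmedian(np.abs(r))) if n_def else np.nan
        if centroids is not None and n_def >= 3:
            ok = np.isfinite(r) & np.isfinite(dist)
            rho, _ = _stats.spearmanr(dist[ok], r[ok])
            self.distance_dependence_rho_ = float(rho)
        else:
            self.distance_dependence_rho_ = None
        counts = {}
        for rid in region_ids:
            counts[rid] = 0
        for (a, b), c in zip(
            zip(self.edges_["region_i"], self.edges_["region_j"]), corrupted
        ):
            if c:
                counts[a] += 1
                counts[b] += 1
        self.region_counts_ = pd.Series(counts, name="n_corrupted_edges")
        return self

    def to_report(self) -> SubjectQCReport:
        """Package fitted attributes into a :class:`SubjectQCReport`."""
        edges = []
        for k, row in self.edges_.iterrows():
            edges.append(
                EdgeQC(
                    edge=(row["region_i"], row["region_j"]),
                    cc_series=self.cc_series_[k],
                    fd_series_w=self.fd_series_w_,
                    r=row["r"],
                    t_stat=row["t"],
                    p_param=row["p_param"],
                    p_surr=row["p"] if self.null_mode == "surrogate" else None,
                    corrupted=bool(row["corrupted"]),
                    distance=row["distance_mm"],
                )
            )
        return SubjectQCReport(
            edges=edges,
            frac_corrupted=self.frac_corrupted_,
            median_abs_r=self.median_abs_r_,
            distance_dependence_rho=self.distance_dependence_rho_,
            alpha=self.alpha,
            correction=self.correction,
            n_undefined=self.n_undefined_,
            fd_degenerate=self.fd_degenerate_,
            region_counts=self.region_counts_.to_dict(),
        )


def _edgewise_parametric(cc_all: NDArray, fdw: NDArray):
    """Vectorised (r, t, p) per edge against one windowed-FD series."""
    L = fdw.shape[0]
    fin = np.isfinite(cc_all)
    all_def = fin.all(axis=1)
    r = np.full(cc_all.shape[0], np.nan)
    # edges with complete windows: vectorised
    if all_def.any():
        r[all_def] = _pearson_rows(cc_all[all_def], np.broadcast_to(fdw, cc_all[all_def].shape))
    # edges with NaN windows: per-edge on finite positions
    for k in np.flatnonzero(~all_def):
        ok = fin[k]
        if ok.sum() >= 4 and cc_all[k, ok].std() > 0 and fdw[ok].std() > 0:
            r[k] = np.corrcoef(cc_all[k, ok], fdw[ok])[0, 1]
    df = L - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
        p = 2.0 * _stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    if fdw.std() == 0:
        r[:] = np.nan
        t = np.full_like(r, np.nan)
        p = np.full_like(r, np.nan)
    return r, t, p


def _edgewise_surrogate_p(
    fd, cc_all, r_obs, win, n_surrogates, rng, randomize
) -> NDArray:
    """Add-one two-sided empirical p per edge, sharing one surrogate set.

    All edges of a subject share the same FD series, so a single batch of
    phase-randomised FD surrogates serves every edge; the per-surrogate
    windowed means are correlated against each edge's windowed-FC series
    by one standardised matrix product.
    """
    surr = phase_randomize(np.asarray(fd, float), n_surrogates, rng)
    fdw_s = _window_view(surr, win.width_tr, win.stride).mean(axis=-1)  # (S, L)
    S = fdw_s - fdw_s.mean(axis=1, keepdims=True)
    S /= np.linalg.norm(S, axis=1, keepdims=True)
    p = np.full(cc_all.shape[0], np.nan)
    fin = np.isfinite(cc_all).all(axis=1)
    C = cc_all[fin] - cc_all[fin].mean(axis=1, keepdims=True)
    norm = np.linalg.norm(C, axis=1, keepdims=True)
    norm[norm == 0] = np.inf
    C /= norm
    if randomize == "both":
        # per-edge randomised cc series: heavier; loop in blocks over edges
        pv = np.empty(C.shape[0])
        idx = np.flatnonzero(fin)
        for n_at, k in enumerate(idx):
            cs = phase_randomize(cc_all[k], n_surrogates, rng)
            cs = cs - cs.mean(axis=1, keepdims=True)
            cs /= np.linalg.norm(cs, axis=1, keepdims=True)
            rn = (cs * S).sum(axis=1)  # surrogate i of cc against surrogate i of fd
            pv[n_at] = (1 + np.sum(np.abs(rn) >= abs(r_obs[k]))) / (n_surrogates + 1)
        p[fin] = pv
        return p
    r_null = C @ S.T  # (n_edges_fin, S)
    exceed = (np.abs(r_null) >= np.abs(r_obs[fin])[:, None]).sum(axis=1)
    p[fin] = (1.0 + exceed) / (n_surrogates + 1.0)
    return p


def evaluate_simulated_pairs(
    x: NDArray[np.float64],
    y: NDArray[np.float64],
    fd: NDArray[np.float64],
    win: WindowSpec = WindowSpec(),
    n_surrogates: int = 1000,
    seed: int | None = None,
    chunk: int = 250,
) -> pd.DataFrame:
    """Apply the FC-FD statistic to a batch of simulated signal pairs.

    ``x``, ``y`` and ``fd`` are ``(n_pairs, T)``; each pair has its own
    ground-truth FD series, so surrogates are generated per pair (in
    vectorised chunks). Returns one row per pair with the windowed FC-FD
    correlation ``r``, the parametric p-value ``p_param``, the
    phase-randomisation p-value ``p_surr``, and the full-series observed
    connectivity ``fc``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fd = np.asarray(fd, float)
    if not (x.shape == y.shape == fd.shape) or x.ndim != 2:
        raise ValueError("x, y, fd must share shape (n_pairs, T)")
    n_pairs, T = x.shape
    rng = np.random.default_rng(seed)
    L = win.n_windows(T)
    w, s = win.width_tr, win.stride

    xv = _window_view(x, w, s)
    yv = _window_view(y, w, s)
    xm = xv - xv.mean(-1, keepdims=True)
    ym = yv - yv.mean(-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (xm * ym).sum(-1) / np.sqrt(
            (xm**2).sum(-1) * (ym**2).sum(-1)
        )  # (n_pairs, L)
    fdw = _window_view(fd, w, s).mean(-1)
    r = _pearson_rows(cc, fdw)
    df = L - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p_param = 2.0 * _stats.t.sf(np.abs(t), df)
    fc = _pearson_rows(x, y)

    p_surr = np.empty(n_pairs)
    nf = T // 2 + 1
    for i0 in range(0, n_pairs, chunk):
        nb = min(chunk, n_pairs - i0)
        amp = np.abs(np.fft.rfft(fd[i0 : i0 + nb], axis=-1))
        ph = rng.uniform(0, 2 * np.pi, (nb, n_surrogates, nf))
        ph[..., 0] = 0.0
        if T % 2 == 0:
            ph[..., -1] = 0.0
        surr = np.fft.irfft(amp[:, None, :] * np.exp(1j * ph), T, axis=-1)
        fdw_s = _window_view(surr.reshape(-1, T), w, s).mean(-1).reshape(nb, n_surrogates, L)
        r_null = _pearson_rows(fdw_s, cc[i0 : i0 + nb, None, :])
        exceed = (np.abs(r_null) >= np.abs(r[i0 : i0 + nb])[:, None]).sum(-1)
        p_surr[i0 : i0 + nb] = (1.0 + exceed) / (n_surrogates + 1.0)

    return pd.DataFrame({"r": r, "t": t, "p_param": p_param, "p_surr": p_surr, "fc": fc})


def assess_subject(
    ts: ParcelTimeSeries,
    fd: NDArray[np.float64],
    win: WindowSpec = WindowSpec(),
    alpha: float = 0.05,
    null_mode: str = "surrogate",
    correction: str = "none",
    n_surrogates: int = 1000,
    seed: int | None = None,
) -> SubjectQCReport:
    """Functional wrapper over :class:`SubjectMotionQC` returning a report."""
    qc = SubjectMotionQC(
        window=win.width_tr,
        stride=win.stride,
        alpha=alpha,
        null_mode=null_mode,
        n_surrogates=n_surrogates,
        correction=correction,
        random_state=seed,
    )
    qc.fit(ts, fd=fd)
    return qc.to_report()
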
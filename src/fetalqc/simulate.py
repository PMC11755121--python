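"""Generative model of motion-corrupted resting-state BOLD signal pairs.

The model produces pairs of observed BOLD time series with a known latent
neural ground truth and a known motion (framewise-displacement) proxy, so
that motion-QC statistics can be validated against a controlled truth.

Generation proceeds in two stages:

1. *Neural stage* — latent neural events are a binary sequence sampled from
   a two-state first-order Markov chain at rate ``nu_g`` Hz with a given
   stationary activity probability. Convolution with a canonical double-gamma
   hemodynamic response function (HRF) yields the noiseless "ideal" BOLD
   signal at the latent rate. Correlated neural activity between signals is
   imposed by mixing ideal signals with the Cholesky factor of a target
   correlation matrix.

2. *Observation stage* — a chain of mappings turns the ideal signal into the
   acquired one: (i) event pruning (each active latent bin is independently
   deleted with probability ``prune_rate`` in the observed branch only),
   (ii) additive physiological/motion noise shared by both signals of a pair,
   scaled so that the signal-to-noise amplitude (RMS) ratio equals
   ``snr_phys``, (iii) temporal downsampling by the integer factor
   ``d = nu_g / nu_o`` to ``n_obs`` points (block averaging by default),
   (iv) additive white scanner noise at amplitude ratio ``snr_scan``, and
   (v) z-scoring.

The shared physiological noise is non-stationary: a low-pass Gaussian
carrier modulated by a slow nonnegative envelope, emulating the episodic
bursts of gross fetal movement separated by quiescent periods. The
ground-truth displacement proxy ``fd_true`` is the magnitude of the shared
noise downsampled at rate ``d``; windows of elevated envelope therefore show
both elevated FD and inflated pairwise correlation, which is exactly the
spurious coupling the QC statistic is designed to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import signal as _signal
from scipy import stats as _stats

__all__ = [
    "SimParams",
    "HRFParams",
    "NeuralEventTrain",
    "BOLDObservation",
    "generate_neural_events",
    "hrf_kernel",
    "impose_correlation",
    "observe",
    "simulate_dataset",
]

# internal batch size for vectorised dataset generation; fixed so that
# results are bit-reproducible for a given (seed, n_pairs, params)
_BATCH = 500


@dataclass(frozen=True)
class SimParams:
    """Parameters of the BOLD observation model.

    Attributes
    ----------
    nu_g : float
        Latent (neural) sampling frequency in Hz.
    nu_o : float
        Observation frequency in Hz; the repetition time is ``TR = 1/nu_o``
        seconds. ``nu_g / nu_o`` must be a positive integer.
    n_obs : int
        Number of observed time points.
    activity_rate : float
        Stationary probability that a latent bin is active, in [0, 1].
    active_self_transition : float
        Probability that an active latent bin stays active at the next bin;
        controls event burstiness at a fixed stationary rate.
    snr_phys : float
        Physiological signal-to-noise amplitude (RMS) ratio, > 0.
    snr_scan : float
        Scanner/thermal signal-to-noise amplitude (RMS) ratio, > 0.
    prune_rate : float
        Probability that an active latent bin is lost in the observation
        branch before the HRF response forms, in [0, 1).
    phys_cutoff_hz : float
        Low-pass cutoff of the physiological noise carrier, Hz.
    envelope_cutoff_hz : float
        Low-pass cutoff of the Gaussian process whose square forms the slow
        nonnegative amplitude envelope of the physiological noise; sets the
        timescale of simulated movement episodes.
    envelope_power : float
        Exponent applied to the absolute low-pass envelope process; 2 gives
        sparse chi-square-like bursts, 0 removes the modulation entirely
        (stationary noise).
    shared_noise : bool
        If True (default) the two signals of a pair receive the identical
        physiological noise realisation; if False each gets an independent
        one (no motion-induced coupling).
    downsample : str
        ``"average"`` (block mean over each window of ``d`` latent samples,
        mimicking volume-integrating acquisition) or ``"decimate"``
        (keep every ``d``-th sample).
    seed : int or None
        Master seed for dataset generation.
    """

    nu_g: float = 20.0
    nu_o: float = 1.0 / 3.0
    n_obs: int = 96
    activity_rate: float = 0.05
    active_self_transition: float = 0.5
    snr_phys: float = 6.0
    snr_scan: float = 9.0
    prune_rate: float = 0.1
    phys_cutoff_hz: float = 0.3
    envelope_cutoff_hz: float = 0.055
    envelope_power: float = 2.0
    shared_noise: bool = True
    downsample: str = "average"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.nu_g > self.nu_o > 0):
            raise ValueError(
                f"require nu_g > nu_o > 0, got nu_g={self.nu_g}, nu_o={self.nu_o}"
            )
        d = self.nu_g / self.nu_o
        if abs(d - round(d)) > 1e-9 or round(d) < 1:
            raise ValueError(
                f"downsampling rate d = nu_g/nu_o = {d:g} must be a positive integer"
            )
        if not 0.0 <= self.activity_rate <= 1.0:
            raise ValueError(f"activity_rate must be in [0, 1], got {self.activity_rate}")
        if not 0.0 <= self.active_self_transition <= 1.0:
            raise ValueError("active_self_transition must be in [0, 1]")
        if self.snr_phys <= 0 or self.snr_scan <= 0:
            raise ValueError("snr_phys and snr_scan must be > 0")
        if not 0.0 <= self.prune_rate < 1.0:
            raise ValueError(f"prune_rate must be in [0, 1), got {self.prune_rate}")
        if self.n_obs < 2:
            raise ValueError("n_obs must be >= 2")
        if self.downsample not in ("average", "decimate"):
            raise ValueError("downsample must be 'average' or 'decimate'")

    @property
    def d(self) -> int:
        """Integer downsampling rate nu_g / nu_o."""
        return int(round(self.nu_g / self.nu_o))

    @property
    def tr(self) -> float:
        """Repetition time of the observed series, seconds."""
        return 1.0 / self.nu_o

    @property
    def n_latent(self) -> int:
        """Length of the latent event train, n_obs * d."""
        return self.n_obs * self.d


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        if not self.peak_delay < self.undershoot_delay:
            raise ValueError("peak_delay must be < undershoot_delay")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be > 0")
        if self.duration <= self.peak_delay:
            raise ValueError(
                f"duration={self.duration}s too short to contain the response "
                f"peak at {self.peak_delay}s"
            )


@dataclass
class NeuralEventTrain:
    """Binary latent activity sequence at rate ``nu_g``."""

    events: NDArray[np.int8]

    @property
    def length(self) -> int:
        return int(self.events.shape[-1])


@dataclass
class BOLDObservation:
    """One simulated pair of observed BOLD signals with ground truth.

    ``observed_x``/``observed_y`` are z-scored length-``n_obs`` series;
    ``fd_true`` is the nonnegative ground-truth displacement proxy;
    ``rho_true`` is the imposed neural correlation. The noiseless latent-rate
    signals ``ideal_x``/``ideal_y`` are kept only when requested.
    """

    observed_x: NDArray[np.float64]
    observed_y: NDArray[np.float64]
    fd_true: NDArray[np.float64]
    rho_true: float
    ideal_x: NDArray[np.float64] | None = None
    ideal_y: NDArray[np.float64] | None = None


def generate_neural_events(
    params: SimParams,
    rng: np.random.Generator | int | None = None,
    n_series: int = 1,
) -> NeuralEventTrain:
    """Sample binary neural event trains from a two-state Markov chain.

    The chain has stationary activity probability ``params.activity_rate``
    and active-state self-transition ``params.active_self_transition``; the
    inactive-to-active probability follows from stationarity.

    Returns a :class:`NeuralEventTrain` whose ``events`` has shape
    ``(n_series, n_latent)`` (squeezed to 1-D when ``n_series == 1``).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = params.activity_rate
    q = params.active_self_transition
    T = params.n_latent
    if p == 0.0:
        ev = np.zeros((n_series, T), dtype=np.int8)
    elif p == 1.0:
        ev = np.ones((n_series, T), dtype=np.int8)
    else:
        # stationarity: p*q + (1-p)*p01 = p
        p01 = p * (1.0 - q) / (1.0 - p)
        if p01 > 1.0:
            raise ValueError(
                "no valid chain: activity_rate/self-transition combination "
                f"requires inactive->active probability {p01:.3f} > 1"
            )
        u = rng.random((n_series, T))
        ev = np.zeros((n_series, T), dtype=np.int8)
        ev[:, 0] = u[:, 0] < p
        for t in range(1, T):
            prev = ev[:, t - 1].astype(bool)
            ev[:, t] = np.where(prev, u[:, t] < q, u[:, t] < p01)
    if n_series == 1:
        ev = ev[0]
    return NeuralEventTrain(events=ev)


def hrf_kernel(hrf: HRFParams = HRFParams(), dt: float = 0.05) -> NDArray[np.float64]:
    """Sample the canonical double-gamma HRF on a grid of spacing ``dt`` s.

    The kernel is the difference of two gamma densities — a positive
    response peaking at ``peak_delay`` and a later undershoot — normalised
    to unit peak. Gamma shapes are chosen so the density mode sits exactly
    at the requested delay.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, hrf.duration, dt)
    peak = _stats.gamma.pdf(
        t, hrf.peak_delay / hrf.peak_dispersion + 1.0, scale=hrf.peak_dispersion
    )
    under = _stats.gamma.pdf(
        t,
        hrf.undershoot_delay / hrf.undershoot_dispersion + 1.0,
        scale=hrf.undershoot_dispersion,
    )
    kernel = peak - hrf.undershoot_ratio * under
    return kernel / kernel.max()


def impose_correlation(
    ideal_signals: NDArray[np.float64], R: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Mix standardized signals so their correlation matrix approaches ``R``.

    ``ideal_signals`` is ``(n_signals, T)``. Rows are z-scored, then mixed
    with the lower Cholesky factor of ``R`` (``Y = L @ S``, so that
    ``cov(Y) = L L' = R`` when the rows of ``S`` are uncorrelated).

    Raises
    ------
    ValueError
        If ``R`` is not symmetric positive-definite with unit diagonal; the
        message reports the offending eigenvalues.
    """
    R = np.asarray(R, dtype=float)
    S = np.asarray(ideal_signals, dtype=float)
    if S.ndim != 2 or R.shape != (S.shape[0], S.shape[0]):
        raise ValueError("ideal_signals must be (n_signals, T) matching R")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ValueError("R must have unit diagonal")
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() <= 0:
        raise ValueError(
            f"R is not positive-definite: eigenvalues {np.sort(eigvals)}"
        )
    L = np.linalg.cholesky(R)
    Z = S - S.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a zero-variance signal")
    Z /= sd[:, None]
    return L @ Z


def _lowpass_white(
    rng: np.random.Generator, shape: tuple[int, ...], cutoff_hz: float, fs: float
) -> NDArray[np.float64]:
    """White Gaussian noise brick-wall low-passed below ``cutoff_hz``."""
    x = rng.standard_normal(shape)
    X = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(shape[-1], 1.0 / fs)
    X[..., f > cutoff_hz] = 0.0
    return np.fft.irfft(X, shape[-1], axis=-1)


def _phys_noise(
    rng: np.random.Generator, n: int, params: SimParams
) -> NDArray[np.float64]:
    """Unit-RMS episodic physiological noise, shape (n, n_latent)."""
    T = params.n_latent
    carrier = _lowpass_white(rng, (n, T), params.phys_cutoff_hz, params.nu_g)
    if params.envelope_power > 0:
        env = np.abs(
            _lowpass_white(rng, (n, T), params.envelope_cutoff_hz, params.nu_g)
        ) ** params.envelope_power
        noise = carrier * env
    else:
        noise = carrier
    rms = np.sqrt(np.mean(noise**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return noise / rms


def _downsample(x: NDArray[np.float64], d: int, mode: str) -> NDArray[np.float64]:
    if mode == "average":
        return x.reshape(*x.shape[:-1], -1, d).mean(axis=-1)
    return x[..., ::d]


def _zscore_rows(x: NDArray[np.float64]) -> NDArray[np.float64]:
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _observe_batch(
    obs_latent: NDArray[np.float64],
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[NDArray, NDArray, NDArray]:
    """Observation mappings for a batch of latent-rate signal pairs.

    ``obs_latent`` is ``(n_pairs, 2, n_latent)`` (the observed branch,
    already pruned/convolved/mixed). Returns ``(x_obs, y_obs, fd_true)``
    with shapes ``(n_pairs, n_obs)``.
    """
    nb = obs_latent.shape[0]
    d, T = params.d, params.n_latent
    sig_rms = obs_latent.std(axis=-1).mean(axis=1)  # per-pair amplitude scale
    if params.shared_noise:
        noise = _phys_noise(rng, nb, params)
        phys = noise[:, None, :] * (sig_rms / params.snr_phys)[:, None, None]
    else:
        noise = _phys_noise(rng, 2 * nb, params).reshape(nb, 2, T)
        phys = noise * (sig_rms / params.snr_phys)[:, None, None]
    contaminated = obs_latent + phys
    ds = _downsample(contaminated, d, params.downsample)
    # ground-truth displacement proxy: magnitude of the downsampled noise
    fd_src = noise if params.shared_noise else noise[:, 0, :]
    fd_true = np.abs(
        _downsample(fd_src * (sig_rms / params.snr_phys)[:, None], d, params.downsample)
    )
    ds_rms = _downsample(obs_latent, d, params.downsample).std(axis=-1).mean(axis=1)
    thermal = rng.standard_normal(ds.shape) * (ds_rms / params.snr_scan)[:, None, None]
    out = _zscore_rows(ds + thermal)
    return out[:, 0, :], out[:, 1, :], fd_true


def observe(
    ideal_pair: NDArray[np.float64],
    params: SimParams,
    rng: np.random.Generator | int | None = None,
    pruned_pair: NDArray[np.float64] | None = None,
    rho_true: float = 0.0,
) -> BOLDObservation:
    """Apply the observation process to one latent-rate ideal signal pair.

    ``ideal_pair`` is ``(2, n_latent)``. ``pruned_pair``, when given, is the
    observed branch after event pruning (same shape); by default the ideal
    pair itself enters the observation chain (no pruning loss), which is the
    noiseless-limit contract: with both SNRs at infinity the observation is
    the normalised downsampled ideal signal.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ideal_pair = np.asarray(ideal_pair, dtype=float)
    if ideal_pair.shape != (2, params.n_latent):
        raise ValueError(
            f"ideal_pair must have shape (2, {params.n_latent}), got {ideal_pair.shape}"
        )
    branch = ideal_pair if pruned_pair is None else np.asarray(pruned_pair, float)
    x, y, fd = _observe_batch(branch[None], params, rng)
    return BOLDObservation(
        observed_x=x[0],
        observed_y=y[0],
        fd_true=fd[0],
        rho_true=float(rho_true),
        ideal_x=ideal_pair[0],
        ideal_y=ideal_pair[1],
    )


def _simulate_batch(
    nb: int,
    params: SimParams,
    rho: float,
    rng: np.random.Generator,
    kernel: NDArray[np.float64],
) -> tuple[NDArray, NDArray, NDArray]:
    """Generate ``nb`` pairs end to end (vectorised). Returns (x, y, fd)."""
    T = params.n_latent
    obs_branch = np.empty((nb, 2, T))
    for k in range(2):
        ev = np.atleast_2d(
            generate_neural_events(params, rng, n_series=nb).events
        ).astype(bool)
        if params.prune_rate > 0:
            ev = ev & (rng.random(ev.shape) >= params.prune_rate)
        obs_branch[:, k, :] = _signal.fftconvolve(
            ev.astype(float), kernel[None, :], axes=-1
        )[:, :T]
    if rho != 0.0:
        R = np.array([[1.0, rho], [rho, 1.0]])
        L = np.linalg.cholesky(R)
        z = _zscore_rows(obs_branch)
        obs_branch = np.einsum("ij,njt->nit", L, z)
    return _observe_batch(obs_branch, params, rng)


def simulate_dataset(
    n_pairs: int,
    params: SimParams,
    rho: float = 0.0,
    hrf: HRFParams = HRFParams(),
    keep_ideal: bool = False,
    as_arrays: bool = False,
):
    """Simulate ``n_pairs`` independent BOLD signal pairs.

    Each pair consists of two signals whose latent neural activity has
    correlation ``rho`` (0 for independent activity), observed through the
    shared-noise contamination chain. Reproducible from ``params.seed``.

    Parameters
    ----------
    keep_ideal : bool
        Retain the latent-rate noiseless signals on each observation
        (memory-heavy for large datasets).
    as_arrays : bool
        If True return a dict of stacked arrays
        (``x``, ``y``, ``fd_true``, ``rho_true``) instead of a list of
        :class:`BOLDObservation`; the numbers are identical either way.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    rng = np.random.default_rng(params.seed)
    kernel = hrf_kernel(hrf, dt=1.0 / params.nu_g)
    xs, ys, fds = [], [], []
    ideals = []
    for i0 in range(0, n_pairs, _BATCH):
        nb = min(_BATCH, n_pairs - i0)
        if keep_ideal:
            # consumes the rng in the same order as _simulate_batch, so the
            # observed numbers are unchanged by keep_ideal
            x, y, fd, ideal = _simulate_batch_with_ideal(nb, params, rho, rng, kernel)
            ideals.append(ideal)
        else:
            x, y, fd = _simulate_batch(nb, params, rho, rng, kernel)
        xs.append(x)
        ys.append(y)
        fds.append(fd)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    fd = np.concatenate(fds)
    if as_arrays:
        return {
            "x": x,
            "y": y,
            "fd_true": fd,
            "rho_true": np.full(n_pairs, float(rho)),
        }
    ideal = np.concatenate(ideals) if keep_ideal else None
    out = []
    for i in range(n_pairs):
        out.append(
            BOLDObservation(
                observed_x=x[i],
                observed_y=y[i],
                fd_true=fd[i],
                rho_true=float(rho),
                ideal_x=ideal[i, 0] if keep_ideal else None,
                ideal_y=ideal[i, 1] if keep_ideal else None,
            )
        )
    return out


def _simulate_batch_with_ideal(nb, params, rho, rng, kernel):
    """Batch generation that also returns the unpruned ideal branch.

    The event trains are sampled once and reused for both branches, so the
    ideal branch "keeps all events" while the observed branch is pruned.
    """
    T = params.n_latent
    obs_branch = np.empty((nb, 2, T))
    ideal = np.empty((nb, 2, T))
    for k in range(2):
        ev = np.atleast_2d(
            generate_neural_events(params, rng, n_series=nb).events
        ).astype(bool)
        ideal[:, k, :] = _signal.fftconvolve(
            ev.astype(float), kernel[None, :], axes=-1
        )[:, :T]
        if params.prune_rate > 0:
            ev = ev & (rng.random(ev.shape) >= params.prune_rate)
        obs_branch[:, k, :] = _signal.fftconvolve(
            ev.astype(float), kernel[None, :], axes=-1
        )[:, :T]
    if rho != 0.0:
        L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
        obs_branch = np.einsum("ij,njt->nit", L, _zscore_rows(obs_branch))
        ideal = np.einsum("ij,njt->nit", L, _zscore_rows(ideal))
    x, y, fd = _observe_batch(obs_branch, params, rng)
    return x, y, fd, ideal
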
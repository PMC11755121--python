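"""Tests of the sliding-window FC-FD statistic and its null models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.base import clone

from fetalqc import (
    ParcelTimeSeries,
    SubjectMotionQC,
    WindowSpec,
    assess_subject,
    fcfd_test,
    sliding_fc,
    sliding_fd,
    surrogate_null,
)
from fetalqc.qc_subject import phase_randomize


def brute_force_sliding_fc(x, y, width, stride=1):
    out = []
    for n in range(0, len(x) - width + 1, stride):
        out.append(np.corrcoef(x[n : n + width], y[n : n + width])[0, 1])
    return np.array(out)


def brute_force_sliding_fd(fd, width, stride=1):
    return np.array(
        [fd[n : n + width].mean() for n in range(0, len(fd) - width + 1, stride)]
    )


class TestSlidingWindows:
    def test_fc_matches_bruteforce_oracle(self, rng):
        x, y = rng.standard_normal((2, 96))
        win = WindowSpec(45, 1)
        np.testing.assert_allclose(
            sliding_fc(x, y, win), brute_force_sliding_fc(x, y, 45), atol=1e-12
        )

    def test_fd_matches_bruteforce_oracle(self, rng):
        fd = np.abs(rng.standard_normal(96))
        np.testing.assert_allclose(
            sliding_fd(fd, WindowSpec(46, 1)), brute_force_sliding_fd(fd, 46),
            atol=1e-12,
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        width=st.integers(3, 30),
        stride=st.integers(1, 5),
        T=st.integers(31, 80),
    )
    def test_fc_oracle_property(self, seed, width, stride, T):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal((2, T))
        got = sliding_fc(x, y, WindowSpec(width, stride))
        want = brute_force_sliding_fc(x, y, width, stride)
        assert got.shape == want.shape
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert np.nanmax(np.abs(got)) <= 1 + 1e-12

    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(60)
        np.testing.assert_allclose(sliding_fc(x, x, WindowSpec(10)), 1.0, atol=1e-12)

    def test_full_width_window_equals_global_pearson(self, rng):
        x, y = rng.standard_normal((2, 50))
        cc = sliding_fc(x, y, WindowSpec(50))
        assert cc.shape == (1,)
        assert cc[0] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_window_count_identity(self):
        # 96 timepoints with a 46-TR window at stride 1 give 51 positions
        assert WindowSpec(46, 1).n_windows(96) == 51

    def test_constant_window_flagged_nan(self):
        x = np.r_[np.ones(20), np.random.default_rng(0).standard_normal(20)]
        y = np.random.default_rng(1).standard_normal(40)
        cc = sliding_fc(x, y, WindowSpec(10))
        assert np.isnan(cc[:5]).all()
        assert np.isfinite(cc[-5:]).all()

    def test_fd_constant_input(self):
        np.testing.assert_allclose(
            sliding_fd(np.full(30, 0.7), WindowSpec(5)), 0.7, atol=1e-15
        )

    def test_fd_single_spike(self):
        fd = np.zeros(30)
        fd[15] = 1.0
        out = sliding_fd(fd, WindowSpec(5))
        covered = (np.arange(len(out)) <= 15) & (np.arange(len(out)) >= 11)
        np.testing.assert_allclose(out[covered], 1 / 5, atol=1e-15)
        np.testing.assert_allclose(out[~covered], 0.0, atol=1e-15)


class TestFCFDTest:
    def test_closed_form_t_statistic(self):
        # construct series with an exact target correlation, L = 51
        L = 51
        rng = np.random.default_rng(0)
        a = rng.standard_normal(L)
        b = rng.standard_normal(L)
        # orthogonalize then mix to r = 0.5 exactly
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        y = 0.5 * a + np.sqrt(1 - 0.25) * b
        r, t, p = fcfd_test(a, y)
        assert r == pytest.approx(0.5, abs=1e-12)
        assert t == pytest.approx(0.5 * np.sqrt(49) / np.sqrt(0.75), abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(t, 49), abs=1e-15)

    def test_zero_correlation_gives_unit_p(self):
        L = 40
        a = np.sin(np.linspace(0, 4 * np.pi, L))
        b = np.cos(np.linspace(0, 4 * np.pi, L))
        b -= a * (a @ b) / (a @ a)
        r, t, p = fcfd_test(a, b)
        assert abs(r) < 1e-12
        assert t == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_perfect_correlation_flagged(self):
        x = np.linspace(0, 1, 30)
        r, t, p = fcfd_test(x, 2 * x + 1)
        assert r == 1.0 and np.isinf(t) and p == 0.0

    def test_matches_scipy_on_random_data(self, rng):
        a, b = rng.standard_normal((2, 51))
        r, t, p = fcfd_test(a, b)
        r2, p2 = stats.pearsonr(a, b)
        assert r == pytest.approx(r2, abs=1e-12)
        assert p == pytest.approx(p2, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fcfd_test(np.ones(3), np.ones(3))


class TestSurrogateNull:
    def test_amplitude_spectrum_preserved(self, rng):
        fd = np.abs(rng.standard_normal(96))
        surr = phase_randomize(fd, 50, rng)
        amp = np.abs(np.fft.rfft(fd))
        for s in surr:
            np.testing.assert_allclose(np.abs(np.fft.rfft(s)), amp, atol=1e-10)

    def test_null_mean_near_zero(self, rng):
        fd = np.abs(rng.standard_normal(96))
        x, y = rng.standard_normal((2, 96))
        cc = sliding_fc(x, y, WindowSpec(46))
        null, _ = surrogate_null(fd, cc, WindowSpec(46), n_surrogates=2000, seed=1)
        se = null.std() / np.sqrt(null.size)
        assert abs(null.mean()) < 3 * se + 0.02

    def test_single_component_spectrum_gives_shifted_sinusoids(self):
        t = np.arange(96)
        fd = 2.0 + np.cos(2 * np.pi * 4 * t / 96)
        surr = phase_randomize(fd, 20, np.random.default_rng(0))
        amp = np.abs(np.fft.rfft(fd))
        for s in surr:
            np.testing.assert_allclose(np.abs(np.fft.rfft(s)), amp, atol=1e-9)
            # a pure tone stays a pure tone: fit amplitude via its rFFT bin
            coef = np.fft.rfft(s)[4]
            recon = 2.0 + (coef.real * np.cos(2 * np.pi * 4 * t / 96)
                           - coef.imag * np.sin(2 * np.pi * 4 * t / 96)) * 2 / 96
            np.testing.assert_allclose(s, recon, atol=1e-9)

    def test_few_surrogates_warns(self, rng):
        fd = np.abs(rng.standard_normal(96))
        cc = sliding_fc(*rng.standard_normal((2, 96)), WindowSpec(46))
        with pytest.warns(UserWarning, match="unstable"):
            surrogate_null(fd, cc, WindowSpec(46), n_surrogates=50, seed=0)

    def test_p_value_reproducible_under_seed(self, rng):
        fd = np.abs(rng.standard_normal(96))
        cc = sliding_fc(*rng.standard_normal((2, 96)), WindowSpec(46))
        _, p1 = surrogate_null(fd, cc, WindowSpec(46), n_surrogates=200, seed=9)
        _, p2 = surrogate_null(fd, cc, WindowSpec(46), n_surrogates=200, seed=9)
        assert p1 == p2


class TestSubjectMotionQC:
    def _subject(self, rng, n_regions=8, T=96):
        data = rng.standard_normal((n_regions, T))
        fd = np.abs(rng.standard_normal(T))
        cents = rng.uniform(0, 60, (n_regions, 3))
        ts = ParcelTimeSeries(data=data, centroids=cents, tr=3.0)
        return ts, fd

    def test_edge_count_for_98_regions(self, rng):
        # 98 ROIs yield 98*97/2 = 4753 region pairs
        data = rng.standard_normal((98, 96))
        fd = np.abs(rng.standard_normal(96))
        qc = SubjectMotionQC(null_mode="parametric").fit(
            ParcelTimeSeries(data=data, tr=3.0), fd=fd
        )
        assert len(qc.edges_) == 4753
        assert qc.n_windows_ == 51

    def test_degenerate_fd_flagged(self, rng):
        ts, _ = self._subject(rng)
        qc = SubjectMotionQC(n_surrogates=100).fit(ts, fd=np.zeros(96))
        assert qc.fd_degenerate_
        assert qc.edges_["p"].isna().all()
        assert not qc.edges_["corrupted"].any()

    def test_zero_variance_region_excluded(self, rng):
        ts, fd = self._subject(rng, n_regions=6)
        ts.data[2] = 5.0
        qc = SubjectMotionQC(null_mode="parametric").fit(ts, fd=fd)
        assert qc.excluded_regions_ == [2]
        assert len(qc.edges_) == 5 * 4 / 2

    def test_region_counts_match_edges(self, rng):
        ts, fd = self._subject(rng)
        qc = SubjectMotionQC(n_surrogates=200, random_state=0).fit(ts, fd=fd)
        total = qc.region_counts_.sum()
        assert total == 2 * qc.edges_["corrupted"].sum()

    def test_fdr_is_no_less_conservative(self, rng):
        ts, fd = self._subject(rng, n_regions=10)
        qc_u = SubjectMotionQC(n_surrogates=200, random_state=0).fit(ts, fd=fd)
        qc_f = SubjectMotionQC(n_surrogates=200, random_state=0, correction="fdr").fit(
            ts, fd=fd
        )
        assert qc_f.edges_["corrupted"].sum() <= qc_u.edges_["corrupted"].sum()

    def test_sklearn_protocol(self):
        qc = SubjectMotionQC(window=30, n_surrogates=111)
        c = clone(qc)
        assert c.get_params()["n_surrogates"] == 111
        assert c.get_params()["window"] == 30

    def test_functional_wrapper_agrees(self, rng):
        ts, fd = self._subject(rng)
        rep = assess_subject(ts, fd, WindowSpec(46), n_surrogates=150, seed=3)
        qc = SubjectMotionQC(n_surrogates=150, random_state=3).fit(ts, fd=fd)
        assert rep.frac_corrupted == qc.frac_corrupted_
        assert rep.median_abs_r == qc.median_abs_r_
        assert len(rep.edges) == len(qc.edges_)

    def test_specificity_to_neural_synchrony(self):
        """Genuine synchrony at low contamination is not called corruption:
        the corrupted count stays near the alpha-level baseline even when
        rho_true = 0.9."""
        from fetalqc import SimParams, simulate_dataset
        from fetalqc.qc_subject import WindowSpec

        params = SimParams(snr_phys=12.0, snr_scan=18.0, seed=21)
        ds = simulate_dataset(300, params, rho=0.9, as_arrays=True)
        win = WindowSpec(46, 1)
        n_sig = 0
        for i in range(300):
            cc = sliding_fc(ds["x"][i], ds["y"][i], win)
            _, p = surrogate_null(
                ds["fd_true"][i], cc, win, n_surrogates=200, seed=1000 + i
            )
            n_sig += p < 0.05
        assert n_sig / 300 < 0.12

    def test_corrupted_count_monotone_in_contamination(self):
        """Matched seeds: more contamination, no fewer corrupted pairs."""
        from fetalqc import SimParams, simulate_dataset

        win = WindowSpec(46, 1)
        counts = []
        for snr in [(12.0, 18.0), (2.0, 3.0)]:
            params = SimParams(snr_phys=snr[0], snr_scan=snr[1], seed=33)
            ds = simulate_dataset(300, params, as_arrays=True)
            n_sig = 0
            for i in range(300):
                cc = sliding_fc(ds["x"][i], ds["y"][i], win)
                _, p = surrogate_null(
                    ds["fd_true"][i], cc, win, n_surrogates=200, seed=2000 + i
                )
                n_sig += p < 0.05
            counts.append(n_sig)
        assert counts[1] > counts[0]
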
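"""Neural preprocessing and spatial-encoding kernels on synthetic
place-tuned sessions."""

import numpy as np
import pytest

from exotwin.arenas import eight_maze
from exotwin.errors import ConfigurationError, ExotwinError
from exotwin.neural import (
    EphysSession,
    FluorSession,
    PlaceTuningSpec,
    build_predictors,
    compute_dff,
    filter_cells,
    kernel_pinv,
    kernel_rrr,
    linear_traversals,
    normalize_sort,
    preprocess_ephys,
    spike_rates,
    subtract_common_mode,
    synth_fluorescence_session,
    true_kernel,
)

PATH_LEN = eight_maze().path_length  # ~0.98 m


class TestDff:
    def test_constant_trace_gives_near_zero_dff(self):
        n = 3000
        sess = FluorSession(
            F_cell=np.full((n, 2), 120.0), F_neu=np.zeros((n, 2)), sample_rate=15
        )
        dff, valid = compute_dff(sess)
        assert valid.all()
        assert np.abs(dff).max() < 1e-6  # band-pass removes DC

    def test_transient_amplitude_recovered_within_5pct(self):
        """A brief in-band transient of amplitude A on baseline B peaks at
        ~100 A/B percent after the pipeline.

        The pulse must actually sit inside the 0.05-5 Hz passband: any
        unipolar transient loses roughly 2 f_hp (area/peak) of its peak to
        the high-pass edge, so a ~0.1 s-scale calcium-like pulse is the
        regime where the formula's amplitude is recoverable."""
        fs, n = 15.0, 9000
        t = np.arange(n) / fs
        B, A, sig = 100.0, 30.0, 0.12
        trace = B + A * np.exp(-0.5 * ((t - 300.0) / sig) ** 2)  # peak on-sample
        sess = FluorSession(
            F_cell=trace[:, None], F_neu=np.zeros((n, 1)), sample_rate=fs
        )
        dff, valid = compute_dff(sess)
        assert valid[0]
        assert dff.max() == pytest.approx(100 * A / B, rel=0.05)

    def test_neuropil_coefficient_is_0p7(self):
        n = 2000
        rng = np.random.default_rng(0)
        F = 100 + rng.normal(0, 1, (n, 1))
        neu = rng.normal(0, 1, (n, 1))
        d0, _ = compute_dff(FluorSession(F_cell=F, F_neu=neu, sample_rate=15))
        delta = np.ones((n, 1))
        d1, _ = compute_dff(FluorSession(F_cell=F, F_neu=neu + delta, sample_rate=15))
        # adding delta to F_neu changes the corrected numerator by -0.7*delta;
        # a constant shift is removed by the band-pass but scales the denominator
        denom0 = (F - 0.7 * neu).mean()
        denom1 = (F - 0.7 * (neu + delta)).mean()
        assert denom0 - denom1 == pytest.approx(0.7, abs=1e-9)
        assert np.allclose(d1 * denom1, d0 * denom0, atol=1e-6)

    def test_nonpositive_denominator_flags_cell(self):
        n = 2000
        sess = FluorSession(
            F_cell=np.full((n, 1), 10.0), F_neu=np.full((n, 1), 100.0), sample_rate=15
        )
        _, valid = compute_dff(sess)
        assert not valid[0]


class TestFilterCells:
    def _dff(self, peak, sd_scale=1.0, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 10 * sd_scale, (n, 1))
        x[n // 2, 0] = peak
        return x

    def test_max_600pct_excluded(self):
        mask, _ = filter_cells(self._dff(600.0))
        assert not mask[0]

    def test_small_soma_excluded(self):
        dff = self._dff(80.0)
        morph = np.array([[10.0, 1.0, 10.0]])  # 10 px soma
        mask, counts = filter_cells(dff, morph)
        assert not mask[0]
        assert counts["soma_pixels"] == 0

    def test_compliant_cell_included(self):
        dff = self._dff(80.0)  # sd ~10 %, max 80 %
        morph = np.array([[100.0, 1.1, 12.0]])
        mask, _ = filter_cells(dff, morph)
        assert mask[0]

    def test_boundaries_inclusive(self):
        x = np.zeros((100, 1))
        x[50] = 20.0  # max exactly at the lower bound
        mask, _ = filter_cells(x, np.array([[20.0, 0.7, 10.0]]))
        assert mask[0]


class TestEphysPreprocessing:
    def test_common_mode_sinusoid_removed(self):
        n, fs = 6000, 20000
        t = np.arange(n) / fs
        hum = 50e-6 * np.sin(2 * np.pi * 60 * t)
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1e-6, (n, 8))
        v = base + hum[:, None]
        out = subtract_common_mode(v, np.ones(8, bool))
        # residual hum is <= 1e-12 of its amplitude
        resid = out - (base - base.mean(axis=1, keepdims=True))
        assert np.abs(resid).max() <= 50e-6 * 1e-12 + 1e-18

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            subtract_common_mode(np.zeros((10, 4)), np.zeros(4, bool))

    def test_poisson_rate_mean_counts_per_window(self):
        """Homogeneous Poisson train at rate lam: mean windowed count
        ~ lam * 0.05 within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        lam, dur = 20.0, 600.0
        n_sp = rng.poisson(lam * dur)
        st = np.sort(rng.uniform(0, dur, n_sp))
        rm = spike_rates([st], dur, zscore=False)
        expect = lam * 0.05
        se = np.sqrt(lam * 0.05) / np.sqrt(rm.Y.shape[0] / 2.5)  # smoothing correlates windows
        assert rm.Y[:, 0].mean() == pytest.approx(expect, abs=5 * se + 0.02)

    def test_output_sampling_interval_20ms(self):
        rm = spike_rates([np.array([0.1, 0.5])], duration=10.0)
        assert rm.sample_rate == pytest.approx(50.0)
        assert rm.Y.shape[0] == pytest.approx(10.0 / 0.02, abs=3)

    def test_zscore_columns_and_zero_variance_flagging(self):
        rng = np.random.default_rng(1)
        st = np.sort(rng.uniform(0, 100, 2000))
        rm = spike_rates([st, np.array([])], 100.0)
        assert rm.Y[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert rm.Y[:, 0].std() == pytest.approx(1.0, abs=1e-12)
        assert 1 in rm.zero_variance_cells
        assert np.allclose(rm.Y[:, 1], 0.0)

    def test_full_pipeline_runs(self):
        rng = np.random.default_rng(2)
        sess = EphysSession(
            channel_voltages=rng.normal(0, 1e-6, (2000, 4)),
            spike_times=[np.sort(rng.uniform(0, 5, 50))],
            in_brain_mask=np.array([True, True, True, False]),
            sample_rate=20000,
            duration=5.0,
        )
        cleaned, rates = preprocess_ephys(sess)
        assert cleaned.shape == (2000, 4)
        assert rates.sample_rate == 50.0


class TestPredictors:
    def test_one_hot_location_rows(self):
        s = linear_traversals(PATH_LEN, 0.12, 120.0)
        pm = build_predictors(s, PATH_LEN, n_bins=82)
        loc = pm.X[:, pm.location_slice]
        assert np.all(loc.sum(axis=1) == 1.0)
        assert pm.off_path_samples == 0

    def test_all_bins_visited_gives_full_column_rank(self):
        s = linear_traversals(PATH_LEN, 0.12, 300.0)
        pm = build_predictors(s, PATH_LEN, n_bins=82)
        loc = pm.X[:, pm.location_slice]
        assert np.linalg.matrix_rank(loc) == 82

    def test_off_path_samples_zero_row_and_counted(self):
        s = np.array([0.1, np.nan, 0.2, 2.5])  # nan + beyond path length
        pm = build_predictors(s, PATH_LEN, n_bins=10)
        assert pm.off_path_samples == 2
        assert np.all(pm.X[1, pm.location_slice] == 0)
        assert np.all(pm.X[3, pm.location_slice] == 0)

    def test_diagonalized_event_lag_structure(self):
        s = np.full(100, 0.1)
        pm = build_predictors(
            s, PATH_LEN, n_bins=5, events={"cue": np.array([10])},
            sample_rate=5.0, lag_span=1.0,
        )
        block = pm.X[:, pm.event_slices["cue"]]
        assert block.shape[1] == 5
        for lag in range(5):
            col = block[:, lag]
            assert col.sum() == 1.0 and col[10 + lag] == 1.0

    def test_covariates_z_scored(self):
        s = np.full(200, 0.1)
        rng = np.random.default_rng(0)
        pm = build_predictors(
            s, PATH_LEN, n_bins=5, covariates={"speed": rng.uniform(0, 1, 200)}
        )
        cov = pm.X[:, pm.covariate_slice]
        assert cov.mean() == pytest.approx(0.0, abs=1e-12)
        assert cov.std() == pytest.approx(1.0, abs=1e-12)


def one_hot_design(n_bins, repeats, rng=None):
    """Visit every bin `repeats` times in shuffled order."""
    idx = np.repeat(np.arange(n_bins), repeats)
    if rng is not None:
        rng.shuffle(idx)
    X = np.zeros((idx.size, n_bins))
    X[np.arange(idx.size), idx] = 1.0
    return X, idx


class TestKernelPinv:
    def test_exact_recovery_of_true_kernel(self, rng):
        X, _ = one_hot_design(12, 8, rng)
        K_true = rng.normal(0, 1, (12, 5))
        Y = X @ K_true
        km = kernel_pinv(Y, X)
        assert np.abs(km.K - K_true).max() <= 1e-8

    def test_single_bin_firing_cell_toy(self):
        """3 bins x 21 samples; a cell firing only in bin 1 yields a kernel
        with one nonzero row there."""
        X, idx = one_hot_design(3, 7)
        y = (idx == 1).astype(float)[:, None]
        km = kernel_pinv(y, X)
        assert km.K[1, 0] == pytest.approx(1.0)
        assert km.K[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert km.K[2, 0] == pytest.approx(0.0, abs=1e-12)

    def test_equals_per_bin_mean_activity_for_one_hot_design(self, rng):
        """Independent oracle: with pure one-hot X, the pseudoinverse
        kernel is the per-bin mean of Y."""
        X, idx = one_hot_design(6, 9, rng)
        Y = rng.normal(0, 1, (idx.size, 4))
        km = kernel_pinv(Y, X)
        for b in range(6):
            assert np.allclose(km.K[b], Y[idx == b].mean(axis=0), atol=1e-10)

    def test_under_visited_bin_row_zeroed(self, rng):
        X, idx = one_hot_design(4, 6, rng)
        # reduce bin 2 to 4 visits (< 5 instances)
        keep = np.ones(idx.size, bool)
        keep[np.nonzero(idx == 2)[0][:2]] = False
        X, idx = X[keep], idx[keep]
        Y = rng.normal(1, 0.1, (idx.size, 2))
        km = kernel_pinv(Y, X)
        assert np.all(km.K[2] == 0.0)
        assert 2 in km.zeroed_rows

    def test_stationary_rows_zeroed_before_fit(self, rng):
        X, idx = one_hot_design(3, 10, rng)
        Y = np.ones((idx.size, 1))
        stationary = np.zeros(idx.size, bool)
        stationary[idx == 0] = True  # all visits to bin 0 are stationary
        km = kernel_pinv(Y, X, stationary_mask=stationary)
        assert km.K[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert km.K[1, 0] == pytest.approx(1.0)

    def test_all_stationary_session_rejected(self, rng):
        X, idx = one_hot_design(3, 10, rng)
        with pytest.raises(ExotwinError):
            kernel_pinv(np.ones((idx.size, 1)), X, stationary_mask=np.ones(idx.size, bool))


class TestKernelRRR:
    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(0, 1, (300, 10))
        K_true = rng.normal(0, 1, (10, 6))
        Y = X @ K_true + 0.05 * rng.normal(0, 1, (300, 6))
        ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
        km = kernel_rrr(Y, X, rank=6)
        assert np.abs(km.K - ols).max() <= 1e-8

    def test_rank1_truth_recovered(self, rng):
        X = rng.normal(0, 1, (400, 8))
        u = rng.normal(0, 1, (8, 1))
        v = rng.normal(0, 1, (1, 5))
        K_true = u @ v
        Y = X @ K_true  # noiseless
        km = kernel_rrr(Y, X, rank=1)
        assert np.abs(km.K - K_true).max() <= 1e-6

    def test_residual_monotone_in_rank(self, rng):
        X = rng.normal(0, 1, (300, 8))
        Y = X @ rng.normal(0, 1, (8, 6)) + 0.3 * rng.normal(0, 1, (300, 6))
        resids = []
        for r in range(1, 7):
            km = kernel_rrr(Y, X, rank=r)
            resids.append(np.linalg.norm(Y - X @ km.K))
        assert all(b <= a + 1e-9 for a, b in zip(resids, resids[1:]))

    def test_rank_out_of_range_rejected(self, rng):
        X = rng.normal(0, 1, (50, 4))
        Y = rng.normal(0, 1, (50, 3))
        with pytest.raises(ConfigurationError):
            kernel_rrr(Y, X, rank=0)
        with pytest.raises(ConfigurationError):
            kernel_rrr(Y, X, rank=4)  # > min(4, 3)


class TestNormalizeSort:
    def test_single_cell_max_exactly_one(self, rng):
        K = np.abs(rng.normal(0, 1, (10, 1)))
        out = normalize_sort(kernel_pinv(np.zeros((20, 1)), np.zeros((20, 10))))
        km = normalize_sort(type(out)(K=K))
        assert km.K.max() == 1.0

    def test_sorted_kernel_diagonally_dominant(self, rng):
        """Ordered synthetic place cells: after normalize+sort, >60% of
        each cell's mass lies within ±3 bins of its maximum."""
        n_bins, n_cells = 40, 30
        centers = np.linspace(0, n_bins - 1, n_cells)
        K = np.exp(
            -0.5 * ((np.arange(n_bins)[:, None] - centers[None, :]) / 1.5) ** 2
        )
        perm = rng.permutation(n_cells)
        from exotwin.neural import KernelMatrix

        km = normalize_sort(KernelMatrix(K=K[:, perm]))
        for j in range(n_cells):
            col = km.K[:, j]
            peak = int(np.argmax(col))
            lo, hi = max(peak - 3, 0), min(peak + 4, n_bins)
            assert col[lo:hi].sum() / col.sum() > 0.6

    def test_permutation_invariance_of_sorted_output(self, rng):
        from exotwin.neural import KernelMatrix

        K = np.abs(rng.normal(0, 1, (15, 8)))
        a = normalize_sort(KernelMatrix(K=K))
        b = normalize_sort(KernelMatrix(K=K[:, rng.permutation(8)]))
        assert np.allclose(np.sort(a.K, axis=1), np.sort(b.K, axis=1))

    def test_depth_ordering(self, rng):
        from exotwin.neural import KernelMatrix

        K = np.abs(rng.normal(0, 1, (10, 4)))
        depths = np.array([0.3, 0.1, 0.4, 0.2])
        km = normalize_sort(KernelMatrix(K=K), order="depth", depth_table=depths)
        assert list(km.sort_order) == [1, 3, 0, 2]


class TestPlaceFieldRecovery:
    def test_zero_noise_recovery_of_peak_bins(self):
        """Noiseless long session: kernel_pinv recovers the tuning-curve
        peak bin (±1 bin) for >=95% of cells."""
        n_bins, n_cells = 82, 40
        s = linear_traversals(PATH_LEN, 0.12, 600.0)
        sess, lam, (centers, widths, peaks) = synth_fluorescence_session(
            s, n_cells, PATH_LEN, seed=0, poisson=False
        )
        pm = build_predictors(s, PATH_LEN, n_bins=n_bins)
        km = kernel_pinv(lam, pm)
        K_true = true_kernel(centers, widths, peaks, 0.1, PATH_LEN, n_bins)
        est = np.argmax(km.K, axis=0)
        truth = np.argmax(K_true, axis=0)
        err = np.minimum(np.abs(est - truth), n_bins - np.abs(est - truth))
        assert np.mean(err <= 1) >= 0.95

    @pytest.mark.parametrize("noise,min_frac", [(0.5, 0.8), (2.0, 0.55)])
    def test_recovery_degrades_gracefully_with_poisson_noise(self, noise, min_frac):
        """Peak-bin recovery (within 2 bins, ~2.4 cm) under Poisson shot
        noise: high at moderate noise, degrading without a cliff when peak
        rates drop 4-fold."""
        n_bins, n_cells = 82, 30
        s = linear_traversals(PATH_LEN, 0.12, 400.0)
        spec = PlaceTuningSpec(peak_rate_hz=(2.0 / noise, 10.0 / noise))
        sess, lam, (centers, widths, peaks) = synth_fluorescence_session(
            s, n_cells, PATH_LEN, seed=1, spec=spec, poisson=True
        )
        rng = np.random.default_rng(1)
        counts = np.random.default_rng(2).poisson(lam / 15.0)
        pm = build_predictors(s, PATH_LEN, n_bins=n_bins)
        km = kernel_pinv(counts.astype(float), pm)
        K_true = true_kernel(centers, widths, peaks, 0.1, PATH_LEN, n_bins)
        est = np.argmax(km.K, axis=0)
        truth = np.argmax(K_true, axis=0)
        err = np.minimum(np.abs(est - truth), n_bins - np.abs(est - truth))
        assert np.mean(err <= 2) >= min_frac

    def test_zero_peak_rate_cell_has_zero_kernel_column(self):
        s = linear_traversals(PATH_LEN, 0.12, 200.0)
        n_bins = 40
        pm = build_predictors(s, PATH_LEN, n_bins=n_bins)
        lam = np.zeros((s.size, 1))
        km = kernel_pinv(lam, pm)
        assert np.allclose(km.K, 0.0)

    def test_seeded_determinism(self):
        s = linear_traversals(PATH_LEN, 0.12, 60.0)
        a = synth_fluorescence_session(s, 5, PATH_LEN, seed=3)
        b = synth_fluorescence_session(s, 5, PATH_LEN, seed=3)
        assert np.array_equal(a[0].F_cell, b[0].F_cell)


class TestComposedPipeline:
    def test_dff_qc_kernel_composition_shows_diagonal(self):
        """Full imaging chain on a synthetic session: ΔF/F + cell QC keep
        most cells, and the kernel of the (inferred) spike counts sorted
        by peak location is diagonally dominant."""
        n_bins, n_cells = 50, 30
        s = linear_traversals(PATH_LEN, 0.10, 400.0)
        rng = np.random.default_rng(4)
        sess, lam, _ = synth_fluorescence_session(
            s, n_cells, PATH_LEN, seed=4, noise_sd=1.0, neuropil_amp=2.0,
            spec=PlaceTuningSpec(peak_rate_hz=(4.0, 12.0)),
        )
        dff, valid = compute_dff(sess)
        mask, _ = filter_cells(dff[:, valid], sess.morphology[valid])
        assert mask.sum() >= 0.5 * n_cells
        counts = rng.poisson(lam / 15.0).astype(float)[:, np.nonzero(valid)[0][mask]]
        pm = build_predictors(s, PATH_LEN, n_bins=n_bins)
        km = normalize_sort(kernel_pinv(counts, pm))
        frac_ok = 0
        for j in range(km.K.shape[1]):
            col = np.abs(km.K[:, j])
            peak = int(np.argmax(col))
            lo, hi = max(peak - 3, 0), min(peak + 4, n_bins)
            frac_ok += col[lo:hi].sum() / max(col.sum(), 1e-12) > 0.5
        assert frac_ok / km.K.shape[1] > 0.6
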
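"""Kramers–Moyal estimation: exact limits, oracles, recovery, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import accubound as ab
from accubound.datasets import TrialEpoch
from accubound.km import MIN_BIN_COUNT, estimate_km_field

from conftest import LSA_DRIFT, LSA_NOISE


def epoch(samples, fs=250.0, t0=0):
    return TrialEpoch("s", "c", 0, np.asarray(samples, float), fs, t0)


class TestConcatenate:
    def test_joins_and_records_boundaries(self):
        y, b = ab.concatenate_trials([epoch([1, 2]), epoch([3, 4])])
        np.testing.assert_array_equal(y, [1, 2, 3, 4])
        np.testing.assert_array_equal(b, [0, 2])

    def test_single_epoch_identity(self):
        y, b = ab.concatenate_trials([epoch([5, 6, 7])])
        np.testing.assert_array_equal(y, [5, 6, 7])
        np.testing.assert_array_equal(b, [0])

    def test_mixed_fs_rejected(self):
        with pytest.raises(ValueError, match="sampling"):
            ab.concatenate_trials([epoch([1, 2], fs=250), epoch([1, 2], fs=100)])

    def test_two_epochs_match_bare_series_estimation(self):
        """Estimating from 2 stationary epochs ~ estimating the bare
        concatenated series: the single boundary contributes a negligible
        number of straddling pairs."""
        cfg = ab.GroundTruthConfig(
            drift_coeffs=LSA_DRIFT, noise_coeffs=LSA_NOISE, n_trials=2,
            n_channels=1, amplitude_scale=1.0, epoch_duration=40.0,
            event_latency=20.0, z0=4.93, seed=17)  # start at equilibrium
        eps = ab.generate_dataset(cfg).select()
        fit_eps = ab.reconstruct(eps, mode="concatenated", degrees=(1, 0))
        y, _ = ab.concatenate_trials(eps)
        f_series = estimate_km_field(y, fs=250.0)
        fit_series = ab.fit_langevin_model(f_series, degree_g=1, degree_h=0)
        np.testing.assert_allclose(fit_eps.drift_coeffs,
                                   fit_series.drift_coeffs, rtol=0.15, atol=0.1)
        np.testing.assert_allclose(fit_eps.noise_coeffs,
                                   fit_series.noise_coeffs, rtol=0.15)


class TestEstimateField:
    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_km_field(np.full(1000, 3.0), fs=250.0)

    def test_deterministic_ramp_moments_are_exact(self):
        t = np.arange(2000) / 250.0
        f = estimate_km_field(t, fs=250.0)
        occ = f.counts[:, 0] > 0
        for j, tau in enumerate(f.taus):
            np.testing.assert_allclose(f.A1[occ, j], tau, rtol=1e-9)
            np.testing.assert_allclose(f.A2[occ, j], tau ** 2, rtol=1e-9)

    def test_ou_central_bin_rates(self, long_ou_epoch):
        """A1/tau ~ -x and A2/tau ~ 1 near the center for g=-x, h=1.

        Tolerances are the replicate-calibrated spreads of these per-bin
        statistics (sd 0.30 and 0.027 over 20 generator seeds).
        """
        f = estimate_km_field(long_ou_epoch)
        i = int(np.argmin(np.abs(f.bin_centers)))
        tau0 = f.taus[0]
        assert abs(f.A1[i, 0] / tau0 - (-f.bin_centers[i])) < 1.2
        assert abs(f.A2[i, 0] / tau0 - 1.0) < 0.15

    def test_right_boundary_pairs_never_straddle_trials(self):
        # two well-separated ramps: a straddling pair would show |dx| ~ 99
        e1 = epoch(np.linspace(0.0, 1.0, 100))
        e2 = epoch(np.linspace(100.0, 101.0, 100))
        f = estimate_km_field([e1, e2], n_bins=20)
        occ = f.counts > 0
        assert np.max(np.abs(f.A1[occ.any(axis=1)])) < 0.5

    def test_brute_force_pairing_oracle_matches_exactly(self, ou_dataset):
        """Production moments equal exhaustive per-bin pairing (<=1e4 samples)."""
        eps = ou_dataset.select()[:8]
        f = estimate_km_field(eps, n_bins=50)
        y, bounds = ab.concatenate_trials(eps)
        lens = [e.n_samples for e in eps]
        lags = np.round(f.taus * 250.0).astype(int)
        max_lag = lags.max()
        edges = np.linspace(y.min(), y.max(), 51)
        for j, s in enumerate(lags):
            base, nxt = [], []
            for start, ln in zip(bounds, lens):
                idx = np.arange(start, start + ln - max_lag)
                base.append(y[idx])
                nxt.append(y[idx + s])
            base = np.concatenate(base)
            dx = np.concatenate(nxt) - base
            b = np.clip(np.digitize(base, edges) - 1, 0, 49)
            for k in range(50):
                sel = b == k
                assert f.counts[k, j] == sel.sum()
                if sel.sum():
                    np.testing.assert_allclose(f.A1[k, j], dx[sel].mean(),
                                               rtol=0, atol=1e-12)
                    np.testing.assert_allclose(f.A2[k, j], (dx[sel] ** 2).mean(),
                                               rtol=0, atol=1e-12)

    def test_low_occupancy_bins_masked(self, ou_dataset):
        f = estimate_km_field(ou_dataset.select()[0])
        assert np.all(f.counts[f.valid_mask].min(axis=1) >= MIN_BIN_COUNT)
        assert np.all(np.isnan(f.D1[~f.valid_mask]) | (f.D2[~f.valid_mask] >= 0))


class TestExtrapolate:
    def test_linear_moment(self):
        taus = np.arange(1, 11) / 250.0
        assert ab.extrapolate_moment(2 * taus, taus) == pytest.approx(2.0)

    def test_quadratic_bias_removed_exactly(self):
        taus = np.arange(1, 11) / 250.0
        vals = 2 * taus + 3 * taus ** 2
        assert ab.extrapolate_moment(vals, taus, order=2) == pytest.approx(2.0)

    def test_noisy_moment_unbiased(self):
        # single-draw sd of the rate is ~0.051 (Monte-Carlo); test the mean
        # of 20 replicate draws at the 5e-2 tolerance (~4 sigma)
        taus = np.arange(1, 11) / 250.0
        rng = np.random.default_rng(0)
        vals = [ab.extrapolate_moment(
            2 * taus + 3 * taus ** 2 + rng.normal(0, 1e-3, 10), taus)
            for _ in range(20)]
        assert abs(np.mean(vals) - 2.0) < 5e-2

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            ab.extrapolate_moment([1.0, 2.0], [0.1, 0.2], order=2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c1=st.floats(-5, 5), c2=st.floats(-5, 5))
    def test_exact_polynomial_recovery(self, c1, c2):
        taus = np.arange(1, 11) / 250.0
        vals = c1 * taus + c2 * taus ** 2
        assert ab.extrapolate_moment(vals, taus) == pytest.approx(c1, abs=1e-8)


class TestFitModel:
    def _field(self, centers, d1, d2):
        n, nt = len(centers), 10
        return ab.KMField(
            bin_centers=np.asarray(centers, float),
            taus=np.arange(1, nt + 1) / 250.0,
            A1=np.zeros((n, nt)), A2=np.zeros((n, nt)),
            counts=np.full((n, nt), 100), D1=np.asarray(d1, float),
            D2=np.asarray(d2, float), valid_mask=np.ones(n, bool))

    def test_exact_linear_drift(self):
        x = np.linspace(-2, 2, 30)
        m = ab.fit_langevin_model(self._field(x, 3 * x + 1, np.ones_like(x)),
                                  degree_g=1, degree_h=0)
        np.testing.assert_allclose(m.drift_coeffs, [3.0, 1.0], atol=1e-10)

    def test_exact_quadratic_noise(self):
        x = np.linspace(-2, 2, 30)
        m = ab.fit_langevin_model(self._field(x, x, (x ** 2 + 1) ** 2),
                                  degree_g=1, degree_h=2)
        np.testing.assert_allclose(m.noise_coeffs, [1.0, 0.0, 1.0], atol=1e-9)

    def test_insufficient_bins_rejected(self):
        x = np.linspace(-1, 1, 3)
        f = self._field(x, x, np.ones_like(x))
        with pytest.raises(ValueError, match="valid bins"):
            ab.fit_langevin_model(f, degree_g=3, degree_h=2)


class TestReconstruct:
    def test_single_trial_returns_one_model_per_epoch(self, ou_dataset):
        eps = ou_dataset.select()[:5]
        models = ab.reconstruct(eps, mode="single_trial", degrees=(1, 0))
        assert len(models) == 5
        assert all(m.degree_g == 1 and m.degree_h == 0 for m in models)

    def test_pooled_over_identical_copies_equals_single_fit(self, ou_dataset):
        e = ou_dataset.select()[0]
        copies = [TrialEpoch("s", "c", i, e.samples, e.fs, e.t0_index)
                  for i in range(4)]
        pooled = ab.reconstruct(copies, mode="pooled", degrees=(1, 2))
        single = ab.reconstruct([e], mode="single_trial", degrees=(1, 2))[0]
        np.testing.assert_allclose(pooled.drift_coeffs, single.drift_coeffs,
                                   rtol=1e-8)
        np.testing.assert_allclose(pooled.noise_coeffs, single.noise_coeffs,
                                   rtol=1e-8)

    def test_concatenated_ou_recovery_within_10pct(self):
        """Round trip: OU ground truth -> reconstruction, >=1e5 samples.

        A 2e6-sample series keeps the Monte-Carlo spread of the slope
        estimate (~13% relative at 1e5) below the 10% band.
        """
        cfg = ab.GroundTruthConfig(
            drift_coeffs=LSA_DRIFT, noise_coeffs=LSA_NOISE, n_trials=1,
            n_channels=1, amplitude_scale=1.0, epoch_duration=8000.0,
            event_latency=4000.0, seed=42)
        m = ab.reconstruct(ab.generate_dataset(cfg), mode="concatenated",
                           degrees=(1, 0))
        assert abs(m.drift_coeffs[0] - (-0.29)) < 0.029
        assert abs(m.noise_coeffs[0] - 1.78) < 0.178

    def test_pure_brownian_limit(self):
        cfg = ab.GroundTruthConfig(drift_coeffs=(0.0,), noise_coeffs=(2.0,),
                                   n_trials=60, n_channels=1,
                                   amplitude_scale=1.0, seed=700)
        m = ab.reconstruct(ab.generate_dataset(cfg), mode="concatenated",
                           degrees=(1, 0))
        assert abs(m.drift_coeffs[0]) < 0.25  # slope -> 0 (replicate sd 0.056)
        assert abs(m.noise_coeffs[0] - 2.0) < 0.2

    def test_consistency_error_shrinks_with_samples(self):
        errs = {}
        for dur, seeds in [(40.0, (0, 1, 2)), (4000.0, (0, 1, 2))]:
            e = []
            for s in seeds:
                cfg = ab.GroundTruthConfig(
                    drift_coeffs=LSA_DRIFT, noise_coeffs=LSA_NOISE,
                    n_trials=1, n_channels=1, amplitude_scale=1.0,
                    epoch_duration=dur, event_latency=dur / 2, seed=900 + s)
                m = ab.reconstruct(ab.generate_dataset(cfg),
                                   mode="concatenated", degrees=(1, 0))
                e.append(abs(m.drift_coeffs[0] - (-0.29)))
            errs[dur] = np.median(e)
        assert errs[4000.0] < errs[40.0]

    def test_rescaling_covariance(self, ou_dataset):
        eps = ou_dataset.select()[:20]
        k = 1e3
        m1 = ab.reconstruct(eps, mode="concatenated", degrees=(1, 0))
        m2 = ab.reconstruct(eps, mode="concatenated", degrees=(1, 0), scale=k)
        assert m2.drift_coeffs[0] == pytest.approx(m1.drift_coeffs[0], rel=1e-6)
        assert m2.drift_coeffs[1] == pytest.approx(k * m1.drift_coeffs[1], rel=1e-6)
        assert m2.noise_coeffs[0] == pytest.approx(k * m1.noise_coeffs[0], rel=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ab.reconstruct([], mode="pooled")
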
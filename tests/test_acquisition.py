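"""Data model, cropping, averaging algebra, and the noise variance law."""

import numpy as np
import pytest
from scipy import stats

import kspace_design as kd
from kspace_design.acquisition import (
    load_dataset_h5,
    load_dataset_npz,
    save_dataset_h5,
    save_dataset_npz,
)


class TestCropKSpace:
    def test_full_grid_is_identity(self, ds16):
        assert np.array_equal(kd.crop_kspace(ds16, 16), ds16.s)

    def test_centered_subgrid_convention(self):
        # N0=4 -> conceptual indices {-2,-1,0,1}; N=2 keeps {-1,0} = positions 1,2
        s = np.arange(4 * 4 * 2, dtype=complex).reshape(4, 4, 2)
        out = kd.crop_kspace(s, 2)
        assert np.array_equal(out, s[1:3, 1:3, :])

    def test_energy_never_increases(self, rng):
        s = rng.standard_normal((8, 8, 2)) + 1j * rng.standard_normal((8, 8, 2))
        full = np.sum(np.abs(s) ** 2)
        for N in (2, 4, 6, 8):
            cropped = np.sum(np.abs(kd.crop_kspace(s, N)) ** 2)
            assert cropped <= full + 1e-12
        # equality iff all discarded samples vanish
        s_zeroed = np.zeros_like(s)
        s_zeroed[2:6, 2:6, :] = s[2:6, 2:6, :]
        assert np.isclose(np.sum(np.abs(kd.crop_kspace(s_zeroed, 4)) ** 2), np.sum(np.abs(s_zeroed) ** 2))

    @pytest.mark.parametrize("bad_N", [3, 18, 0])
    def test_invalid_grid_rejected(self, ds16, bad_N):
        with pytest.raises(ValueError):
            kd.crop_kspace(ds16, bad_N)


class TestEffectiveAverages:
    def test_identity_at_full_grid(self):
        w = kd.effective_averages(np.full(8, 8.0), N=8, N0=8)
        assert np.allclose(w, 8.0)

    def test_bandwidth_gain(self):
        # halving the grid doubles the effective averages per actual average
        assert np.allclose(kd.effective_averages(np.array([2.0]), N=160, N0=320), 4.0)

    def test_round_trip(self, rng):
        q = rng.uniform(0.5, 20.0, size=12)
        w = kd.effective_averages(q, N=12, N0=48)
        assert np.allclose(kd.actual_averages(w, N=12, N0=48), q)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kd.effective_averages(np.array([1.0, 0.0]), N=2, N0=4)


class TestSimulateNoisyAcquisition:
    def test_zero_noise_returns_signal(self, ds16):
        pat = kd.uniform_pattern(8, 16, 8)
        s_N = kd.crop_kspace(ds16, 8)
        acq = kd.simulate_noisy_acquisition(s_N, pat, kd.NoiseModel(sigma=0.0, seed=1), t=0)
        assert np.array_equal(acq.d, s_N)

    def test_determinism(self, ds16):
        pat = kd.uniform_pattern(8, 16, 8)
        s_N = kd.crop_kspace(ds16, 8)
        noise = kd.NoiseModel(sigma=0.3, seed=7)
        a = kd.simulate_noisy_acquisition(s_N, pat, noise, t=3)
        b = kd.simulate_noisy_acquisition(s_N, pat, noise, t=3)
        assert np.array_equal(a.d, b.d)

    def test_variance_law_chi2(self):
        """Per-line variance sigma^2/w_m within 99% chi-square bounds."""
        N, L, sigma = 8, 2, 0.7
        w = np.array([1.0, 2.0, 4.0, 8.0, 8.0, 4.0, 2.0, 1.0]) * 4
        pat = kd.AveragingPattern(N=N, w=w * (8 * 64 / N / w.sum()), N0=64, w0=8)
        s_N = np.zeros((N, N, L), dtype=complex)
        draws = 625  # 625 draws x 8 readout x 2 channels = 1e4 samples per line
        sq = np.zeros(N)
        noise = kd.NoiseModel(sigma=sigma, seed=42)
        for t in range(draws):
            acq = kd.simulate_noisy_acquisition(s_N, pat, noise, t=t)
            sq += np.sum(np.abs(acq.d) ** 2, axis=(1, 2))
        k = draws * N * L  # complex samples per line -> 2k chi-square dof
        lo = stats.chi2.ppf(0.005, 2 * k) / (2 * k)
        hi = stats.chi2.ppf(0.995, 2 * k) / (2 * k)
        ratio = (sq / k) / (sigma ** 2 / pat.w)
        assert np.all(ratio > lo) and np.all(ratio < hi)

    def test_variance_halves_when_w_doubles(self, ds16):
        N, L = 8, 2
        s_N = np.zeros((N, N, L), dtype=complex)
        noise = kd.NoiseModel(sigma=1.0, seed=5)
        budget = kd.uniform_pattern(N, 16, 8).w.sum()
        w1 = np.full(N, budget / N)
        var = {}
        for scale in (1.0, 2.0):
            pat = kd.AveragingPattern(N=N, w=w1 * scale, N0=16, w0=8 * scale)
            sq = 0.0
            for t in range(400):
                acq = kd.simulate_noisy_acquisition(s_N, pat, noise, t=t)
                sq += np.sum(np.abs(acq.d) ** 2)
            var[scale] = sq
        assert var[2.0] / var[1.0] == pytest.approx(0.5, rel=0.05)

    def test_noise_whiteness_across_channels(self):
        """Empirical covariance of d - s is diagonal (no interchannel mixing)."""
        N, L = 4, 3
        s_N = np.zeros((N, N, L), dtype=complex)
        pat = kd.AveragingPattern(N=N, w=np.full(N, 8.0 * 16 ** 2 / N / 4), N0=16, w0=8)
        noise = kd.NoiseModel(sigma=1.0, seed=9)
        samples = []
        for t in range(2000):
            acq = kd.simulate_noisy_acquisition(s_N, pat, noise, t=t)
            samples.append(acq.d.reshape(-1, L))
        z = np.concatenate(samples)
        cov = z.conj().T @ z / z.shape[0]
        off = np.abs(cov - np.diag(np.diag(cov))).max()
        assert off < 0.05 * np.abs(np.diag(cov)).min()

    def test_shared_realization_crop_equals_direct(self):
        """Master-grid noise cropped to N is bit-identical to the direct N draw."""
        noise = kd.NoiseModel(sigma=0.4, seed=21)
        full = noise.noise(5, 16, 2)
        assert np.array_equal(noise.noise(5, 16, 2, N=8), full[4:12, 4:12, :])

    def test_shape_mismatch_rejected(self, ds16):
        pat = kd.uniform_pattern(8, 16, 8)
        with pytest.raises(ValueError):
            kd.simulate_noisy_acquisition(ds16.s, pat, kd.NoiseModel(sigma=0.1), t=0)


class TestNormalizeDataset:
    def test_peak_magnitude_is_one(self, ds16):
        peak = np.abs(ds16.channel_images()).max()
        assert peak == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_and_scale_invariant(self, ds16):
        from dataclasses import replace

        again = kd.normalize_dataset(ds16)
        assert np.allclose(again.s, ds16.s)
        scaled = kd.normalize_dataset(replace(ds16, s=5.0 * ds16.s))
        assert np.allclose(scaled.s, ds16.s)

    def test_zero_dataset_rejected(self, ds16):
        from dataclasses import replace

        with pytest.raises(ValueError):
            kd.normalize_dataset(replace(ds16, s=np.zeros_like(ds16.s)))


class TestScanTime:
    def test_uniform_baseline(self):
        pat = kd.uniform_pattern(320, 320, 8)
        assert kd.scan_time(pat) == 2560

    def test_budget_conserved_after_rounding_any_N(self):
        for N in (4, 8, 12, 16):
            q = kd.round_to_integer_averages(kd.uniform_pattern(N, 16, 8))
            assert kd.scan_time(q) == 8 * 16

    def test_matches_bruteforce_sum(self, rng):
        q = rng.integers(0, 10, size=16)
        q[0] += 8 * 16 - q.sum()
        ip = kd.IntegerPattern(N=16, q=q, N0=16, w0=8)
        assert kd.scan_time(ip) == sum(int(v) for v in q)


class TestDatasetIO:
    def test_h5_and_npz_round_trip(self, ds16, tmp_path):
        for save, load, name in [
            (save_dataset_h5, load_dataset_h5, "ds.h5"),
            (save_dataset_npz, load_dataset_npz, "ds.npz"),
        ]:
            path = tmp_path / name
            save(path, ds16)
            back = load(path)
            # float32 storage bounds the round-trip error
            assert np.allclose(back.s, ds16.s, atol=1e-6)
            assert np.allclose(back.maps, ds16.maps, atol=1e-6)
            assert back.fov_mm == ds16.fov_mm and back.id == ds16.id
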
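"""Bilevel design machinery: loss, references, inner SGD loops, outer search."""

import numpy as np
import pytest

import kspace_design as kd
from kspace_design.optimize import outer_loss_for
from kspace_design.recon import Reconstructor


class TestTrainingLoss:
    def test_zero_at_equality_and_unit_energy(self, rng):
        x = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        assert kd.training_loss(x, x) == 0.0
        u = x / np.linalg.norm(x)
        assert kd.training_loss(u, np.zeros_like(u)) == pytest.approx(1.0)

    def test_matches_double_loop_summation(self, rng):
        x = rng.standard_normal((5, 3)) + 1j * rng.standard_normal((5, 3))
        r = rng.standard_normal((5, 3)) + 1j * rng.standard_normal((5, 3))
        acc = 0.0
        for i in range(5):
            for j in range(3):
                acc += abs(x[i, j] - r[i, j]) ** 2
        assert kd.training_loss(x, r) == pytest.approx(acc)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kd.training_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMakeReference:
    def test_full_resolution_equals_combined_image(self, ds16):
        r = kd.make_reference(ds16, 16)
        expect = kd.coil_combine(kd.ifft2c(ds16.s), ds16.maps)
        assert np.allclose(r, expect)

    def test_single_coil_truncation_oracle(self, single_coil_ds):
        """r^N equals the ideal image convolved with the N-point periodic
        Dirichlet (sinc-like) kernel; checked by direct DFT truncation."""
        N, N0 = 4, 16
        r = kd.make_reference(single_coil_ds, N)
        s = single_coil_ds.s[:, :, 0]
        keep = np.zeros((N0, N0))
        lo = N0 // 2 - N // 2
        keep[lo : lo + N, lo : lo + N] = 1.0
        expect = kd.ifft2c(s * keep)
        assert np.allclose(r, expect, atol=1e-12)


class _ToyScale(Reconstructor):
    """Scalar toy: reconstruction = p * (inverse transform of the data)."""

    kind = "toy"

    def __init__(self, maps, N, p=0.0):
        super().__init__(maps, N)
        self.p = float(p)

    def reconstruct(self, d, w=None):
        return self.p * kd.ifft2c(d[:, :, 0])

    def get_params(self):
        return np.array([self.p])

    def set_params(self, p):
        self.p = float(np.asarray(p).ravel()[0])

    def loss_and_grads(self, s_N, z_N, w, r, need_wgrad=False):
        d = self.data_from(s_N, z_N, w)
        base = kd.ifft2c(d[:, :, 0])
        e = self.p * base - r
        loss = float(np.sum(np.abs(e) ** 2))
        grad = np.array([2.0 * np.real(np.vdot(base, e))])
        return loss, grad, None


class TestInnerUniform:
    def test_scalar_toy_converges_to_wiener_weight(self, small_train):
        """SGD recovers the closed-form least-squares scale p* within 1%."""
        train = small_train
        train.noise = kd.NoiseModel(sigma=0.5, seed=6)
        N = 16
        recon = _ToyScale(train.datasets[0].maps, N, p=0.0)
        sched = kd.InnerSchedule(epochs_joint=200, lr_p=0.002, decay_p=0.995, batch_size=2)
        kd.inner_optimize_uniform(recon, N, train, sched, seed=0)
        num = den = 0.0
        w = kd.uniform_pattern(N, 16, train.w0).w
        for t in train.train_indices:
            ds = train.datasets[t]
            z = train.noise.noise(t, 16, ds.L, N=N)
            d = ds.s + z / np.sqrt(w)[:, None, None]
            base = kd.ifft2c(d[:, :, 0])
            r = kd.make_reference(ds, N)
            num += np.real(np.vdot(base, r))
            den += np.real(np.vdot(base, base))
        assert recon.p == pytest.approx(num / den, rel=0.01)

    def test_descent_and_determinism(self, small_train):
        train = small_train
        train.noise = kd.NoiseModel(sigma=0.3, seed=2)
        sched = kd.InnerSchedule(epochs_joint=5, lr_p=0.01, decay_p=0.99, batch_size=4)
        runs = []
        for _ in range(2):
            ap = kd.ApodizedReconstructor(train.datasets[0].maps, 8)
            res = kd.inner_optimize_uniform(ap, 8, train, sched, seed=11)
            runs.append(res)
        assert runs[0].loss_trace[-1] <= runs[0].loss_trace[0]
        assert np.array_equal(runs[0].p_hat, runs[1].p_hat)

    def test_empty_split_rejected(self, small_train):
        import dataclasses

        train = dataclasses.replace(small_train, split={"train": [], "val": [0], "test": [1]})
        ap = kd.ApodizedReconstructor(small_train.datasets[0].maps, 8)
        with pytest.raises(ValueError):
            kd.inner_optimize_uniform(ap, 8, train, kd.InnerSchedule(), seed=0)


class TestInnerNonuniform:
    def test_budget_and_rounding_artifacts(self, small_train):
        train = small_train
        train.noise = kd.NoiseModel(sigma=0.4, seed=3)
        N = 8
        ap = kd.ApodizedReconstructor(train.datasets[0].maps, N)
        sched = kd.InnerSchedule(epochs_joint=6, epochs_refine=2, lr_p=0.5, lr_w=0.1, batch_size=4)
        res = kd.inner_optimize_nonuniform(ap, N, train, sched, seed=4)
        budget = kd.uniform_pattern(N, 16, train.w0).budget
        assert res.w_hat.sum() == pytest.approx(budget, rel=1e-9)
        assert res.w_hat.min() > 0
        assert int(res.q_hat.q.sum()) == train.w0 * 16
        assert np.allclose(res.w_final, res.q_hat.q * 16 / N)

    def test_low_snr_averaging_concentrates_at_center(self, small_train):
        """With strong noise the trained pattern puts at least as many
        averages on the central line as on the outermost line."""
        train = small_train
        train.noise = kd.NoiseModel(sigma=1.5, seed=8)
        N = 8
        ap = kd.ApodizedReconstructor(train.datasets[0].maps, N)
        sched = kd.InnerSchedule(epochs_joint=20, epochs_refine=2, lr_p=0.5, lr_w=0.2, batch_size=4)
        res = kd.inner_optimize_nonuniform(ap, N, train, sched, seed=5)
        q = res.q_hat.q
        center = max(q[N // 2 - 1], q[N // 2])
        assert center >= max(q[0], q[-1])


class TestOuterSelect:
    def test_single_candidate_returned(self, small_train):
        train = small_train
        train.noise = kd.NoiseModel(sigma=0.2, seed=1)
        sched = kd.InnerSchedule(epochs_joint=2, lr_p=0.5, batch_size=4)
        res = kd.outer_select_N("apodized", [8], train, sched=sched, seed=0)
        assert res.N_hat == 8 and len(res.records) == 1

    def test_outer_loss_replay_oracle(self, small_train):
        """Recomputing the outer loss from the stored artifacts reproduces
        the recorded value exactly."""
        train = small_train
        train.noise = kd.NoiseModel(sigma=0.2, seed=1)
        sched = kd.InnerSchedule(epochs_joint=3, lr_p=0.5, batch_size=4)
        res = kd.outer_select_N("apodized", [8, 12], train, sched=sched, seed=2)
        for rec in res.records:
            fresh = kd.ApodizedReconstructor(train.datasets[0].maps, rec["N"])
            fresh.set_params(rec["p_hat"])
            replay = outer_loss_for(fresh, train, rec["N"], rec["w_final"])
            assert replay == pytest.approx(rec["outer_loss"], abs=1e-10)

    def test_zero_noise_selects_full_resolution(self, small_train):
        """With sigma = 0 there is no noise to trade resolution against, so
        the outer search must keep the full grid."""
        train = small_train
        train.noise = kd.NoiseModel(sigma=0.0, seed=0)
        sched = kd.InnerSchedule(epochs_joint=2, lr_p=0.2, batch_size=4)
        res = kd.outer_select_N("apodized", [8, 12, 16], train, sched=sched, seed=1)
        assert res.N_hat == 16

    def test_nonuniform_at_least_as_good_as_uniform(self, small_train):
        """Uniform averaging lies in the nonuniform feasible set, so the
        trained nonuniform inner loss cannot be meaningfully worse."""
        train = small_train
        train.noise = kd.NoiseModel(sigma=0.8, seed=4)
        for N in (8, 12):
            ap_u = kd.ApodizedReconstructor(train.datasets[0].maps, N)
            res_u = kd.inner_optimize_uniform(
                ap_u, N, train, kd.InnerSchedule(epochs_joint=15, lr_p=0.5, batch_size=4), seed=3
            )
            ap_n = kd.ApodizedReconstructor(train.datasets[0].maps, N)
            res_n = kd.inner_optimize_nonuniform(
                ap_n,
                N,
                train,
                kd.InnerSchedule(epochs_joint=13, epochs_refine=2, lr_p=0.5, lr_w=0.2, batch_size=4),
                seed=3,
            )
            assert res_n.loss_trace[-1] <= res_u.loss_trace[-1] * 1.02

    def test_invalid_mode_rejected(self, small_train):
        with pytest.raises(ValueError):
            kd.outer_select_N("apodized", [8], small_train, mode="adaptive")
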
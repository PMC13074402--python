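"""Train the compact CNN reconstructor on a tiny synthetic cohort.

The network maps the 2L real/imaginary planes of the zero-padded
per-channel images to the 2 planes of the combined image.  A few Adam
epochs on a small cohort are enough to show the training loss falling and
the trained network beating its untrained self; this demonstrates the
plugin interface and its hand-written backpropagation, not state-of-the-art
learned reconstruction.
"""

import numpy as np

import kspace_design as kd

spec = kd.PhantomSpec(N0=32, L=2, T=12, seed=4)
train = kd.assemble_training_set(spec, w0=8)
_, _, roi = kd.generate_phantom(spec, 0)
sigma = kd.calibrate_sigma(train, target_snr=5.0, roi=roi)
train.noise = kd.NoiseModel(sigma=sigma, seed=1)

N = 16
cnn = kd.CnnReconstructor(train.datasets[0].maps, N, width=8, seed=0)
sched = kd.InnerSchedule(epochs_joint=30, lr_p=3e-3, decay_p=0.99, batch_size=4, optimizer_p="adam")
res = kd.inner_optimize_uniform(cnn, N, train, sched, seed=0)
print(f"training loss: epoch 1 = {res.loss_trace[0]:.3f} -> epoch {len(res.loss_trace)} = {res.loss_trace[-1]:.3f}")

# score on the held-out test split against the high-resolution reference
pat = kd.uniform_pattern(N, spec.N0, train.w0)
for label, recon in [("trained", cnn), ("untrained", kd.CnnReconstructor(train.datasets[0].maps, N, width=8, seed=0))]:
    errs = []
    for t in train.split["test"]:
        ds = train.datasets[t]
        recon.set_maps(ds.maps)
        z = train.noise.noise(t, spec.N0, ds.L, N=N)
        d = recon.data_from(kd.crop_kspace(ds, N), z, pat.w)
        errs.append(kd.nrmse(recon.reconstruct(d), kd.make_reference(ds, spec.N0)))
    print(f"{label:>9} CNN: mean test NRMSE = {np.mean(errs):.3f}")
# The trained network should come out with a much lower NRMSE.
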
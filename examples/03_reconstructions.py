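"""Reconstruct one noisy low-resolution acquisition with all three methods.

Simulates an SNR-2-like acquisition at half resolution and compares apodized
(windowed Fourier), SENSE-TV (ADMM), and the compact CNN plugin (untrained,
so it serves only as an interface demonstration) against the matched
noise-free reference.
"""

import numpy as np

import kspace_design as kd

spec = kd.PhantomSpec(N0=64, L=4, T=4, seed=1)
train = kd.assemble_training_set(spec, w0=8)
_, _, roi = kd.generate_phantom(spec, 0)
sigma = kd.calibrate_sigma(train, target_snr=2.0, roi=roi)
train.noise = kd.NoiseModel(sigma=sigma, seed=3)

ds = train.datasets[0]
N = 32
pat = kd.uniform_pattern(N, spec.N0, train.w0)
acq = kd.simulate_noisy_acquisition(kd.crop_kspace(ds, N), pat, train.noise, t=0)
r_hi = kd.make_reference(ds, spec.N0)

conventional = kd.coil_combine(kd.zero_pad_recon(acq.d, spec.N0), ds.maps)
print(f"conventional recon:      NRMSE={kd.nrmse(conventional, r_hi):.3f}  SSIM={kd.ssim(conventional, r_hi):.3f}")

hamming = np.outer(np.hamming(N), np.hamming(N))
apod = kd.ApodizedReconstructor(ds.maps, N, window=hamming)
x_apod = apod.reconstruct(acq.d)
print(f"apodized (Hamming):      NRMSE={kd.nrmse(x_apod, r_hi):.3f}  SSIM={kd.ssim(x_apod, r_hi):.3f}")

stv = kd.SenseTVReconstructor(ds.maps, N, lam=1.0)
x_tv = stv.reconstruct(acq.d, pat.w)
print(f"SENSE-TV (lambda=1.0):   NRMSE={kd.nrmse(x_tv, r_hi):.3f}  SSIM={kd.ssim(x_tv, r_hi):.3f}")

cnn = kd.CnnReconstructor(ds.maps, N, width=8, seed=0)
x_cnn = cnn.reconstruct(acq.d)
print(f"CNN (untrained weights): NRMSE={kd.nrmse(x_cnn, r_hi):.3f}  SSIM={kd.ssim(x_cnn, r_hi):.3f}")
# Lower NRMSE / higher SSIM is better; the untrained CNN is expected to be
# poor until fitted with the inner optimization loop.
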
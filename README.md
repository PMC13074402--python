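# kspace-design

Joint optimization of MRI k-space coverage, signal-averaging patterns, and
denoising/reconstruction parameters under a fixed scan-time budget.

## The problem

Computational MRI denoising is usually designed with the acquisition held
fixed, yet classical experiment design teaches that shrinking k-space
coverage (lowering spatial resolution) and spending the saved repetitions
on signal averaging can buy large SNR gains.  This package treats the
acquisition and the reconstruction as one design problem.  With a scan-time
budget of `w0*N0` repetitions (the reference scan: `N0` phase-encode lines,
uniform `w0`-fold averaging), a design chooses

- the grid size `N <= N0`,
- effective per-line averages `w_m` with `sum(w) = w0*N0^2/N`
  (line averaging plus the readout-bandwidth SNR gain), and
- the parameters `p` of a reconstruction `g_{p,N,w}(d)` that always outputs
  a full-resolution `N0 x N0` image,

by a bilevel optimization: for each candidate `N`, fit `(p, w)` by
projected stochastic gradient descent on `sum_t ||g(s_t + z_t/sqrt(w)) -
r_t^N||_2^2` against matched-resolution references, then pick the `N` whose
trained design best reproduces the *high-resolution* references `r_t^{N0}`.
Continuous averaging patterns are rounded to integers by a greedy scheme
that is provably optimal for the l1 rounding cost and conserves the TR
budget exactly.

Three reconstruction families sit behind one interface: apodized
(trainable k-space window + Fourier + SENSE combination), SENSE-TV
(`argmin_x sum_m w_m ||(Ex-d)_m||^2 + lambda*||Dx||_1` via 50-iteration
ADMM, differentiated by forward-mode tangent propagation), and a compact
CNN plugin.  A synthetic multicoil brain-like phantom suite with SNR
calibration makes every stage runnable on a workstation.  See
`docs/methods.md` for the model, conventions, and numerical choices.

## Worked example

`examples/04_design_search.py` runs the whole pipeline at SNR 2 on a
64-grid synthetic cohort (4 coils, budget 512 TRs) with the apodized
reconstructor and nonuniform averaging:

```
target SNR 2.0 -> sigma = 1.1724
   N   outer loss   inner loss (final)
  20      613.275               7.3516
  32      638.996              25.9463
  44      750.801              44.6271
  56      865.311              61.4670
  64      956.741              73.7841
selected N_hat = 20 (31% of full resolution)
optimized integer averages: center=26, edge=25 (low-frequency lines receive the most averaging)
test-split metrics at each candidate:
 N    nrmse     ssim  one_minus_nrmse
20 0.183345 0.543080         0.816655
32 0.189129 0.541175         0.810871
44 0.207544 0.504336         0.792456
56 0.225227 0.469040         0.774773
64 0.237409 0.448137         0.762591
```

At this low SNR the outer search selects roughly a third of the nominal
resolution — the noise reduction from concentrated averaging outweighs the
truncation error — and the optimized pattern puts its extra averages on the
central (low-frequency) k-space lines.  Rerun with `target_snr = 10` and
the selected grid moves up.  The other examples cover phantom generation
and SNR calibration (`01`), scan-time bookkeeping and pattern rounding
(`02`), and the three reconstructors on one noisy acquisition (`03`).

A thin CLI wraps the same machinery:

```bash
kspace-design optimize --snr 2 --recon apodized --averaging nonuniform --out runs/snr2
kspace-design evaluate --snr 2 --recon apodized --averaging nonuniform --out runs/snr2-eval
kspace-design make-fixtures --seed 0 --out fixtures/
```

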
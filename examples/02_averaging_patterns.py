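"""Scan-time bookkeeping: uniform patterns, budget projection, integer rounding.

Every design in this package spends exactly the same number of TRs as the
reference experiment (N0 lines, uniform w0-fold averaging).  This script
shows the effective-averages algebra, projects a perturbed pattern back onto
the budget, and rounds it to integer actual averages with the
center-preserving greedy rule.
"""

import numpy as np

import kspace_design as kd

N0, w0, N = 64, 8, 32
uni = kd.uniform_pattern(N, N0, w0)
print(f"reference: {N0} lines x {w0} averages = {w0 * N0} TRs")
print(f"at N={N}: uniform effective averages w = {uni.w[0]:.0f} per line "
      f"(x{N0 // N} from line averaging, x{N0 // N} from readout bandwidth)")
print(f"effective budget sum(w) = {uni.w.sum():.0f} = w0*N0^2/N")

rng = np.random.default_rng(0)
w_perturbed = uni.w * np.exp(rng.uniform(-0.5, 0.5, N))
w_feasible = kd.project_to_budget(w_perturbed, uni.budget)
print(f"perturbed sum {w_perturbed.sum():.1f} -> projected sum {w_feasible.sum():.1f}")

q = kd.round_to_integer_averages(kd.AveragingPattern(N=N, w=w_feasible, N0=N0, w0=w0))
print(f"integer actual averages: sum(q) = {q.q.sum()} TRs (exactly the budget)")
print(f"central lines get {q.q[N // 2 - 1]},{q.q[N // 2]}; outermost get {q.q[0]},{q.q[-1]}")
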
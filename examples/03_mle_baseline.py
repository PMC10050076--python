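"""The step-distance MLE baseline and its 1/sqrt(N) precision law.

For 2-D Brownian motion, step lengths over a lag tau are Rayleigh
distributed and the MLE for D has the closed form sum(r^2)/(4 N tau).
Each step costs two single-molecule images, which is the accounting used
when comparing against stack-based evaluation at matched image budgets.
"""

import numpy as np

import blurmap as bm
from blurmap.mle import (images_to_steps_accounting, mle_estimate,
                         relative_se, simulate_step_sample)

rng = np.random.default_rng(0)
D_true, tau = 3.0, 0.009

sample = simulate_step_sample(D_true, tau, 10_000, rng)
print(f"D = {D_true} µm²/s, 10,000 steps: D_hat = {mle_estimate(sample):.4f}")

print("\nrelative SE vs number of steps (analytic 1/sqrt(N) vs Monte-Carlo):")
for N in (10, 50, 200, 1000):
    est = np.array([mle_estimate(simulate_step_sample(D_true, tau, N, rng))
                    for _ in range(3000)])
    print(f"  N={N:5d}: analytic {relative_se(N):6.3f}   "
          f"empirical {est.std(ddof=1)/D_true:6.3f}")

print("\nimage-budget accounting (two images per step):")
for n_images in (40, 80, 160):
    n_steps = images_to_steps_accounting(n_images)
    print(f"  {n_images:3d} images -> {n_steps:2d} steps -> "
          f"MLE relative SE {relative_se(n_steps)*100:.1f}%")
print("stack-based evaluation of the same image budgets reaches roughly "
      "half\nthese errors (see 05_precision_vs_budget.py).")
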
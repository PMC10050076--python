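"""Simulate motion-blurred single-molecule images.

Builds Brownian trajectories over one 9 ms camera exposure at several
diffusion coefficients and renders them through the Gaussian PSF onto
the 160 nm pixel grid.  Prints the fixed micro-step length, the
end-to-end MSD against the 4*D*t law, and the photon budget per image.
"""

import numpy as np

import blurmap as bm

config = bm.SimConfig()
rng = np.random.default_rng(0)

print(f"exposure {config.exposure_time*1e3:.0f} ms resolved into "
      f"{config.n_micro_steps} micro-steps\n")

for D in (1.0, 3.0, 5.0):
    step = config.step_length_nm(D)
    trajs = bm.simulate_trajectories(D, 2000, config, rng)
    disp_um = (trajs[:, -1] - trajs[:, 0]).astype(float) / 1e3
    msd = float((disp_um**2).sum(axis=1).mean())
    print(f"D = {D} µm²/s: micro-step {step:5.2f} nm, "
          f"MSD {msd:.4f} µm² (theory 4Dt = {4*D*config.exposure_time:.4f})")

print("\nrendering 1000 images at D = 2, 90 photons/ms ...")
trajs = bm.simulate_trajectories(2.0, 1000, config, rng)
imgs, _ = bm.render_images(trajs, config, 90.0, rng, add_background=False)
print(f"mean total counts/image {imgs.sum(axis=(1, 2)).mean():.0f} "
      f"(expected 90 photons/ms x 9 ms = 810)")
# a molecule's image is its trajectory convolved with the PSF: the
# radial spread of the rendered spot grows with D
for D in (0.0, 2.0, 5.0):
    t = bm.simulate_trajectories(D, 1000, config, rng)
    im, _ = bm.render_images(t, config, 90.0, rng, add_background=False)
    yy, xx = np.mgrid[0:7, 0:7]
    tot = im.sum(axis=(1, 2))
    cx = (im * xx).sum(axis=(1, 2)) / tot
    cy = (im * yy).sum(axis=(1, 2)) / tot
    m2 = ((im * ((xx - cx[:, None, None])**2 + (yy - cy[:, None, None])**2))
          .sum(axis=(1, 2)) / tot).mean()
    print(f"D = {D}: mean radial second moment {m2:.2f} px² (motion blur)")
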
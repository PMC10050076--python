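# blurmap

**Super-resolved diffusivity mapping from motion-blurred single-molecule
images.**

`blurmap` is for single-molecule microscopists and method developers who
want local diffusion coefficients *D* from ordinary single-molecule
localization microscopy (SMLM) movies — without tracking. A molecule
diffusing at *D* during a finite camera exposure *T* leaves a
motion-blurred spot: the convolution of its Brownian path with the
microscope PSF. One blurred image cannot yield a meaningful *D* (the
same *D* produces diverse paths), but a **stack of n_ch uncorrelated
images** at a common *D* can. The package:

* simulates the forward process — 2-D Brownian paths over a 9 ms
  exposure (micro-steps of length √(4·D·t)), photon-level PSF rendering
  onto a 160 nm pixel grid, camera background, spatially patterned *D*
  fields, whole synthetic movies;
* trains a shallow residual CNN (conv3×3 + batchnorm + Swish blocks,
  implemented in pure numpy) that regresses *D* (µm²/s) from 7×7×n_ch
  image stacks, with brightness/background domain randomization;
* detects and centroid-localizes molecules frame by frame, discarding
  overlapping ROIs;
* maps *D* at super-resolution: localizations are binned on a fine grid
  (default 120 nm); every bin with more than 10 images is evaluated by
  averaging the model over m = 100 random n_ch-stacks drawn from the
  bin's pool (bounded-repetition sampling for small pools: each image
  at most j times, j the minimum integer with j·p > n_ch; negative
  means clamped to 0);
* provides the step-distance MLE baseline D̂ = Σr²/(4·N·τ) with its
  1/√N precision law for budget-matched comparisons (each step costs
  two images).

See `docs/methods.md` for the model details and `examples/` for short
narrative scripts, one per capability.

## Worked example

Train the reduced-scale regressor and map a two-level diffusivity
pattern (~1 µm square and circular domains at 4 µm²/s in a 2 µm²/s
background) on a 120 nm grid, ~200 molecule images per bin:

```bash
python examples/05_map_diffusivity_pattern.py
```

```
training the reduced-scale regressor (several minutes) ...
final validation MSE 0.165 (µm²/s)²
simulating and mapping the square/circle pattern ...
map: 16 x 32 bins of 120 nm, mean pool 186 images/bin
boundary transition widths (bins) per row: {7: [1, 2, 1, 0], 8: [3, 1, 1, 1], 9: [0, 1, 1, 0]}
median transition width: 1.0 bins (120 nm); max 3
median |%Error| over interior bins: 6.3% (73% of bins within 10%)
wrote pattern_dmap.png / pattern_dmap.csv
```

Reading: the map recovers the 2 vs 4 µm²/s regions; crossings from one
plateau to the other typically complete within one 120 nm bin (the
occasional wider reading is single-bin noise against the ±10 % plateau
window), so ~300 nm features are resolvable; the per-bin relative error
against the ground-truth field is below 10 % for most interior bins.
Numbers vary slightly with the seed.

The same machinery is exposed as a thin CLI
(`blurmap simulate|train|localize|map|mle`) for shell pipelines: e.g.
`blurmap simulate frames --seed 1 --out movie.tif`, then
`blurmap localize --frames movie.tif --out locs.h5`, then
`blurmap map --locs locs.h5 --model model.ckpt.npz --out dmap`.

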
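# panorf

Panoramic natural scenes have strongly structured statistics: contrast
power falls from the sky toward the ground and drops abruptly at the
horizon. Efficient-coding theory predicts that retinal ganglion cell
(RGC) receptive fields (RFs) should track this structure across the
visual field — stronger antagonistic surrounds and smaller centers where
the signal-to-noise ratio (SNR) is high, and vertically asymmetric
surrounds where the SNR is vertically asymmetric (near the horizon).
`panorf` implements both halves of that story as a tested Python
library:

* **Theory.** A linear model neuron responds `r_t = φᵀ s_t` to noisy
  normalized image patches. Its filter is optimized under

  `L(φ) = ⟨√(r_t²)⟩_t + λ Σᵢ φᵢ² d(i)`, with `‖φ‖ = 1`,

  where `d(i)` is the squared pixel distance from the filter's peak
  entry and λ the spatial-locality strength. Sweeping the additive
  noise variance σ² and the patch-wise vertical SNR asymmetry
  (bottom-half scaling before normalization) produces the three
  predictions above.

* **Measurement.** The pipeline a retinal-imaging experiment needs to
  test those predictions: a shifting white-noise stimulus (100 µm
  checkers, 10 µm shift quanta, 6 Hz), RF estimation from deconvolved
  calcium traces via a population-subtracted calcium-triggered average
  on a 0.025 s latency grid, normalization / localization / 1-mm crop /
  15-dB SNR gating, a constrained two-Gaussian (difference-of-Gaussians,
  DoG) parametrization with derived metrics (center size, relative
  surround strength `|Σ surround| / |Σ center|`, vertical surround
  asymmetry `(u−l)/(u+l)`), and retina-wide statistics (alignment to an
  optic-nerve-centred frame, 1D/2D binning, ventral-vs-dorsal
  Kolmogorov–Smirnov tests, elevation/azimuth regression weights,
  diagonal-covariance GMM clustering of temporal RFs with BIC-elbow
  model selection, RF tiling index, saccade detection and circular
  orientation tuning).

* **Synthetic retina.** A ground-truth RGC population with imposed
  dorsoventral gradients, a rendered shifting-checkerboard stimulus and
  a linear–nonlinear forward model emitting deconvolved-like traces, so
  the entire measurement chain is validated by parameter recovery
  without any downloaded data.

## Worked example

```python
from panorf import coding, scenes

images = [scenes.generate_panorama(scenes.SceneParams.homogeneous(seed=s))
          for s in range(30)]
sweep = coding.run_sweep(images, "snr", levels=[8.0, 2.0, 0.5, 0.125],
                         lam=0.1, n_patches=5000, edge=15, seeds=(0, 1, 2))
print(sweep.groupby("level")[["relative_surround", "center_size"]].mean())
```

prints (level = noise variance σ², so SNR increases upward in the
table):

```
       relative_surround  center_size
level
0.125           1.033815     9.333333
0.500           0.937672    10.333333
2.000           0.822674    11.666667
8.000           0.676864    14.666667
```

i.e. as photoreceptor SNR rises the optimal RF's surround strengthens
(relative surround 0.68 → 1.03) and its center shrinks (≈15 → 9
pixels inside the 90%-energy circle) — the center–surround trade-off
the theory predicts. `examples/` contains one short script per
capability (scene statistics, theory sweeps, mapping and fitting a
single cell, retina-wide trend recovery, saccade statistics); each
prints what it computes and what the numbers mean.

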
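# Methods

## The coding model

A model RGC is a linear filter over image patches: `r_t = φᵀ s_t`. The
filter minimizes

    L(φ) = ⟨√(r_t² + ε)⟩_t + λ Σᵢ φᵢ² d(i),   ‖φ‖₂ = 1,

the mean absolute response (response sparsity; ε = 1e−8 smooths the
kink at zero) plus a spatial-locality penalty, where `d(i)` is the
squared pixel distance between entry *i* and the filter's peak-|φ|
entry. The unit-norm constraint excludes the trivial zero solution.
Minimizing transmitted activity while keeping the filter local and
informative is the predictive-coding trade-off: the optimal filter
subtracts a surround prediction from a center measurement, and how
aggressively it does so depends on how reliable the input is.

**Inputs.** Patches are sampled uniformly from 1/f-correlated surrogate
panoramas (`SceneParams.homogeneous`), normalized per patch to zero
mean/unit variance, and corrupted with additive i.i.d. Gaussian noise of
variance σ² (the SNR knob). Vertical SNR asymmetry is imposed
patch-wise: the bottom half of each raw patch is multiplied by a factor
`b < 1` *before* normalization, then constant-variance noise is added.
Data are reduced to `k_pca` principal components (computed on noiseless
patches for the SNR sweep; per asymmetry level for the asymmetry
sweep). The elevation-graded panorama generator (luminance/contrast
gradients, multiplicative horizon step) feeds the scene-statistics
analyses: the per-row power profile, `snr = power / noise_power`, and
the windowed vertical SNR asymmetry
`asym(y) = (m_up − m_down)/(m_up + m_down)`, which peaks for windows
centred on the horizon.

**Optimization.** Projected gradient descent with momentum in the PCA
coordinate system; the pixel-space filter is reconstructed each step for
the locality term and renormalized to unit norm. Initialization is
Gaussian noise (variance 0.1) with the central pixel set to −1. The
cost is even in φ, so the returned filter is canonicalized to a
negative peak (the center-negative convention). Defaults: step 0.02,
momentum 0.5, ≤4000 iterations, relative-cost tolerance 1e−6. The
locality anchor is the central pixel by default (`anchor="center"`),
where the initialization pins the peak; re-identifying the peak every
iteration (`anchor="peak"`) is available, but during the early
transient it lets the filter drift off the patch midline, and a filter
that sits entirely in one half of the patch cannot feel the bottom-half
scaling that defines the asymmetry sweep. At the optimum the two rules
coincide. λ defaults to 0.1, chosen once so that optima at the
15×15-pixel working scale are center–surround with the surround ring
well inside the 90%-energy circle; much larger λ collapses the
surround's room inside the circle, much smaller λ leaves the orientated
(Gabor-like) regime of λ → 0.

**Characterization.** Per sweep, the per-pixel energy φᵢ² is averaged
across all conditions and the smallest circle holding 90% of that
energy defines the analysis region. Inside it: center = entries φᵢ<0,
surround = entries φᵢ≥0; surround (center) strength is the summed
|φᵢ| of the respective set, center size the count of negative entries,
and vertical asymmetry `(u−l)/(u+l)` over the positive entries above vs
below the circle's center row.

## The synthetic retina

`GroundTruthCell` is a space–time separable linear–nonlinear unit: a
DoG spatial profile (center amplitude ±1; surround of opposite sign
whose *integrated-mass ratio* to the center is the cell's true relative
surround strength; surround σ = 2.2 × center σ; the surround may be
displaced along the dorsoventral axis, giving a true vertical asymmetry
`2Φ(−δ/σ_s) − 1`), times a biphasic temporal kernel at the 6-Hz frame
rate (taps 1, −0.35). The default dorsoventral gradients over a
±500 µm retina: relative surround 0.35 ± 0.25·(y/500), center σ
55 ∓ 15·(y/500) µm, surround offset ∓60·(y/500) µm. The offset
gradient shifts ventral cells' surrounds dorsally and dorsal cells'
surrounds ventrally, so the measured vertical asymmetry rises from
dorsal to ventral and spans roughly ±0.4 — comparable to strongly
asymmetric measured surrounds. ON/OFF polarity is a fair coin.

The stimulus is a binary checkerboard, 100 µm checkers on a 10 µm/px
grid, whole-grid offsets drawn uniformly from multiples of 10 µm
spanning one checker period, per axis per frame, at 6 Hz. Responses:
frame-wise projection of the rendered RF, temporal-kernel convolution,
optional pre-rectification Gaussian noise (`pre_noise`, in units of the
drive s.d.; models membrane noise and dithers the nonlinearity),
half-wave rectification, exact boxcar resampling to the 10 Hz imaging
rate, additive Gaussian noise (`noise_level`, in units of the trace
s.d.; stands in for deconvolution residuals) and clipping at zero, so
traces are nonnegative like deconvolved calcium events. With
`pre_noise = noise_level = 0` the model is deterministic and is checked
against a brute-force loop to 1e−10.

Eye traces are a slow drift plus step-like saccades at Poisson times
(≥1 s apart) whose directions alternate along a preferred orientation;
ground-truth times/amplitudes/directions are recorded and the median
position is re-zeroed.

## RF estimation

The calcium-triggered average for neuron *i*:

    RF(i,x,y,τ) = Σ_t s(x,y,t−τ)·r(i,t) − Σ_t s(x,y,t−τ)·pop(t)

with `pop` the population-mean response by default (the raw-sum variant
and `none` are options). The mean makes the correction term commensurate
with the first term; its purpose is to remove the residual stimulus
distribution and any drift common to all neurons. The stimulus is
evaluated by zero-order hold (the last frame before `t−τ`) and τ moves
in 0.025 s steps. Implementation note: because the stimulus is constant
within a frame, the sum over samples collapses to per-frame accumulated
trace weights followed by one matrix product per latency; this is
algebraically identical to the direct sum (unit-tested against a
four-deep loop at 1e−10) and is what makes 500-cell recovery runs
affordable.

Normalization subtracts the mean over pre-stimulus latencies and
divides by the global |max|. One subtlety: with a 6-Hz zero-order-hold
stimulus, latencies less negative than one frame period (≈0.167 s)
still index the frame that drove the response, so a baseline over all
τ<0 is contaminated by the RF itself — noticeably so when the baseline
is averaged over a small cropped window. The pipeline therefore uses
τ < −0.17 s for the baseline (`normalize_rf(..., baseline_before=-0.17)`);
the τ<0 convention remains the function's default.

`P_var`/`T_var` are the argmax of temporal variance per pixel and
spatial variance per latency (ties → lowest flat index). Crops are
1 mm squares centred on `P_var` (600 µm in the desk-scale pipeline),
zero-padded and masked outside the field. RF quality is the
peak-to-noise ratio `10·log₁₀(peak²/noise_power)` with noise power the
mean squared value over pixels >0.5 mm from `P_var` across latencies;
only RFs strictly above 15 dB are kept.

## DoG parametrization

`RF_2D` is the per-pixel median in a ±2-sample latency window around
`T_var`; pixels whose time course correlates with the `P_var` course at
|r| below a threshold (default 0.25; 0.1 in the pipeline) are zeroed
and masked, and an optional Gaussian blur (20 µm in the pipeline)
suppresses checker-scale sampling noise. Fitted widths/amplitudes can
be corrected for a known blur in closed form (`deblur_fit`), since a
Gaussian stays Gaussian under Gaussian smoothing.

Stage 1 fits a single Gaussian to the center lobe — pixels of the same
sign as the dominant extremum above 15% of it — plus a nuisance
constant that absorbs the locally near-constant surround pedestal;
without these two precautions the center's fitted shape inherits a
surround bias that stage 2 can never undo. The RF is then classified:
if the |min|/|max| ratio is below 0.75 or the extrema are closer than
`d = 2·min(σ₁ˣ, σ₁ʸ)`, center and surround overlap ("overlapping"),
otherwise they are well separated. Stage 2 fits G1+G2 with G1's
location/shape frozen, G1's amplitude and all six G2 parameters free,
G2's amplitude constrained to the opposite sign via an exponential
parametrization, and — for overlapping RFs — a sigmoid penalty
`P(dist) = C/(1+exp(−k(dist−d)))` on the G1–G2 centre distance with
`C = 10×` the data sum of squares and `k = 30/d`: prohibitive beyond
`d`, negligible (≈`C e⁻³⁰`) at the centre, so it never competes with
the residual of a good fit. Three surround inits guard against local
minima. An optional joint polish (default on) then frees all twelve
parameters from the staged optimum; on noiseless rendered DoGs this
converges to the exact generating parameters, which the strictly frozen
protocol cannot (≈18% surround-amplitude bias). For measured maps with
correlated reverse-correlation noise the frozen protocol is the more
robust choice and is what the pipeline uses (`polish=False` there).

Derived metrics use 2-s.d. ellipse pixel sets (center: within G1's;
surround: within G2's and not center). Center size is the center-pixel
count in mm². Relative surround strength is |Σ surround| / |Σ center|;
vertical asymmetry is `(u−l)/(u+l)` with u, l the |sums| over the
surround pixels dorsal/ventral of G1's centre row. Both sums default
to raw `RF_2D` values at the operation level; the pipeline evaluates
them on the fitted components (G1/G2 surfaces over the same pixel
sets), because with a weak surround the center's same-signed tail can
outweigh the surround inside the annulus and flip the sign of the raw
|u|,|l| statistic — on noiseless renders the component variant tracks
the generating asymmetry at r ≈ 1.0 while the raw variant is
uncorrelated with it. COM distance/orientation connect the
|value|-weighted centres of mass of the two sets; radial profiles are
ring means around `P_var`; center/surround temporal dynamics are the
per-latency means over the two pixel sets.

The 1D difference-of-Gaussians fit for axial profiles enforces the box
constraints amplitude_center ≥ M_peak/2, amplitude_surround ≥ 0,
|loc_center| ≤ 20°, |loc_surround| ≤ 25°, σ_center ≥ W_peak/4,
σ_surround ≥ W_peak, initialized from the peak magnitude M_peak and a
half-max width estimate W_peak; a second start on the zero-surround
bound catches pure-center profiles.

## Population statistics

Alignment is rigid: translate the optic nerve to the origin, rotate the
ventral direction onto +y, mirror left retinas in x (attached RF crops
are rotated/mirrored consistently). ON-center RFs can be sign-flipped
so all centers are negative; summary metrics are sign-symmetric. 2D
binning covers ±1500 µm with a minimum of five cells per bin; 1D
binning uses six equal-width bins over the group's coordinate range.
Trends are tested with a two-sided two-sample KS test between ventral
and dorsal samples (exact p for n ≤ 25, asymptotic otherwise) and with
a joint OLS of the metric on z-scored y (elevation) and x (azimuth).
In the recovery experiment the KS test runs on per-cell values (a
single desk-scale retina yields only 3+3 binned values, which cannot
reach small p); binned-value testing is available through the same
functions. Temporal-RF clustering: 10 PCA components, diagonal-
covariance Gaussian mixtures (k-means++ init, 10 restarts, 1e−6
variance floor) over a k grid, model order at the BIC curve's elbow
(maximum discrete second difference), with a manual override. The
tiling index rasterizes 2-s.d. center ellipses at 1 µm pitch:
Area(union)/Σ Area. Saccades are detected on a 0.7 s median-filtered
trace (speed > 45°/s, amplitude ≥ 3°, interval ≥ 0.25 s) and summarized
by the amplitude-weighted circular statistic on doubled angles
(`ᾱ = ½ arg Σ r_t e^{2iα_t}`, `r̄ = |Σ r_t e^{2iα_t}|/Σ r_t`).

## The recovery experiment

`pipeline.run_recovery_experiment` chains everything on one synthetic
retina that lives directly in the aligned frame. Defaults: 500 cells
over ±500 µm, a 30-minute stimulus on a 1.7 mm field (white-noise
totals of 15-60 min per recording match the experimental protocols
the pipeline emulates), trace noise 0.5,
pre-rectification noise 0.75, population-mean subtraction, latencies
−0.25…0.25 s, 600 µm crops, 20 µm smoothing, |r| ≥ 0.1 pixel
correlation gate, frozen-G1 fits, component-based surround metrics.
Estimation runs in two passes — a full-field three-latency pass for
localization and SNR gating, then the full latency stack evaluated only
inside each kept cell's crop window (identical arithmetic). Outputs:
per-cell recovered vs true metrics, Pearson/Spearman recovery
correlations, six-bin dorsoventral profiles, per-metric KS tests and
elevation/azimuth weights. `null_ks_calibration` repeats the KS test on
50 gradient-free populations (ground-truth metrics plus measurement
jitter) to confirm nominal false-positive rates; it deliberately skips
re-running the full imaging chain 50 times, since the control concerns
the statistic, not the imaging model.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses rely on
(1/f spatial correlations with elevation-dependent power and a horizon
step; binary shifting checkers with exact geometry; nonnegative noisy
traces from rectified linear drives; dorsoventral gradients and
asymmetric surrounds; saccadic eye traces with orientation structure).
It does not model calcium-indicator kinetics or deconvolution
artifacts, cell-type diversity beyond ON/OFF polarity and smooth
gradients, spatial nonlinearities (subunits), eye/optics blur, or
recording-session artifacts (drift fields, overlapping ROIs). Passing
recovery tests therefore demonstrate that the measurement chain is
correct and well-calibrated for linear–nonlinear cells under realistic
sampling noise — not that real retinas satisfy those assumptions.

## Numerical choices and limitations

* Estimator/forward-model oracles hold to 1e−10 (float64 throughout).
* Argmax ties break at the lowest flat index; crops pad with zeros and
  carry validity masks which all downstream statistics respect.
* At 20 dB peak SNR the surround amplitude of a weak (6–16% of center)
  surround is recoverable only to ≈19% median error: restarting the
  optimizer at the ground truth reaches the same global optimum, i.e.
  the limit is the DoG amplitude–width degeneracy (the surround mass
  A·σ² is determined about twice as well), not the implementation.
* The measured-map fidelity of the estimator is reverse-correlation
  sampling noise limited (r with the rendered truth rises from ≈0.93 at
  15 min to ≈0.96 at 30 min per cell on linear responses); rectification
  adds a further structured distortion of a few percent.
* Problem sizes in tests are desk-scale by design: 15×15 theory patches
  (5000 samples, 3 seeds), a 500-cell retina on a 1.7 mm field, 1D
  profiles on a 101-point grid.
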
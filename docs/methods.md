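# Methods

## The phenomenon being measured

Retrospective undersampling experiments evaluate a reconstruction
algorithm by masking fully sampled k-space and comparing the
reconstruction against the fully sampled "gold standard". The experiment
is only as honest as the k-space it starts from. When the starting point
is re-synthesized from an already-processed magnitude image, two things go
wrong at once:

1. **Zero padding** (scanner default, often 2× per axis) squashes the true
   frequency content into the central part of the enlarged grid.
   Variable-density masks, which by design concentrate samples near the
   center, then cover the true data at a much higher rate than the
   advertised global rate. The *effective sampling rate* — the sampled
   fraction inside the original data box — is the statistic that exposes
   this.
2. **Lossy processing** (JPEG, 8-bit quantization, magnitude-only export)
   strips exactly the content (noise, fine texture, phase) that an
   undersampled reconstruction cannot recover anyway. Because the gold
   standard is built from the *same* processed image, the error metrics
   are blind to the processing: both arms lose the same content and the
   measured error falls although the image got worse.

Both effects inflate reported quality without any algorithmic progress,
and solvers tuned under them degrade when they finally meet raw data (the
generalization gap).

## Synthetic raw data

The generator replaces a raw-data archive download. One slice is:

* **Anatomy** — an elliptical support (~0.84 of the grid) holding four
  soft-contrast ellipses, multiplicative low-frequency shading, and
  `n_features = 8` small high-contrast details (2–5 px ellipses and short
  bars at the 320² reference scale, scaled with the grid), emulating fine
  structures and focal pathology. A Gaussian point-spread blur
  (σ = 0.008·grid) keeps the slice band-limited, as acquired MRI is.
* **Texture** — a stochastic field band-limited to 0.1–0.45 of Nyquist at
  amplitude 0.04 of the tissue scale, emulating parenchymal/trabecular
  texture. This is the content lossy compression acts on; without it JPEG
  has nothing realistic to remove.
* **Phase** — a smooth random field (cutoff 0.04 of Nyquist, ~1 rad),
  so the complex slice is *not* conjugate-symmetric while every processed
  magnitude image is. This encodes the fact that magnitude-only data halve
  the inverse problem.
* **Coils** — `n_coils = 4` smooth complex sensitivities: positive
  Gaussian bumps on the image rim over a 0.1 floor with smooth phase,
  hard band-limited to 8% of Nyquist; root-sum-of-squares of the maps is
  bounded away from zero.
* **Noise** — i.i.d. complex Gaussian in k-space with per-sample std
  `2e-3` of the peak k-space magnitude (≈5% of the image intensity scale
  in the image domain), the standard MRI noise model at a realistic SNR.

Everything is deterministic in the slice seed; the background anatomy is
drawn before the detail substream, so slices differing only in
`n_features` share their background bit for bit (the detail-count unit
test depends on this).

**What the generator does not emulate:** real anatomy and contrast
mechanics, 3D volumes and slice correlation, non-Gaussian (RSS-rectified)
noise statistics in the image domain, scanner-specific filters, motion.
Passing tests therefore demonstrate the *mechanisms* of the bias —
effective-rate inflation, entropy stripping, metric blindness — not the
magnitudes any particular clinical dataset would show.

## Processing pipelines

* **Scanner export**: symmetric zero padding of the multicoil k-space about
  the centered DC to `round(factor·size)` per axis (DC pixel stays at
  `n//2`), per-coil inverse orthonormal FFT, RSS combination. The output
  image is nonnegative and interpolated; provenance records where the true
  data sit in the enlarged k-space.
* **JPEG storage**: per-image max-scaling to 8-bit grayscale (the scale is
  recorded and inverted after decoding), baseline JPEG at quality factor
  75/50/20 via the standard libjpeg codec; `"none"` skips the codec but
  keeps the 8-bit round trip so the quantization itself is never hidden.
  JPEG is applied to the RSS image *before* the training-time
  normalization, mirroring compression at storage time.
* **Intensity normalization**: division by the image's own 98th percentile,
  applied at dataset-preparation time (the common practice for training
  data in the 0–1 range).
* **Re-synthesis**: forward orthonormal FFT of the processed image — the
  single-"coil", conjugate-symmetric k-space a naive pipeline would treat
  as raw data.

The zero-pad forensic helper (`detect_zero_pad_box`) works on the log of
the median `|k|²` over centered box-boundary rings: a padding edge is a
*step* — densities just outside a boundary fall far below the linear
extrapolation of the densities just inside (detrending distinguishes a
step from the steep smooth decay near the spectral knee; the minimum
accepted step is 0.8 nats). A located edge is confirmed only if the total
energy outside the box is below `threshold` (default 1e-2) times the
energy inside. Boxes smaller than a quarter of the grid (padding beyond
4×) are not considered. On scanner-pipeline output the box is recovered to
within ±2 px per edge; on unpadded spectra nothing is flagged.

## Sampling

Probability maps: `prob = clip((1−r)^p + c, 0, 1)` with `r` the
per-axis-normalized center distance (r = 1 at every mid-edge) and the
offset `c` (possibly negative) solved by scalar root finding so that the
mean equals `1/R` to 1e-6, with the calibration region pinned to 1 first.
Under this construction a *large* power is a narrow bump over a
near-uniform floor — weak variable density (`p = 7`) — while small powers
(`p = 1, 2, 3` for R = 2, 3, 4) put substantial extra mass on the center —
strong variable density. For the 17% (R = 6) effective-rate study the
strong-VD power is not pinned down by the R = 2..4 ladder; `p = 3` is the
default (it reproduces the ~38% effective-rate anchor at 2× padding,
where `p = 2` overshoots to ~44%) and the power remains configurable.

Calibration region: 6×6 at 320², scaled proportionally with the grid
(minimum 2 px per axis). Masks are independent Bernoulli draws — Monte
Carlo rather than exact-count — so averaging over 15 masks per cell is
meaningful; a fresh mask is drawn for every k-space example in every
experiment ("on-the-fly" masking), which prevents tuning to any one mask.

## Solvers

**CS (FISTA, ℓ1-wavelet).** Orthonormal centered FFT + binary mask gives a
data-consistency gradient with Lipschitz constant 1, so the step size is
fixed at 1. Wavelet: Daubechies-4, periodized; 4 levels by default, 3 in
the desk-scale experiments (96–256 px grids; the grid must be divisible by
2^levels for orthonormality). Soft-thresholding acts on complex
coefficients by magnitude (phase preserved), including the approximation
band, so the iteration is the exact prox of λ‖Ψx‖₁. Initialization is the
zero-filled adjoint; stop at 200 iterations (100 in the experiments) or
relative iterate change < 1e-6 (1e-5). λ is calibrated per processing
level by grid search minimizing mean NRMSE over 10 reserved tuning slices;
the library default grid spans [1e-9, 1e-1] (9 points/decade), the
experiments use 7 log-spaced points in [1e-4, 1e-1] — on normalized images
the optimum consistently falls inside this range (1e-3-ish), consistent
with the full-grid searches this mirrors.

**DictL (OMP + K-SVD alternation).** Patches of `b = 8` on a stride-2
grid (trailing offset always included, so assemble∘extract = identity via
overlap counts). Per outer iteration: `L = 500` patches sampled uniformly
at random train the dictionary (one OMP pass + one sequential K-SVD pass,
unused atoms replaced by the worst-represented patch); then *all*
stride-grid patches are coded with the refreshed dictionary and the image
update is closed-form in k-space — at measured locations
`(Fx)_k = (y_k + λ_D z_k)/(1+λ_D)` with `z = F R(DA)`, elsewhere
`(Fx)_k = z_k` — the exact minimizer in `x` for fixed (D, A). Patch means
are not subtracted (the objective has no DC-removal term). OMP runs
batched with per-step batched least-squares refits and stops at K atoms or
residual < 1e-10. Because the greedy coding of a *changed* image need not
lower the joint objective, the image update is accepted only when it does
(monotone acceptance); rejected passes keep the image and let the
dictionary keep evolving. This makes the objective trace non-increasing
by construction without altering the accepted iterates. The desk-scale
calibration grid is K ∈ {3, 5}, λ_D ∈ {0.01, 0.1} at P = 64, b = 8,
N_iter = 5 (5 tuning slices); the full-scale ranges (P up to 300, K to 13,
b to 32, N_iter to 13) remain configurable but a search of that size is a
cluster campaign, not a desk run. Note that with the image-domain coupling
term ½λ_D‖x − R(DA)‖² the natural λ_D scale is O(0.01–1); values are not
comparable across formulations that sum per-patch errors instead.

**Metrics.** NRMSE = ‖recon − ref‖₂ / ‖ref‖₂ over magnitude images (the
convention of the public raw-data benchmarks; range- and
mean-normalization are available since the field is not unanimous). SSIM:
Gaussian window (11×11, σ = 1.5), K1 = 0.01, K2 = 0.03, weighted
covariance, data range = reference max. Absolute metric values depend on
these conventions and on the synthetic data; only *changes* across
processing levels are meaningful study outputs.

## Experiment design

Splits are disjoint at the synthetic-subject level: 10 CS-tuning, 5
DictL-tuning and 20 test slices per study, all descending from one master
seed through a fixed seed tree (stable across processes). For every
processing level the solvers are re-calibrated on that level's own tuning
split ("instance-optimal" hyperparameters), so the measured trends cannot
be blamed on a solver mis-tuned for one arm. The gold standard of each
level is that level's processed image — deliberately, since that is the
flawed evaluation being studied. Trend significance uses a paired
one-sided sign test across test slices (ties dropped), which assumes
nothing about the error distribution.

Desk-scale problem sizes: 96² base grids for the zero-pad and gap studies
(1.5× → 144², 2× → 192²), 128² for the JPEG study (at 96² the 8×8 JPEG
blocks are so coarse relative to the image that blocking artifacts offset
the entropy the codec removes; at 128² and above the codec is in its
intended regime), 320² for the effective-rate study (mask statistics only,
so the full reference grid is cheap). R = 4 strong VD for the
reconstruction studies; R = 6 (17%) for the effective-rate study; 15 masks
per effective-rate cell.

## Numerical choices and degenerate inputs

* Centered orthonormal FFT throughout; Parseval holds exactly and the
  zero-pad box is a centered rectangle with DC at `n//2`.
* PDF offset solved by `brentq` to 1e-10; infeasible configurations
  (calibration region alone exceeding the budget) raise.
* λ ties in calibration break toward smaller λ; DictL grid ties toward
  smaller P, then smaller K.
* OMP adds a 1e-12 ridge to the batched normal equations; K-SVD skips an
  atom if its restricted SVD fails; all-zero patch sets raise.
* JPEG requires a positive image maximum (8-bit scaling); the 98th
  percentile must be positive; NaNs in solver inputs raise.
* `L` larger than the available patch count is clamped with a warning.

## Known limitations

* Single-coil encoding downstream of the pipelines (all processed data are
  magnitude images; there is no SENSE-style multicoil operator) and
  Cartesian 2D masks only.
* The DictL solver is a faithful desk-scale implementation, not a
  performance-tuned one; its absolute NRMSE trails CS here, which matches
  the general ordering reported for these solver families but should not
  be read as a benchmark.
* Trend *directions* and mechanism sizes transfer to real data; absolute
  NRMSE/SSIM values and percentage changes do not — they depend on
  anatomy, SNR, and resolution that the generator only sketches.
* No deep-learning arm: training unrolled networks is out of scope for a
  single-CPU artifact, and nothing in the bias mechanisms is specific to
  the solver class.
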
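# Methods

`specgp` evolves multispectral sensor configurations: small, readable
programs that select a handful of wavelength intervals (and optionally
image texture features) from a hyperspectral cube and emit a feature
vector for a regression model. The intended application is predicting
sediment attributes — organic-matter content as percent loss-on-ignition
— from surface reflectance imagery of intertidal quadrats, but nothing in
the machinery is specific to sediment.

## Radiometric calibration

Raw counts become reflectance by the standard two-point rule
`R = (raw − dark) / (white − dark)` per pixel and band. Field white
references are frequently overexposed in the visible range; entries of
the white spectrum above the sensor maximum are reconstructed from a
non-overexposed *seed* acquisition by fitting `a·seed^b + c` on the valid
entries (least squares, `b` initialised at 1 and bounded to [0.05, 20] so
the power stays defined; `scipy.optimize.curve_fit`). Entries at or below
the maximum pass through unchanged, so the correction is the identity on
clean spectra.

Bright shell and specular pixels are removed from the region of interest
by thresholding the band nearest 873 nm — shells respond strongly there
while wet sediment does not — followed by a morphological erosion with a
disc. Neither the numeric cutoff nor the erosion radius is canonical;
the defaults are an Otsu threshold on that band within the current ROI
and a radius of 1 px, both configurable. Each 25×25 cm quadrat is divided
into a 5×5 grid of subregion cells (remainder pixels go to the last
row/column so the cells tile the quadrat exactly); the field protocol
pairs ground-truth cores with the four corner cells and the centre cell.

## Spectral pretreatment

Per pixel, before averaging to a mean spectrum: standard normal variate
(subtract the spectrum mean, divide by its sample standard deviation;
removes multiplicative illumination effects) followed by Savitzky–Golay
smoothing. The order and the smoothing parameters are not canonical
either; the defaults are SNV first, then a window of 9 bands at
polynomial order 2, all configurable. Sample-sd (n−1) conventions are
used throughout the package so the spectral statistics match the
chemometric ones.

## Program structures and the typed function set

Two strongly-typed program structures are searched. Both end in a root
that is either a feature concatenation of arity 2–4 or a single-feature
conversion (`=`), so every program emits a variable-length feature
vector.

* **Spectra-based** programs read a preprocessed mean reflectance
  spectrum. Their only extraction primitive is *interval selection*: the
  mean or median of a window of odd nominal width w ∈ {1,3,5,7,9,11}
  bands centred at an evolvable band index λ. Windows are truncated at
  the spectrum edges with the averaging weights renormalised to sum to
  one. Selected scalars can be combined with +, −, ×, ÷ (protected: a
  denominator below 1e−9 yields 0).
* **Image-based** programs read the full cube and additionally can:
  collapse a band window to a grayscale image by per-pixel mean, median
  or Gaussian weighting (weights `exp(−Δ²/2σ²)` over band offsets,
  renormalised); filter that image (Gaussian, derivative-of-Gaussian as
  gradient magnitude, median, max, min, 7×7 and 9×9 Gabor, min-max
  scaling of the ROI to [0,1]); and summarise it either by the ROI mean
  (a spectral feature) or by a texture descriptor (one of five GLCM
  features, or a histogram moment). They can also extract the mean
  spectrum in-tree and apply SNV/Savitzky–Golay before interval
  selection, which makes the spectra-based structure a strict subset.

Gabor kernels fix σ = 2, aspect ratio γ = 0.3 and phase ψ = 1; only the
orientation θ ∈ {0…7}·π/4 and the angular frequency
f = π·2^−(1+0.5v), v ∈ {0..3} evolve. The real part of the response is
used. All 2-D filtering uses reflect padding and is computed over the
full rectangle; features are read only within the ROI, which keeps
convolution defined next to mask holes. Filters never alter the mask.

### GLCM descriptors

The co-occurrence matrix quantises intensities by min-max binning over
the ROI (default 32 levels, configurable — descriptor values are thus
invariant to affine intensity rescaling) and counts a pixel pair only
when both pixels lie in the ROI. Accumulation is symmetric, so an offset
angle and its opposite give identical matrices; only the four angles
{0, 45, 90, 135}° are used, with distances d ∈ {1..5}. The five
descriptors are homogeneity Σ p/(1+(i−j)²), entropy −Σ p log₂ p (in
bits, 0·log 0 := 0), contrast Σ p(i−j)², correlation
Σ(i−μᵢ)(j−μⱼ)p / (σᵢσⱼ) with σ the standard deviations of the marginal
index distributions (a flat texture with σᵢσⱼ = 0 scores 0 so the search
stays total), and energy √(Σ p²), the square root of the angular second
moment. Histogram features are the ROI mean, sample sd, skewness and
excess kurtosis (raw kurtosis behind a flag).

## Tree generation, variation, and the evolutionary loop

Initialisation is ramped half-and-half under per-type height budgets:
at every node, only primitives whose argument types can still be
completed within the remaining height are candidates, which forces each
branch toward terminals before the cap (depth 8 for spectra-based, 9 for
image-based programs; initial depths 3–6 and 4–7). The *full* method
additionally requires every data-flow branch to close at one sampled
target depth, so primitives that consume the raw input are only placed
one level above it. Every generated or varied tree type-checks by
construction; this is verified at the 10⁴-tree scale in the tests.

Selection is size-4 tournament (ties favour the smaller tree). Only
non-leaf nodes are crossover points — almost all leaves are parameter
constants, so leaf swaps carry no variation — and offspring exceeding
the depth cap are rejected with up to 5 retries before the parents pass
through unchanged. A subtree swapped into the root position must itself
be a legal root. Mutation picks a non-leaf node with probability 0.75
(its subtree is regrown in place within the depth budget) and otherwise
re-samples one parameter leaf from its range. Per generation the top 1%
are copied unchanged (elitism), and the remainder is filled from
tournament parents through crossover (rate 0.8) then mutation (rate 0.2),
generational `varAnd`-style. Defaults: population 2048, 50 generations —
the experiments in this repository run scaled-down searches (population
64–128, 10–20 generations), which the planted-band problems below are
sized for.

Fitness: the calibration set is split 70:30 once per run (shared by all
individuals; the prediction set never participates). A tree's features
are extracted for all calibration samples, standardised per feature
(x → (x−mean)/sd computed over all calibration feature vectors;
zero-variance features map to 0), then a linear-kernel SVR (C = 1,
ε = 0.1, fixed — no per-individual search, for tractability) is fitted
on the training portion and scored on the evaluation portion by R²
(maximised) or MSE (minimised). Trees that fail to evaluate or emit
non-finite features receive the worst-possible sentinel. Spectra-based
trees are evaluated on the whole sample matrix at once (each node
computes over an n×B matrix), which is what makes a population
evaluation cheap; the per-sample and batched paths are tested to agree.

Final reported models refit the best tree's features with the
grid-searched SVR from the chemometrics module. Selected wavelengths are
reported as unique (centre λ, width w) pairs with occurrence counts,
aggregated over a run's top-10 individuals as in the frequency analyses.

## Chemometric baselines

* **SPXY split** (2:1 calibration:prediction): greedy Kennard–Stone-style
  selection on the joint distance `dX/max(dX) + dy/max(dy)`; the most
  distant pair seeds the calibration set and the sample with the largest
  minimum joint distance is added until the ratio is met.
* **PLSR** with the latent-variable count minimising RMSECV under
  five-fold cross-validation with two repeats; **SVR** (linear and RBF)
  with grid-searched C ∈ {0.1,1,10,100}, ε ∈ {0.01,0.1,1} and, for RBF,
  γ at the `scale` heuristic × {0.1,1,10}.
* **Comparison protocol**: five-fold CV over the calibration set; per
  fold the model is fitted on four segments and six numbers are recorded
  — R²/MSE on the training segments (Rc², MSEc), the held-out fold
  (Rcv², MSEcv) and the full prediction set (Rp², MSEp) — then averaged
  over folds. GP runs are aggregated by the median across repetitions,
  because rare anomalous runs produce large negative R² that would skew
  a mean.
* **SPA**: from every starting wavelength, a chain grown by successive
  orthogonal projections (always taking the column with the largest
  residual norm, which minimises collinearity); every (start, size)
  prefix is scored by cross-validated RMSE of an ordinary linear model.
* **CARS**: 50 Monte-Carlo iterations; each fits a PLS model on a random
  80% row subset, enforces an exponentially decreasing retention ratio
  (from 1 down to 2/B) on wavelengths ranked by |regression coefficient|,
  then resamples survivors with probability proportional to those
  coefficients; the subset with the lowest five-fold RMSECV wins.
* **RC**: |PLS coefficient| ranking with non-maximum suppression (window
  ±5 bands, threshold 20% of the global maximum; both configurable).

## Synthetic scenes and what passing tests mean

The generator builds cubes from a smooth sediment-like base curve
(low-order polynomial rising from ~0.08 in the blue to ~0.30 in the NIR)
with planted Gaussian absorption dips whose depths are proportional to
the target attribute, modulated by: a per-sample smooth baseline
perturbation (random cubic, sd 0.02 — emulating grain-size/moisture/sky
variability between samples; without it, SNV normalisation makes the
attribute decodable from any band, because the dip shifts the whole
spectrum's mean and sd), a spatial texture field (Gaussian-smoothed white
noise, correlation length 3 px, amplitude 5%), a per-sample illumination
scalar (±10%), optional flat bright shell blobs, and i.i.d. per-pixel
noise.

Default study conditions for recovery experiments: 204 bands over
397.32–1003.58 nm, 32×32 px scenes, two planted dips at 550 and 850 nm
with sd 6 nm (a narrow absorption feature about twice the camera's 7 nm
resolution), attribute range 0.5–2.1 (mimicking percent organic matter),
and dip depth at the top of the range equal to 5× the per-pixel noise sd
(depth/noise = 5). Averaging ~1000 ROI pixels makes the mean spectra
nearly noise-free, so the limiting confound is the smooth baseline
variability — a planted-band selector must localise, not merely denoise.

What passing does **not** show about real data: the planted dips are the
only attribute signal (real organic matter expresses through broad,
overlapping absorption and albedo effects); the baseline variability is
a low-order polynomial (real inter-sample variation has more structure,
e.g. water-vapour bands near 920–970 nm); textures are stationary
Gaussian fields and shells are flat discs. The fixture validates the
machinery and the selectors' localisation behaviour, not field-scale
accuracy.

One behaviour worth knowing when interpreting selections: on a narrow
dip whose neighbouring bands are almost perfectly collinear, PLS
regression coefficients peak at the dip *shoulders* (the contrast
points), not the centre. Coefficient-driven selectors (CARS, RC)
therefore tend to select bands ~2σ from a planted centre, while SPA and
the evolved interval centres sit on the dip itself.

## Numerical choices and degenerate inputs

* Band lookup by wavelength is nearest-neighbour; coordinates are
  0-based row-major.
* Overexposure is `white > sensor_max` strictly; calibration refuses
  bands with `white ≤ dark`.
* Constant ROI under min-max scaling → all zeros; constant spectrum
  under SNV → error; empty ROI → error everywhere it would silently
  poison a mean.
* Median of an even-count truncated window is the midpoint of the two
  central values.
* Protected division cutoff 1e−9; invalid individuals get −∞/+∞
  fitness sentinels rather than exceptions.
* All randomness flows through a single `numpy.random.Generator` per
  run; identical config + seed reproduces the trace and best tree
  bit-for-bit (tested).

## Known limitations

* The image-based structure is considerably slower (per-cube evaluation
  cannot be vectorised across samples) and is exercised at small scale.
* SPA's validation criterion (internal CV of an OLS model) is one of
  several reasonable choices; with very few samples its CV folds can be
  too small for a meaningful R².
* CARS' adaptive resampling is implemented with unique-ified
  with-replacement draws, so realised subset sizes can fall slightly
  below the enforced ratio.
* The white-reference power-law fit assumes the seed spectrum is
  positive where fitted and at least three entries are clean.
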
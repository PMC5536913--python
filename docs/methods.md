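# Methods

## Scope and conventions

Everything operates on single-channel time-lapse movies of laterally
oriented embryos, or on pre-extracted space-time matrices. Conventions,
fixed once and used everywhere: egg length normalised to [0, 1] with the
anterior pole at 0; dorsal is the top image edge; a space-time matrix has
AP positions along rows (anterior first) and frames along columns;
intensities are arbitrary units, nonnegative, used raw (no bleach
correction — recordings are ≤ 3 h at one frame per 30 s and comparisons
are within-experiment).

## Separability analysis

The rank-one decomposition is a plain SVD with no detrending or
smoothing. Sign ambiguity of the singular pair is resolved by forcing the
spatial mode to nonnegative mean (for the nonnegative matrices produced
by imaging this makes the mode entrywise nonnegative, the Perron
direction); the temporal amplitude is the projection u₁ᵀX, so it carries
the physical intensity magnitude while the mode is unit-norm. The
accuracy ratio σ₁/√(Σσᵢ²) = ‖X‖₂/‖X‖_F is scale-invariant and equals 1
iff the matrix is rank one; by the Eckart–Young theorem the relative
rank-one residual is √(1 − r²), which the tests verify numerically.

For cross-embryo comparisons the amplitude is additionally reported
*plateau-scaled*: multiplied by the spatial-mode peak, i.e. the
reconstruction's intensity time course at the brightest AP position.
Unit-norm modes have grid-size-dependent peaks, so raw projections from
different embryos are not in common units; the plateau-scaled amplitude
is, and for a separable embryo it equals the generating amplitude times
the (≈1) spatial-shape peak.

## Event detection and alignment

Mitotic dips are local minima of the amplitude after a 3-frame moving
average, kept when their prominence exceeds 15% of the amplitude maximum,
then refined to the raw minimum within ±2 frames. Movies are assumed to
run into gastrulation, so the last dip is labelled the 13th division; an
explicit labelling can be supplied instead. Alignment shifts each
embryo's time axis so that dip sits at t = 0 and resamples by linear
interpolation onto a shared 0.5-min grid (the acquisition interval)
snapped so t = 0 is on-grid; the grid spans the union of shifted ranges
with absent samples marked NaN, and point-wise mean/SD use only grid
points where at least two embryos overlap.

The cycle-14 amplitude metric is the mean over a window opening 20 min
after the 13th division (configurable): with recovery timescales of a few
minutes this skips the post-mitotic transient so the metric reflects the
plateau, and for a noiseless synthetic embryo it reproduces the
generating plateau within a fraction of a percent.

## Boundary fit

The anterior 40% of the spatial mode is fitted with
f(x) = baseline + (plateau − baseline)·xⁿ/(λⁿ + xⁿ) by bounded
least squares (λ ∈ (0.01, 0.39), n ∈ (0.5, 30), baseline free — mutants
retain residual polar Cic). Initialisation: λ₀ at the mode's mid-range
crossing, n₀ = 4. f(λ) is the baseline/plateau midpoint by construction,
so λ is definitionally the half-maximal position. A profile whose dynamic
range over the region is below 5× an estimated noise floor (robust SD of
second differences) is declared degenerate rather than fitted. The fit is
invariant to overall scaling of the mode.

## Single-cell recovery

Cycle-14 nuclei are detected on a reference frame late in the cycle as
local maxima of a difference-of-Gaussian response inside the dorsal band,
gated by the in-embryo Otsu brightness threshold, refined to DoG-weighted
centroids, and restricted to the mid-body (x ∈ [0.28, 0.72]) because the
steep boundary gradients produce blob-like responses at the poles.
Nuclei are linked by position (cortical cycle-14 nuclei are static in
this model; no tracking across divisions is attempted), and per-frame
intensity is the mean over a disc of radius half the minimum
inter-nucleus distance. Each trace is fitted with
I(t) = plateau·(1 − e^{−t/τ}) for t ≥ 0 (t = 0 at the 13th division).
Because "recovery time" admits several definitions, both τ and
t½ = τ·ln 2 are reported; comparisons use τ by default.

## Statistics

Genotype comparisons are two-tailed Student's t-tests with pooled
variance by default (Welch available), coded n.s./*/**/*** at
0.05/0.005/0.0005. No multiple-testing correction is applied by default;
a Bonferroni flag exists. Degenerate zero-variance equal-mean pairs
report p = 1.

## Synthetic embryos

The generator emulates the statistical structure the analysis assumes,
with every quantity annotated as ground truth.

**Spatial profile.** Double sigmoid
S(x) = floor + (plateau − floor)·H(x; λ, n)·H(1 − x; λ_post, n) with
H the Hill function; the posterior boundary mirrors the anterior
(λ_post = λ measured from the posterior pole) since only the anterior
40% is analysed and the posterior shape is a free convention. Wild-type
defaults: plateau 100, λ = 0.12, n = 6, floor 5, chosen so the mid-body
(x ∈ [0.3, 0.7]) mean sits within 2% of the plateau — the uniform central
~50% expected of this pattern.

**Temporal amplitude.** Nuclear cycles 10–14 with interphase durations
8/10/12/14/50 min and 3-min mitoses (only the ordering and cycle-14
dominance matter downstream; total 106 min fits a 3-h recording at one
frame per 30 s). Within each interphase the amplitude recovers as
A_c·(1 − e^{−t/τ}) from zero — first-order nuclear import — with
per-cycle plateaus at 40/55/70/85/100% of the cycle-14 plateau; during
mitosis it decays with timescale (mitosis duration)/6, reaching e⁻⁶ of
the pre-mitotic level, and the annotated mitosis frame is the amplitude
minimum in the mitosis window. Wild-type τ = 3 min, in line with
recovery completing within the short early interphases.

**Kymograph and noise.** X = ŝ·aᵀ with ŝ the dimensionless profile shape
(peak ≈ 1) and a in intensity units, so the kymograph plateau equals the
genotype's plateau amplitude. Noise is multiplicative Gaussian speckle
(CV 5%) plus additive Gaussian detector noise (SD 2, i.e. 2% of the
wild-type plateau), clipped at zero — the standard fluorescence-imaging
decomposition. Zero noise gives an exactly rank-one matrix.

**Movie rendering.** Pixels inside an ellipse (default semi-axes 132 × 40
px in a 120×300 frame, AP axis horizontal) take the kymograph value at
their fractional AP coordinate. Nuclei are Gaussian spots (σ = 1.5 px,
multiplicative contrast 0.6) at band mid-depth whose brightness follows
each nucleus's own first-order recovery and vanishes during mitosis.
Spots are rendered *flux-normalised*: each spot's depth-averaged
band-sampling response is subtracted along its AP extent, so the dorsal
band average equals the tissue kymograph value by construction. This is
the generator's self-consistency convention — the kymograph is defined
as the band mean of the image, and real spot brightness comes out of the
inter-nuclear background rather than being created on top of it. Movie
noise is applied per pixel to the rendered noiseless kymograph.

**Ensembles.** Members get distinct start-phase offsets (initial frames
cropped; offsets drawn without replacement, since trapped embryos arrive
at different developmental ages) and ±5% jitter of plateau, λ, n and τ.
Everything is deterministic given the base seed, via spawned seed
sequences.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: embryo-to-embryo variation in shape and
orientation beyond a rigid ellipse; optical effects (point-spread blur,
depth attenuation, bleaching); nuclear crowding, movement and division
geometry; biological deviations from exact separability (the real test
of which is the accuracy ratio itself); and any genotype-specific real
intensity, λ or τ value, which require the original movies.

## Extraction pipeline

Geometry is fitted once per movie on the temporal mean of a 21-frame
mid-movie window (trapped embryos do not move; averaging lets the dim
poles segment reliably). Thresholding is Otsu-initialised and refined to
median + 4·1.4826·MAD of the sub-Otsu pixels — a robust background
estimate, since the sub-Otsu population contains the dim embryo tail that
would inflate a mean/SD estimate. The ellipse comes from the second
moments of the filled binary component; binary rather than
intensity-weighted moments, because intensity weighting would shrink the
fitted axis toward the bright mid-body and bias the egg-length scale.

The dorsal band spans 5–15% of the semi-minor axis inward from the dorsal
boundary (the cortical nuclear layer, clear of edge pixels), sampled at
n_positions equal steps of fractional egg length × 5 depths by bilinear
interpolation, averaged over depth. Near the poles samples are clamped at
the AP axis and shrunk to 98% of the ellipse radius so they never mix in
background pixels. AP polarity is flag-controlled ("keep" = anterior at
the lower-column end, "flip", or "auto", which picks the orientation
whose anterior 40% is better fitted by a rising Hill boundary); dorsal
identification is likewise a convention (top edge) with "flip" available,
since neither is recoverable from a cross-section alone.

## Numerical choices and problem sizes

Curve fits use bounded trust-region least squares with analytic-free
Jacobians; non-convergence is flagged, not silently accepted. Default
grids: 100 AP positions, 0.5-min time grid. The test-suite simulations
use 10–50 embryos per check and 500 simulated pairs for the type-I-error
calibration of the comparison stage (expected rejection ∈ [0.02, 0.08]
at α = 0.05) — sizes at which the binomial uncertainty of the checked
rates is comfortably inside the asserted bands.

## Known limitations

Only cycle 14 is analysed at the single-cell level; there is no nuclear
tracking across mitoses and no 3-D segmentation. The last-dip-equals-
13th-division rule fails for movies truncated before gastrulation —
supply explicit dip labels in that case. The t-tests assume approximate
normality of per-embryo metrics; with 3–10 embryos per genotype this is
an approximation inherited from the experimental design. λ is only
meaningful for profiles whose anterior boundary lies inside the fitted
region (λ < 0.39 by construction).
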
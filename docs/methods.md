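# Methods

## The structural model

`metagrad` quantifies how well a tumor's 3-D FDG uptake pattern conforms to
an idealized elliptically contoured structure, and extracts what the
deviation and the radial shape of the pattern say about the tumor.

Each in-mask voxel contributes a pair `(x, Y)` of world coordinates (mm)
and SUV. The spatial reference is a rigid ellipsoid with location `mu` and
SPD shape matrix `Sigma` (mm²); a voxel's radial coordinate is the squared
Mahalanobis radius

    u(theta) = (x - mu)' Sigma^{-1} (x - mu),      theta = (mu, Sigma),

so `u = 1` is the reference surface. No square root is taken: `u` is
quadratic in distance, and all derivatives below are with respect to this
`u`. Uptake is modelled semiparametrically as

    Y_i = f[u_i(theta)] + eps_i,

with `f` a shape-constrained nonparametric step function: unimodal
(nondecreasing up to a mode, then nonincreasing). The unimodal class
contains the monotone-decreasing profile of a homogeneously avid tumor as
the special case mode = 0, and additionally describes a necrotic core —
low central activity rising to an avid rim before decaying into
background.

Fitting profiles `f` out exactly: for fixed `theta` the inner least-squares
problem over unimodal step functions is solved by scanning the mode
position and running pool-adjacent-violators (PAVA) isotonic regressions on
the prefix (increasing) and suffix (decreasing) of the u-sorted sample;
`theta` is then chosen to minimize the profiled residual sum of squares.

### Identifiability and optimization

`u` is invariant to `(mu, Sigma) -> (mu, c Sigma)` up to rescaling of the
radial axis, which leaves the step-fit RSS unchanged; the radial scale is
therefore a convention, not an estimable quantity. The fitter pins
`det(Sigma)` to the value of the moment initializer (uptake-weighted voxel
covariance), and reported `u` values, mode locations and gradient
magnitudes are in that per-study radial scale. Direction and anisotropy of
`Sigma`, and `mu`, are identified.

The search initializes `mu` at the uptake-weighted centroid and `Sigma` at
the uptake-weighted spatial covariance (for any radial uptake pattern the
weighted covariance is proportional to the true shape matrix, so the
initializer is already direction-consistent), parameterizes `Sigma` by its
log-Cholesky factor, and refines all nine parameters with Powell's
derivative-free line-search method, restarted from perturbed initial
points (fixed seeds) with the best final RSS retained. Powell was chosen
over a simplex search because on these objectives it reliably drives the
profiled RSS several orders of magnitude lower at equal evaluation budget,
which matters for the noiseless-phantom exactness checks; line searches
suit the objective's long curved valleys. During the search the mode scan
is capped at 64 order-statistic candidate positions (and samples beyond
3000 voxels would be aggregated into equal-count bins); the profile at the
optimum is recomputed with the full cap of 200 candidate modes, or
exhaustively below 200 voxels.

One subtlety arises in the near-exact regime (profiled RSS below 1e-8 of
`sum Y^2`, as for noiseless phantoms): the step fit can absorb uptake
scatter across near-tied radii that no *function* of `u` can reproduce, so
the step-SSE objective under-reports the residual that the smoothed
profile will eventually see. In that regime only, `theta` receives a final
short polish against the smoothed-profile RSS itself, which drives the
reported noiseless H0 to the 1e-12 level; noisy fits never enter this
branch.

### Smoothing and metabolic gradients

The optimal step fit is piecewise constant, so a cubic smoothing spline is
fit to the step values to obtain a differentiable profile `f~`. The
smoother is a penalized cubic B-spline: knots at quantiles of `u` (at most
64 basis functions), a second-divided-difference penalty on the
coefficients over the Greville abscissae (exactly zero for any linear
function, so constants and lines are reproduced unpenalized), and penalty
weight chosen by minimizing the generalized cross-validation score
`n RSS / (n - tr H)^2` over a 29-point log-spaced grid. The GCV search is
done on this explicit basis because the hat-matrix trace is then exact and
cheap, and the selection remains well-behaved in the noiseless limit,
where black-box smoothing-spline GCV can collapse. Duplicate radii are
collapsed to their mean step value with multiplicity weights.

Per-voxel signed metabolic gradients follow by the chain of definitions

    g_i  = -f~'(u_i)            raw gradient (SUV per unit u)
    g~_i = g_i / max_i f~(u_i)  normalized to the study's fitted peak
    gY_i = Y_i g~_i             uptake-weighted.

The sign convention: inside the mode of a necrotic-core profile uptake
still rises with radius, so `g < 0` there; on the decaying flank `g > 0`.
The normalizer is the maximum *fitted* (smoothed) value, not the raw
SUVmax, so a single hot voxel cannot deflate every normalized gradient.
Each gradient family is summarized by its 25th and 95th
linear-interpolation percentiles, giving the structural feature frame
`g[0.25], g[0.95], g~[0.25], g~[0.95], gY[0.25], gY[0.95]`.

### Heterogeneity

With fitted values `Yhat_i = f~[u_i(theta_hat)]` and
`RSS = sum (Y_i - Yhat_i)^2`:

    H0 = RSS / (sum Y_i^2 / N),        H1 = RSS / Var(Y).

Both are implemented exactly in this form. Note that for fixed relative
noise both statistics then grow linearly with the voxel count N; a
`h0_mean_normalized` option divides by `sum Y_i^2` instead (dividing H0 by
N) for users who prefer an intensive statistic. `Var(Y)` uses the sample
(n-1) denominator by default; configurable.

## Segmentation and quantization

The crude input VoI (box or ellipsoid in world mm, as drawn around a tumor
by a reader) is assumed to contain the tumor plus a modest rim of
background. The per-study threshold is computed from the subsample `S` of
the lower 15% of in-VoI uptake (linear-interpolation quantile cut, ties
included low): `t = mean(S) + 3 sd(S)`, with the sample (n-1) sd
convention (configurable). Voxels strictly above `t`, restricted to the
largest 26-connected component, form the segmented VoI used for *both*
structural and textural features. Two interpretation points the rule
leaves open are resolved as: strict inequality `Y > t`, and a single
connected component (to drop satellite background speckle). The rule
presumes the dim in-VoI shell is tumor-margin/background gradient; on a
VoI dominated by flat noise the threshold falls near the background mean
and delineation degrades — crude VoIs should be drawn around the tumor,
not around the field of view.

In-mask SUV is requantized to Q = 32 gray levels by fixed bin number:
`level = floor((Q-1)(Y - min)/(max - min)) + 1`, over in-mask voxels only,
with no resampling beforehand.

## Radiomic features

Feature definitions follow IBSI conventions; names carry their frame
suffix (`.HIST`, `.GLCM`, `.GLSZM`, `PCA.*`).

* Histogram (12): mean, median, variance, skewness, excess kurtosis and
  CoV on raw SUV; entropy (base 2) and uniformity on the Q-level
  histogram; histogram-gradient max/min and their gray levels from
  differences of successive bin counts, attributed to the upper level.
* GLCM (8): symmetric co-occurrences at distance 1 over the 13
  sign-collapsed grid directions, normalized per direction to sum 1;
  entropy (bits), dissimilarity, homogeneity (inverse difference),
  contrast, autocorrelation, maximum probability, correlation and
  uniformity (angular second moment), each averaged over directions at the
  feature level. A flat region has correlation defined as 1.
* GLSZM (2): 26-connected equal-level zones; zone-size non-uniformity
  (`Size.zone.GLSZM`) and gray-level non-uniformity (`Intensity.GLSZM`).
  The printed feature names in this family are ambiguous in the
  literature; the IBSI non-uniformity pair was chosen.
* Morphology (6): asphericity `S/(36 pi V^2)^(1/3) - 1` (the
  dimensionally consistent form) with `V` from voxel count and `S` from a
  marching-cubes mesh at the 0.5 iso-level of the mask indicator, lightly
  mollified with a 0.7-voxel Gaussian — raw binary isosurfaces carry an
  ~8% staircase surface bias that the mollification removes (a digitized
  ball then reads |asphericity| < 0.03); axis lengths `4 sqrt(lambda)`
  from the population covariance of voxel centers, plus elongation
  `sqrt(lambda_minor/lambda_major)` and flatness
  `sqrt(lambda_least/lambda_major)`.
* Avidity: SUVmax, SUVmean, segmented volume (ml), TLG = SUVmean x volume
  (reported in the clinical frame).

Directions and zones are defined on the grid without interpolation,
appropriate for near-isotropic PET voxels.

## Feature frame and exploration

The per-study vector has 44 variables in three frames: clinical 8 (grade,
volume, subtype, age, sex, SUVmax, SUVmean, TLG), structural 8 (H0, H1 and
the six gradient quantiles), textural 28 (asphericity, 5 PCA-morphology,
12 histogram, 8 GLCM, 2 GLSZM). Grade enters analyses as an ordinal
(1/2/3), sex as a male indicator, subtype as bone/cartilage indicators
(STS baseline); constant columns are excluded from correlation and PCA
with a warning.

Exploration: Pearson correlation of the continuous variables; scaled
(correlation-based) PCA of the z-scored table retaining the smallest
number of leading components reaching a configured explained-variance
fraction (default 0.95); k-means (fixed seed, 25 restarts) of each
variable's loadings in the retained component space; and per-study
cluster-centroid covariates defined as the mean of the z-scored member
variables of each cluster — the mean rather than the raw sum, so cluster
size does not inflate the covariate's variance when the scores are used in
downstream risk models. Survival modelling itself is out of scope; the
covariates are exported as a tidy table.

## Synthetic phantoms

The phantom generator is the package's test bed and stands in for clinical
data, which cannot be shipped. A phantom is a 64³ grid at PET-like
anisotropic spacing (4.30 x 4.30 x 4.25 mm) containing a rotated triaxial
ellipsoidal tumor (semi-axes 30/24/18 mm, i.e. about 7-4 voxels), radial
profile either `peak * exp(-u/decay)` (monotone, peak 10 SUV above a
background of 1, decay scale 0.8 in u units) or a necrotic-core variant
(linear ramp from a core SUV of 2.5 to the peak at mode radius u = 0.6,
then the same exponential decay), evaluated exactly from the ground-truth
`u`, then blurred with an isotropic Gaussian PSF (10 mm FWHM by default,
the reconstructed resolution of older FBP systems), plus i.i.d. Gaussian
noise (default sd 0.2 SUV; the test batches use 0, 1 and 3 SUV = 0, 10 and
30% of peak), clipped at zero. The seed governs noise only; geometry is
deterministic, and a fixed (spec, seed) pair is bit-reproducible.

What the phantom does *not* emulate: sinogram-level reconstruction
(correlated FBP streak noise, object-dependent resolution), anatomical
background structure, respiratory motion, or partial-volume effects beyond
the Gaussian PSF. Passing the recovery tests therefore demonstrates
correctness of the estimator under the model's own assumptions plus blur
and additive noise — not robustness to every clinical artifact.

Crude VoIs for phantoms are axis-aligned ellipsoids at the true center
with semi-axes 1.4x the true bounding semi-axes, emulating a reader's
drawn VoI (tumor plus a small background rim).

## Problem sizes and numerical choices

Test batches use 20 moderate-noise replicates for parameter recovery and
10 seeds per noise level for the heterogeneity-vs-noise check, on the 64³
grid (about 1.4-1.7 thousand segmented voxels per study); these sizes give
stable medians while keeping a full run in minutes on one core. Powell
refinement uses ftol 1e-10 with at most 12 cycles per start and 2 starts.
Ties in `u` are resolved by stable sort. Degenerate inputs are contracts,
not crashes: constant uptake returns the moment-initialized ellipsoid with
zero RSS (H1 undefined, NaN); coplanar voxel sets and samples below 30
voxels raise errors; a constant in-mask volume cannot be quantized and
raises.

## Known limitations

* The radial scale of `Sigma` is conventional (see identifiability);
  mode radii and raw gradients are comparable within, not across, studies
  unless rescaled — the normalized gradients exist for exactly this
  reason.
* H0/H1 as defined grow with N at fixed relative lack of fit.
* The GLSZM feature-name mapping and the histogram-gradient difference
  convention are documented choices among published variants.
* The threshold rule assumes the crude VoI is tumor-dominated; it is not a
  general-purpose background/noise segmenter.
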
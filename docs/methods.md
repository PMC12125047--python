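# Methods

## Photon transport model

Light propagation in the phantom is modeled as a hop-drop-spin random walk
in a homogeneous absorbing/scattering medium. Step lengths are sampled
from the exponential with attenuation μt = μa + μs; at each interaction a
fraction μa/μt of the packet weight is deposited and the remainder is
deflected by a Henyey–Greenstein angle (analytic inverse-CDF sampling of
cos θ for anisotropy g). Packets below weight 1e-4 enter Russian roulette
with survival factor 10; the survival boost and killed weight are both
recorded, so the audit closes exactly:
specular + absorbed + escaped + killed − created = launched.

Fluence is tallied with the track-length estimator: every voxel crossed by
a sub-step accumulates weight × pathlength (Amanatides–Woo traversal, one
voxel-face crossing per iteration), divided by voxel volume and normalized
by the incident photon fluence N/A_beam. This estimator stays well defined
at μa = 0, where the absorbed-weight estimator degenerates, and makes a
non-scattering matched-index medium reproduce exp(−μa z) on axis to within
counting noise (verified to <1% in the tests). The per-interaction
absorbed-weight tally is kept as the independent energy audit.

Geometry: depth z = 0 at the illuminated surface increasing into the
medium; the beam axis is the lateral grid center (lateral voxel counts are
forced odd so a voxel column sits on the axis). The top face is an
unpolarized air/medium Fresnel interface — specular entry reflection is
deducted from the launched weight, internal reflections (including total
internal reflection beyond 45.6° for n = 1.4) are sampled stochastically.
The bottom face absorbs totally, emulating the black foil placed beneath
the phantom; lateral faces absorb, with the escaped fraction logged. The
slab forward model used for optical-property work differs only in having a
Fresnel bottom face and unbounded lateral extent.

A single seeded generator drives each kernel, single-threaded, so a fixed
(configuration, seed) pair reproduces tallies bit-identically.

Default desk-scale grid: lateral width max(3 × spot, 6 mm), depth 5.5 mm,
0.05-mm voxels. The voxel size is a free parameter because the source
description of the production grids is internally inconsistent (counts ×
voxel pitch disagree with the stated domain centers by a factor of ten);
all results here are voxel-size-converged at 0.05 mm. Photon budgets of
1e6–4e6 replace the 1e9-photon production runs; because those reference
maps are effectively noise-free, the pipeline denoises its desk-scale
axial slice with a σ = 0.1 mm Gaussian before the slice is consumed, and
the same smoothed slice feeds both image synthesis and fluence binning, so
the smoothing cannot bias the recovered dose-response.

## Inverse Monte Carlo

(μa, μs) are estimated from total slab reflectance and transmittance
(specular included) with g and n fixed, minimizing the squared relative
misfit of (R, T). Every objective evaluation reuses one MC seed (common
random numbers), making the objective a deterministic, quasi-smooth
function of the parameters. A 5 × 5 coarse grid in log-parameter space
(span ±1.8, quarter photon budget) brackets the optimum; Nelder–Mead then
refines from the best node with a large initial simplex (0.45 in log
space) so residual MC noise cannot collapse it prematurely. Positivity is
enforced by the log parameterization. A fit is declared converged when its
residual is consistent with the binomial noise floor of the photon budget.
The integrating-sphere instrument is idealized as a bare 1-mm slab in air
(no glass slides or sphere corrections).

## Synthetic phantom imagery

Pre-irradiation images are Gaussian background texture (mean 90, sd 3, 8
bits) plus sparse 1-px bright specks (25 /mm², the debris the extraction
stage must learn to remove). Post-irradiation images add cavity disks by
an inhomogeneous Boolean process: with per-pixel center intensity λ and
mean stamped disk area A, coverage is 1 − exp(−λA), so stamping at
λ(x) = −log(1 − p(x))/A makes the expected covered fraction track the
clamped logistic p(x) exactly; the calibration is verified to ±0.003
absolute on uniform-fluence fields. The center field is padded by the
maximum radius so edge pixels see the correct center intensity.

Cavity radii are drawn uniformly from 6–20 µm (vacuole-scale bubbles
around pigment organelles). Two considerations fix this range: it matches
the `tiny cavity' scale seen in phantom cross-sections, and it sets the
number of independent cavities that carry each 0.1-J/cm² bin of the
dose-response. The per-bin counting noise of a covered-area fraction is
binomial at the cluster (not pixel) level, sd ≈ sqrt(p(1−p)·A/n_px); with
~50-px clusters the rise-region bins of a 2-mm-spot experiment hold only
tens of clusters and no estimator can recover the sigmoid slope reliably,
while at the chosen scale (~5.5-px clusters) recovery is comfortably
within the stated tolerances. Cavity pixels are brightened by +40 gray
levels: the segmentation rule needs an excess of ≥10 over the local mean,
and the local mean is self-inflated by up to the plateau coverage (~0.24),
leaving a worst-case margin of 40 × (1 − 0.24) ≈ 30 ≫ 10.

Per-shot fluence jitter (uniform ±f multiplier, emulating device output
stability of e.g. ±20%) is available but off by default: the analysis bins
with the nominal simulated map, so jitter makes the recovered threshold a
biased estimate of the generating one (≈ −0.03 J/cm² at ±20%), which would
confound the calibration contract the generator exists to support.

What the generator does not emulate: coherent speckle, physical bubble
nucleation and growth, melanosome-scale optics, camera vignetting and
focus. Passing the end-to-end tests therefore shows the analysis chain is
calibrated for images whose cavity statistics follow the assumed
dose-response — not that the chain is robust to every real-image artifact.
Surface saturation artifacts can be switched on
(`surface_artifact_fraction`) to exercise the 0.19-mm exclusion rule.

## Cavity extraction

A pixel is a cavity candidate when its value exceeds the mean over the
circular neighborhood of radius 0.1 mm (center pixel included) by ≥10 gray
levels. At image borders the mean is taken over the disk ∩ image. The
implementation decomposes the disk into per-row runs evaluated with exact
cumulative sums — integer pixel values sum exactly in float64 — so it is
pixel-for-pixel identical to the naive O(N·r²) reference (tested). Note an
arithmetic consequence of including the pixel in its own neighborhood: a
feature exactly +10 above a flat background inflates its local mean and is
never marked; the rule requires a strictly larger increment.

Connected components use 8-connectivity. Noise removal deletes
post-irradiation components strictly smaller than the mean component area
of the paired pre-irradiation mask (identity when the pre mask is empty);
the mean is computed per image pair. The surface band of
ceil(0.19 mm / pixel) rows below the surface row is cleared from masks and
from both numerator and denominator of all downstream ratios.

## Dose-response estimation

The fluence slice is resampled bilinearly onto the finer image grid
(masks are never interpolated), laterally shifted so the simulated beam
axis coincides with the centroid of the mask pixels, and pinned at the
surface row in depth. The cavitation ratio in bin [x, x + 0.1) is
(cavity pixels with fluence in bin)/(all pixels in bin); empty bins are
NaN, never 0/0. Replicates contribute per-bin means, with the
across-replicate sd retained.

Curves from irradiation fluences 2/3/4/5 J/cm² contribute only in-phantom
fluence intervals [0,2), [2,3), [3,4), [4,5) respectively to the pooled
fit set (low-fluence bins of high-fluence shots are far off axis and
noisy); a full-range fit is reported alongside as a sensitivity check.

The four-parameter logistic is fitted by least squares with positivity
bounds on L and k, initialized at L₀ = max−min, b₀ = min, x₀₀ = half-rise
abscissa, k₀ = 4/rise-span. For pipeline data the fit is weighted by the
inverse cluster-binomial variance p(1−p)·A/n per bin, with weights
iterated twice from the fitted curve (IRLS). Unweighted least squares —
the naive reading of "least-squares fit" — proved unstable here: bins
holding a handful of cavity clusters get the same vote as bins holding
thousands, and across repeated synthetic experiments the unweighted slope
estimate wandered with sd ≈ 1 (occasionally diverging), versus ≈ 0.15
weighted. Degenerate (constant) inputs, non-convergence and an inflection
outside the data range are flagged in the diagnostics, with parameters
still reported.

## Depth prediction

On-axis fluence is the mean over the 3 × 3 voxel column around the axis
(MC-noise suppression). The threshold depth is the deepest depth at which
absolute fluence still reaches the threshold, linearly interpolated
between bracketing voxel centers — deepest rather than first crossing
because backscatter makes the near-surface profile non-monotone; a map
that never reaches the threshold returns NaN. Ratio-vs-depth profiles are
clamp(sigmoid(F(z)), 0, 1) pointwise, tabulated per spot size and
irradiation fluence.

## Problem sizes and numerical choices

Desk-scale runs use 1e6–4e6 photons for fluence maps (4e6 for the
end-to-end recovery experiment), 2e5–3e5 for slab measurements, 1e5–1.5e5
per inversion objective evaluation, 5 replicate image pairs per fluence at
0.01-mm pixels, and the grids above. At these sizes the end-to-end
experiment recovers (L, x₀, k) with spread ≈ (0.01, 0.05, 0.16) about the
generating values and the inversion recovers μa within ~1% and μs′ within
~2%. Tolerances used in tests follow directly from these statistics.

Known limitations: single homogeneous layer (no epidermis/dermis
structure, no spatially varying melanosome density); unpolarized light;
collimated normal incidence assumed for the clinical handpiece; the
integrating-sphere idealization above; cavity morphology reduced to
uniform-brightness disks.
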
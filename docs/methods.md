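# Methods

This note documents the models and numerical choices behind each pipeline
stage, the synthetic data the validation rests on, and the limits of what
passing tests demonstrate.

## Coordinate and frame conventions

All volumes are native-space arrays with axis 0 as the left–right axis and
an even size along it, so the hemispheric midline is a grid plane and
mirroring is an exact voxel permutation (an involution).  The left half is
the contralateral (reference) hemisphere; lesions are planted on the
right.  Frame ordinals quoted protocol-style ("bolus at the 180th image",
"truncated at the 400th image") are 1-based and converted to 0-based
indices exactly once, at the container boundary
(`DscSeries.from_ordinals`); everything internal is 0-based.

## Parametric maps

**ADC.** With only two b-values (0 and 1454 s/mm²) the monoexponential fit
is closed-form per gradient direction, ADC_d = ln(S₀/S_b)/b, and the map
is the arithmetic mean over the three directions.  Voxels with
non-positive signal are dropped from the fit mask rather than clipped
(clipping would silently bias low-SNR regions); negative ADCs from noise
are retained in the values but excluded from the mask so downstream users
choose their own policy.

**T2.** The multi-echo fit is log-linear least squares of ln S against TE
with S² weights — the first-order variance-stabilizing weight for
log-transformed magnitude data — followed by one reweighting pass using
the *fitted* signal, which makes the estimator a Gauss–Newton step of the
nonlinear least-squares problem.  This matters because at SNR 50 the
190 ms echo of ~50 ms tissue has near-unity SNR: the unweighted log fit
deviates from nonlinear least squares by ~13% (median), the weighted
one-pass fit by ~2%, and the reweighted fit by ~0.4%.  Flat or rising
signal (infinite or undefined T2, e.g. pure noise) is flagged out of the
fit mask.  The fit operates on magnitude data; complex-valued fitting
would require phase information the pipeline does not model.

## DSC perfusion

**Concentration.** C(t) = −ln(S(t)/S₀)/TE with S₀ the mean over a
baseline window (default frames 20–170, 1-based: after the approach to
steady state, before the injection at frame 180).  Frames with
non-positive signal are masked and set to zero concentration; voxels whose
baseline is non-positive are invalid.  The proportionality constant
between ΔR2* and gadolinium concentration is set to 1: every downstream
quantity is contralateral-relative, so the constant cancels.

**Arterial reference.** The arterial curve comes from the contralateral
hemisphere.  Candidate voxels (excluding any with masked frames, which are
air or near-zero-baseline artifacts) are ranked by the sum of three ranks
— tallest peak, earliest arrival (first crossing of 10% of peak), smallest
first-moment width — and the top k = 10 curves are averaged.  The ranking
is deterministic with index-order tie-breaks.  A manual mask can be
supplied instead.

**Deconvolution.** The circular convolution model c = A r is inverted by
truncated SVD of the block-circulant AIF matrix.  A circulant matrix is
diagonalized by the DFT, so its singular values are |DFT(aif)|·Δt and
truncated-SVD inversion reduces to masked spectral division — numerically
identical to the dense formulation but fast enough to deconvolve whole
cohorts.  Curves are zero-padded to twice the window length to avoid
wrap-around.  Per voxel, a ladder of truncation thresholds (0, 0.02, 0.04,
0.06, 0.08, 0.10, 0.13, 0.17, 0.22, 0.30, 0.40, 0.50 of the largest
singular value) is scanned from weakest to strongest regularization and
the first whose reconstructed residue r(t) satisfies

    OI = (1/L) · (1/max r) · Σ_k |r(k) − 2r(k+1) + r(k+2)| ≤ 0.17

is selected (the most-faithful admissible solution; if none passes, the
strongest rung is used).  The OI formula is pluggable.  CBF is the residue
peak, searched only over physically admissible lags (up to the post-bolus
window length).  All-zero tissue curves return CBF = 0 by contract; an
all-zero AIF is an error.

**CBV and MTT.** CBV is the trapezoidal integral of the concentration
curve from the first frame through the truncation frame (the 400th image;
later frames, contaminated by recirculation, have no effect — this is
bit-exact by construction).  Negative concentration excursions are clipped
to zero for the integral but retained for the deconvolution, which is a
linear-systems operation.  When an AIF is supplied the integral is
normalized by the AIF integral over the same window.  MTT = CBV/CBF where
CBF exceeds a small epsilon and is masked (zero) elsewhere, so the output
maps satisfy MTT = CBV/CBF exactly wherever defined.

**Known estimator behavior.** At the in-vivo frame interval (164 ms) the
AIF spectrum decays steeply, so regularized inversion rounds the residue's
leading edge and underestimates peak CBF — strongly at low flow.  This is
the well-known oSVD bias and is the reason the analysis uses only
contralateral-relative quantities, in which multiplicative bias largely
cancels.  The recovery validation therefore uses the standard
deconvolution-validation design — Δt = 1 s, 140 frames, bolus at frame 20,
a first passage fully contained in the window, residue support limited so
the discrete model is exactly invertible — isolating estimator error from
window truncation.  Measured with the default ladder: noiseless maximum
CBF error 2.0% (the residual (Δt/MTT)²/12 quadrature bias), SNR-50 median
error ~14%.

**Residue normalization.** Discrete residues are scaled so their
*trapezoidal* integral equals MTT.  This matches the CBV integrator, makes
∫C = CBV·∫AIF hold to machine precision in the forward model, and leaves
the residue peak within O((Δt/MTT)²) of one — the rectangle-rule
alternative costs Δt/(2·MTT) of peak amplitude (4% at MTT = 2 s on the
in-vivo grid; 25% on the validation grid), which would be pure estimator
bias.

## Lesion segmentation and tissue fate

Reference statistics (mean, SD, median) are computed from the
contralateral S1FL + S2 + CPu territory after CSF exclusion by atlas label
*and* by parameter cutoffs (ADC > 1.2×10⁻³ mm²/s or T2 > 90 ms are
CSF-like; conventional rodent values, configurable).  A floor of 100
reference voxels and a strictly positive SD are enforced.  Thresholds are
strict inequalities: acute = ADC < x̄ − 2sd, subacute = T2 > x̄ + 2sd,
ipsilateral non-CSF voxels only.

Manual noise correction is replaced by a deterministic surrogate: removal
of 26-connected components below 50 voxels, then morphological closing
with the face-connected (6-neighbour) structuring element — with
0.3×0.3×1.2 mm voxels the 26-neighbour cube over-dilates thin parcels.
The remove/close pair is iterated to a fixed point (closing can leave
sub-floor crumbs near borders), which makes the cleanup idempotent by
construction.

Fate algebra is exact set arithmetic (core = acute ∩ subacute,
salvageable = acute \ subacute, delayed = subacute \ acute), so the
partition identities hold identically, not approximately.  Lesion location
(cortical / subcortical / diencephalic, an outcome-model covariate) is the
majority atlas label of the acute mask.  Volumes are reported in µL and as
hemispheric fractions; the 30 µL acute-lesion inclusion rule is applied as
a flag, and excluded subjects never reach the statistics stage.

## Perfusion profiles

rr indices are plain ROI-mean ratios (×100) against the mirrored
homologue; non-physiological voxel values are *not* trimmed (an optional
winsorizing flag exists, off by default) — the binning path is the
designed mitigation for contaminated small-ROI means.  Repercentaging
divides each voxel by the contralateral-hemisphere median (positive voxels
inside the perfusion mask).  Binning uses the 85–115% band with strict
inequalities, so the band edges are normoperfused; for MTT the classes are
reversed (short transit = hyperperfusion).  Class fractions are counts
over the ROI size; because the float divisions round, the returned triple
is adjusted by at most a few ulps (via a small search over ulp
neighbourhoods) so that f_hypo + f_normo + f_hyper equals 1.0 exactly in
float arithmetic as well as in exact arithmetic.

Perfusion maps live on a coarser grid than the structural maps (as in the
acquisition protocol) and are resampled to the analysis grid by
nearest-neighbour repetition before ROI sampling.

## Statistical layer

**Mixed models.**  Each rr index is modeled as
session + occlusion duration + sex with a random intercept per subject,
fitted by REML (statsmodels MixedLM).  Fixed effects are tested with Wald
F statistics using between-within (containment) denominator degrees of
freedom — session: (n_subj − 1)(n_sessions − 1); between-subject factors:
n_subj − p_between − 1.  No Python backend implements the Kenward-Roger
correction, but for the balanced subject × session designs this pipeline
produces, between-within df coincide with it; the cross-check test against
lmerTest's KR ANOVA confirms the agreement, and the null simulation puts
the session-effect type-I error at ~4.6% (nominal 5%).  Post-hoc session
contrasts are Bonferroni-adjusted.  A singular fit downgrades to a
fixed-effects model with a warning flag.

**Fraction models.**  Voxel-class fractions are modeled by beta regression
with a log link (statsmodels BetaModel); boundary values are shrunk by
(y·(n−1)+0.5)/n, the standard transformation onto the open interval.  No
Python package fits a beta GLMM with random effects, so subject clustering
enters through cluster-robust standard errors — a marginal-model surrogate
for the random intercept; the cross-check test against R's glmmTMB (beta
family, random subject intercept) verifies that effect directions and
back-transformed hemisphere means agree.

**Multi-model inference.**  The candidate set for lesion volume change
(Gaussian) and SDS (Poisson, log link) is the nuisance base model
(occlusion × sex, scaled acute lesion volume, lesion location with
cortical reference) augmented with the four admissible perfusion subsets —
{rrCBF, rrCBV}, {rrMTT}, {rrCBV}, {rrCBF}; rrMTT never co-occurs with
rrCBF or rrCBV, of which it is the quotient — plus an intercept-only NULL.
Continuous predictors are scaled and centered, so coefficients are
standardized.  Models are ranked by AICc = AIC + 2k(k+1)/(n−k−1) with k
counting all estimated parameters (intercept and, for Gaussian models, the
residual variance).  Perfusion models are compared with the base by nested
F-tests (Gaussian) or likelihood-ratio tests (Poisson, an interpretation
of the same comparison); Nagelkerke R² is reported for the Poisson branch.
Models with n ≤ k + 1 are flagged unfit and dropped from the ranking.

## Synthetic data

**Phantom.**  A 40×40×8 slab at 0.3×0.3×1.2 mm voxels (≈691 µL per
hemisphere, a realistic rat scale at a desk-scale grid) with
mirror-symmetric parcellation: lateral cortex containing S1FL and S2,
striatum containing CPu, medial cortex, a ventricular CSF block, and a few
arterial voxels that survive downsampling to the perfusion grid.  Tissue
properties are rodent-typical (cortex ADC 0.76×10⁻³ mm²/s, T2 48 ms,
MTT 2.0 s; CSF ADC 2.6×10⁻³, T2 150 ms); smooth mirror-symmetric
heterogeneity (3% SD) gives the reference territory non-degenerate spread.
Truth maps satisfy MTT = CBV/CBF identically.  The planted lesion is an
ellipsoid in the right hemisphere partitioned into a radial core and an
anterior/posterior split of the shell into salvageable and delayed-injury
tissue; acute = core ∪ salvageable and subacute = core ∪ delayed by
construction.  Session-specific truth perturbations encode the biology:
ADC drops ~40% in acutely ischemic tissue and pseudo-normalizes; T2 rises
~60% in the subacute infarct; perfusion collapses during occlusion
(CBF ×0.22–0.45), delayed-injury tissue stays hypoperfused at 0.5 h
(CBF ×0.7), and the whole lesion becomes hyperperfused by day 4
(CBF ×1.3).

**Acquisitions.**  Forward models are the exact inverses of the fitters
(monoexponential DWI and multi-echo decay; T2* signal equation for DSC)
with additive Gaussian noise by default (Rician optional — at the SNRs of
interest the difference is negligible and Gaussian keeps oracles exact).
Baseline SNR defaults: 50 for the structural scans, 100 for DSC (whose
voxels are several times larger).  The DSC bolus is a gamma-variate
A·(t−t₀)^α·exp(−(t−t₀)/β) with α = 3, β = 1.5 s, injected at the 180th of
450 frames at TR 164 ms.  The pipeline presmooths DSC signal in-plane
(Gaussian, σ = 0.8 voxels), standard DSC preprocessing without which
voxelwise deconvolution noise dominates the voxel-class bins.

**Imaging cohort.**  Per subject, lesion geometry is jittered and the
salvageable share of the lesion shell is drawn by sex (females ~0.78,
males ~0.56, SD 0.08): with shell share s, the expected acute-to-subacute
volume change is (1 − 2s)/(1 + s), reproducing the observed sex difference
in lesion shrinkage.  The imaging cohort's between-subject spread is
narrower than a real cohort's, because fate composition is its only
biological variability.

**Table cohort.**  The statistics-layer generator draws subject-level
records directly: volume-change cell means −36.6/−26.2% (females,
45/90 min) and −11.4/−5.0% (males) with residual SD 20, lesion-location
effects (subcortical −20, diencephalic +18 points) sized so location is an
independent predictor, rr-index session profiles (e.g. rrCBF 30% during
occlusion, 100% at 0.5 h, 120% at day 4, with a male excess
post-recanalization), a shared subject intercept making the rr indices
correlate (~0.5) across parameters, couplings of volume change to the
standardized hyperacute indices (+15 per SD of rrCBF, −16 per SD of rrCBV,
0 for rrMTT), beta-distributed voxel-class fractions per
ROI × hemisphere × session (delayed-injury tissue hypoperfused at 0.5 h,
everything ipsilateral hyperperfused at day 4), and Poisson SDS scores
coupled weakly (−0.17 log-units per SD) to rrMTT.  The realized
distribution (females −35 ± 30%, males −11 ± 28%) and the model-ranking
behavior (the paired configuration first, NULL last, base adjusted
R² ≈ 0.47) match the study-scale effect structure this layer is designed
to detect.  Every effect is a parameter; the null-calibration experiments
zero them all.

## What the validation does and does not show

Parameter recovery on these phantoms demonstrates the correctness and
calibration of the *estimators* — not robustness to the many properties of
real data the generator deliberately omits: no realistic anatomy or
partial-volume mixing, no motion or registration error (inputs are assumed
co-registered), no bias fields or EPI distortion, no contrast-agent
recirculation or leakage, no Rician floor at very low SNR (unless
enabled), and no manual mask editing.  Dice targets are evaluated at a
defined contrast (4 contralateral SDs); real lesions have graded
boundaries.  The statistics layer is validated by simulation only; the
study's empirical coefficients are not reproducible without the original
animal data.

## Problem sizes

Validation experiments use 10³ voxels for deconvolution and noisy-T2
recovery, 20 phantom seeds for segmentation Dice, 1000 null cohorts for
mixed-model calibration (500 in the acceptance script), 200 replicates for
fraction-sign and model-ranking recovery, and a 40-subject imaging cohort
(≈45 s end to end on one CPU).
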
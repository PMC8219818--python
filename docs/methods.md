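# Methods

## Scope and model

The package analyses event-related BOLD responses to objects embedded in
scenes at six object-scene scale-consistency levels (level 1 = normal,
level 6 = mis-scaled by ×4), with four image properties per stimulus:
scale consistency, object retinal size, real-world object size, and
scene field-of-view (FOV).  Since no empirical recordings ship with the
package, every stage runs on a synthetic BOLD generator whose voxels
have known linear tuning to the four properties; the analyses are the
object of study, the generator is the instrument that makes them
testable.

## Stimulus design and property levels

Ten objects, five small (mis-scaled to be too large: toothbrush, teacup,
computer mouse, bedside lamp, frying pan) and five large (mis-scaled to
be too small: sofa, car, bus shelter, playground slide, pool table).
Real-world sizes (inches, 3D diagonal), base retinal sizes (degrees) and
base scene FOVs (degrees) are fixed plausible constants per object,
deliberately slightly irregular to avoid rank ties.  Two manipulations
per object: retinal size scaled by the level's factor with the scene
fixed, or scene FOV scaled with the object's retinal size fixed
(widening the FOV shrinks the surroundings, making the object relatively
larger).  The factor ladder is linear from 1 to 4 in steps of 0.6.

Nuisance properties are binned to ordinal levels by rank quantiles with
midranks for ties (retinal size: 5 levels; real-world size: 5; FOV: 4).
Rank binning is invariant to monotone transforms, so binning log or raw
real-world size is equivalent; tied raw values always share a level.
The factorial structure makes the scale-consistency level *exactly*
orthogonal to any object-constant property (each object contributes all
six levels equally), which the Spearman checks confirm to machine
precision; the nuisance properties are inter-correlated with one another
(retinal vs FOV ≈ −0.53) as an unavoidable consequence of using large
real-world objects for one mis-scaling direction and small ones for the
other.  Perceived-rating aggregation (0–5 scale) uses the per-image mean
rounded half-up; half-up is a documented choice where plain "nearest
whole number" leaves ties open.

## Scan schedule

Per scan: 120 stimulus + 20 task trials in 10 blocks of 14, blocks
alternating manipulation (FOV first — the alternation is specified, the
starting block is a package choice).  Trial = scene alone for
U(2, 3.5) s, object for 0.5 s, blank 0.5 s; task trials omit the object.
Presentation order is randomized within each manipulation's 60 images
under a no-consecutive-object constraint (rejection sampling; a valid
order of 6 copies × 10 objects appears about once per 150 shuffles, so
the retry cap is set generously at 2·10⁵).  10 s blanks separate blocks,
with 10 s leading and trailing blanks so that every scan has a baseline
before the first block and room for the final HRF to decay; expected
scan length ≈ 635 s (~10.5 min, 905 TRs at TR = 0.7 s).

## BOLD generator

Event amplitude per voxel: a_e = baseline + Σ_f w_f x_{e,f} for stimulus
trials (task trials: baseline only), with x the per-scan normalized
features.  A stick series at object-onset TRs (onsets rounded to the TR
grid; sub-TR timing is not modelled because all read-outs are in TR
units) scaled by a_e is convolved with a voxel-specific HRF — a gamma
bump with unit peak at a per-voxel delay of 6–8 TRs minus a small
delayed gamma undershoot (construction raises an error if the undershoot
ever displaces the argmax).  Overlapping responses sum linearly (the LTI
assumption the GLM itself makes).  Added on top: a constant offset of
100, per-voxel linear drift (slope ~ N(0, 0.003) per TR), and Gaussian
noise of sd 1.0 (an AR(1) option exists for robustness experiments;
default noise is white because the emulated acquisition is not
characterized further).  Baseline event amplitudes ~ U(0.8, 1.2) give
single-event z responses of order 1, a realistic event-related SNR.

Scenarios: `null` (all weights 0), `scale_negative` (w_scale ~
N(−0.6, 0.1), other weights ~ N(0, 0.05) — a scene-region-like
population whose activity drops with increasing mis-scaling), and
`heterogeneous` (a quarter null, the rest each preferring one random
feature, for exercising top-voxel selection).  What the generator does
*not* emulate: spatially correlated noise, motion, physiological
artifacts, nonlinear response saturation, or voxel populations with
mixed selectivity structure; passing tests therefore validate the
estimators and their calibration, not robustness to those real-data
properties.

## Extraction

Per scan and voxel: OLS linear detrend over the full scan, then
z_n = (d_n − b̄)/s_b with b̄ and s_b computed from that scan's blank TRs.
The first 2 TRs of every post-block blank are excluded as hemodynamic
washout (the leading blank needs none); this pooling rule is a package
decision where the blank-baseline definition is otherwise open.
Event responses are z values at onset TR + peak delay: voxel selection
uses scene onsets with the fixed 7-TR (4.9 s) delay, decoding and
encoding use object onsets with per-voxel estimated delays.  Top-voxel
selection takes the 50 highest mean scene-onset z values (all voxels if
fewer), ties broken toward the lower voxel index.

## Rank-1 FIR GLM

Model: y = Σ_{l,k} h_l β_k x_{l,k} + per-scan (constant + linear)
nuisances, i.e. the L × K FIR coefficient matrix constrained to h βᵀ.
Solver: alternating least squares on the precomputed Gram matrix of the
full FIR design — the β-step solves the normal equations for condition
sticks convolved with the current h, the h-step for β-weighted lag
regressors, both jointly with the nuisances, so per-iteration cost is
independent of the number of timepoints.  h is initialized from a
canonical gamma HRF sampled at TR (peak ≈ 4.9 s); iteration stops when
the relative change of h βᵀ falls below 1e−6 or at 100 iterations
(permutation refits use identical settings so the null is fair).  The
returned h has unit positive peak and β carries the amplitude; the
factorization is only identified up to that scale split, so accuracy is
assessed on the outer product, which noise-free tests recover to 1e−6.
All-zero β (no attributable signal) short-circuits with the initial h.
Scans are concatenated with per-scan nuisance columns for both the
condition-wise and the single-condition (HRF-delay) fits; fitting scans
separately is not implemented.  The per-voxel peak delay is the argmax
tap of the single-condition fit.

## MVPA

Linear SVM (C = 1; the regularization constant is a documented,
configurable default) on training-fold-standardized responses; 5
leave-one-run-out folds × 5 pairings (level 1 vs each mis-scaled level;
20 vs 20 events per scan, so classes are balanced by construction, and
imbalance raises an error).  Decision-boundary ties resolve to the
mis-scaled class.  The permutation null randomizes training labels only,
test labels intact; per-permutation generators derive from the master
seed by counter.  Feature standardization uses training statistics only
(no leakage); whether the original toolbox standardized is unknown, so
it is a flag.

## Encoding model

Per-scan feature levels are mean-centered and scaled by the maximum
absolute deviation (range [−1, 1]); events of all five scans are
concatenated before regression.  Ridge penalty 1.0 applied on the
internally standardized (unit-variance) design, weights returned on the
original feature scale, intercept unpenalized; with 600 events the
default penalty is mild, and λ = 0 reproduces OLS to 1e−8 against an
independent least-squares oracle.  Responsiveness and selectivity nulls
shuffle whole feature rows across events, one shared shuffle for all
voxels per permutation.  Empirical p-values are plain exceedance
proportions without +1 smoothing (p = 0 is possible; the smoothed
alternative is positively biased relative to this convention), two-sided
p doubles the smaller tail, capped at 1.

Selectivity uses ratio |w_target| / Σ_f |w_f| averaged over the top 30%
of voxels ranked by |w_target| (count = ⌈0.3 n⌉; all-zero weight vectors
are excluded from the mean with a warning).  Under exchangeable voxel
tuning the all-voxel mean ratio is 1/4; subsampling after ranking biases
it upward, which is why the null repeats the ranking and subsetting
inside every permutation.  One calibration subtlety: with responses
*independent* of the features (no tuning at all), fitted weights inherit
the design's nuisance-feature correlations — the correlated
retinal-size/FOV columns have inflated estimation variance — so the
all-voxel ratio for scale consistency sits slightly below 1/4 (~0.237 at
this design) rather than at it.  The 1/4 figure is exact only under
feature exchangeability; both regimes are tested.

Validation predicts each scan's event responses from weights fit on the
other four scans, averages predictions over voxels and the events of
each of the 12 design cells (6 levels × 2 mis-scaling directions),
z-normalizes each subject's 12 condition means (the group normalization
is under-determined, so mean-0/sd-1 per subject is the package's
documented choice), and applies one-tailed paired t-tests of normal >
mean mis-scaled per direction with BH-FDR across the tested family.
Zero-variance differences yield a flagged ±∞ statistic rather than an
exception so batch runs survive degenerate inputs.

## Problem sizes and defaults

Simulated studies default to 14 subjects, 5 scans each; analysis-level
demonstrations and tests use regions of 24–48 voxels and permutation
counts of 100–200, sizes at which every calibration property (chance
level 50% ± 1, ratio 0.25 ± 0.01, null p uniformity) is already stable.
All randomness flows from a single integer seed through
`numpy.random.default_rng` with counter-derived sub-streams, so any
result is reproducible from its config.

## Known limitations

* The generator's linearity means the rank-1 GLM is correctly specified
  by construction; model misspecification (HRF variability within
  voxel, nonlinear summation) is not probed.
* Exact raw retinal-size/FOV values of the original stimuli are
  unpublished, so the synthetic design reproduces the structural zero
  correlation and the *pattern* of small scale-consistency correlations,
  not the printed off-diagonal values.
* The separate-designs rank-1 variant (per-condition HRF designs) and
  multi-subject mixed-effects GLMs are out of scope.
* Ratings aggregation: a 0–5 coded scale averaged and rounded yields six
  possible groups; the package keeps the arithmetic rule as stated and
  does not force the result into five groups.
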
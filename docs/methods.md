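# Methods

## Model of the data

The pipeline treats a subject as three objects: a cortical atlas (vertex
coordinates in world mm plus one integer functional-network label per
vertex; 15 usable networks in the canonical setting, with DMN, PMN, CAN and
FPN named through a config map), a hippocampal voxel mask on a volume grid
with an affine, and dense time × unit BOLD matrices for cortex and
hippocampus. All correlations are Pearson r on the full concatenated run,
Fisher-transformed with r clipped to ±(1 − 1e-7) so that degenerate
(noiseless, synthetic) inputs yield large finite z rather than infinities.
Frame censoring, nuisance regression and registration are upstream concerns:
the containers reject NaNs.

Voxel indexing is 0-based and world coordinates always go through the
affine, so 4 mm and 2.6 mm grids need no special-casing. Network identity is
carried by a name→label map rather than positional order, because the same
operations are rerun with different pairs (DMN–PMN, CAN–FPN).

## Parcellation rules

Network reference time courses are unweighted means over each network's
vertices lying strictly more than `exclusion_radius_mm` (default 20, straight
Euclidean distance in world mm — hippocampus-to-cortex geodesics are not
defined on a cortical mesh) from any hippocampal voxel centre. Multi-network
winner-take-all takes the candidate with the greatest *positive* z; voxels
with no positive candidate are left unassigned (a strict reading of the
rule; the alternative of assigning the least-negative network would invent
connectivity that is not there). Ties break to the lowest label with a
warning — they have measure zero on real data but arise in tests. The
runner-up is the best non-winner candidate with positive z at least
`runner_up_fraction` (default 0.66) of the winner's strength.

Forced choice between two networks assigns every voxel to the stronger
member of the pair without a positivity requirement; winners with z ≤ 0 are
flagged "weak" rather than dropped, since a two-alternative design is meant
to produce a complete binary mask even where one network is merely less
uncorrelated than the other.

Parcel proportions are reported both over assigned voxels and over all
voxels (it is not decidable from the published figures which denominator was
used; both are one key apart in the summary).

## Null model

For the parcel-vs-chance question, the forced choice is rerun on every
unordered pair of usable networks other than the observed pair; each
resulting parcel contributes its mean winner-network z to the null. With m
usable labels this yields 2·(C(m,2) − 1) values when no parcel is empty.
The usable set defaults to all atlas networks minus the FPN; a narrower set
(e.g. only DMN/PMN/CAN) is available via `null_pair_labels` since the
published description is ambiguous between the two readings. The test is a
rank-based empirical p with a +1 correction, which never reports p = 0 and
exposes the resolution limit 1/(N+1) of a small null. No attempt is made to
reproduce the (unnamed) test machinery behind the original figure's
significance stars; the empirical rank is the assumption-light analogue.

One genuine subtlety, visible in noiseless synthetic data: null pairs that
*contain* DMN or PMN produce parcels as strongly connected as the observed
ones (at the z clip they tie exactly), so the attainable p is bounded by the
fraction of such pairs. With noise the observed pure parcels strictly beat
the mixed-pair parcels and p reaches the resolution floor.

## Longitudinal axis and variance partition

Axis coordinates come from the first principal axis of each hemisphere's
voxel world coordinates (hemispheres are disjoint clouds and are handled
separately), sign-fixed against a configurable anatomical-anterior direction
(default +y, i.e. RAS) so the anterior end maps to 0. A direct world-axis
projection (`y_axis`) is available. PCA coordinates are invariant to rigid
rotation of the grid when the anterior direction is rotated along.

The gradient-vs-parcel question is posed as three OLS fits of
ΔFC = z(DMN) − z(PMN): on the continuous axis coordinate, on the binary
forced-choice parcel indicator, and on both. "ANOVA with a continuous
regressor" is thus ordinary regression r²; a per-slice binning option
exists because the original coding (continuous mm vs slice bins) is
unstated. The semi-partial r² of a factor is r²(full) − r²(model without
it), with a partial F test on one numerator degree of freedom. When only one
parcel is present the result degrades to gradient-only and is flagged.
Hemispheres are modelled separately and pooled; both results are reported.

## Border ROC

Border voxels are parcel voxels with an other-parcel voxel within
`border_radius_voxels` (default 2) in **Chebyshev** distance on voxel
indices — the box-neighbourhood reading of a "two-voxel radius"; Euclidean
is a config option since the metric was not defined. Similarities are
Pearson correlations of the voxels' cortical Fisher-z profiles, computed
with the exclusion mask applied for consistency with the WTA inputs.
Same-parcel pairs are the positive class, so AUC > 0.5 means within-parcel
coherence. AUC is the trapezoidal area of the stored ROC curve and equals
the Mann–Whitney U statistic normalised by n₊·n₋ with ties counted ½.

Significance permutes **voxel** labels, not pair labels: pair labels are not
exchangeable because pairs share voxels. Pair-level shuffling is implemented
only as a deliberately wrong baseline; in regimes with unbalanced parcels
and heterogeneous per-voxel profile quality it rejects a true null several
times above nominal, while the voxel-level scheme stays calibrated (the
direction of pair-level miscalibration is regime-dependent — with balanced
parcels and i.i.d. profiles it can be near-nominal — so the test suite
demonstrates the anticonservative regime explicitly rather than asserting it
universally). The permutation p uses the +1 correction and is deterministic
given the seed.

## Anatomical segmentation and Dice

The percentage split cuts each hemisphere's axis-length span at
1 − `posterior_fraction` (default 0.20): geometric "posterior 20%", not a
voxel-count quantile (that variant is `by="count"`). A voxel sitting exactly
on the cut is assigned to head/body, with a 1e-9·span tolerance so rigid
rotations cannot flip knife-edge voxels. The landmark split consumes a
coronal slice index identified upstream (fornix-posterior-to-thalamus
criterion); voxels strictly posterior to it form the tail, and the valid
slice range includes both all-head/body and all-tail boundary cases.
Two-class comparisons report per-class Dice, their mean, and whole-labelling
agreement; the tail class is the conventional headline.

## Task GLM

Event responses are modelled with 8 delta-function regressors per condition
(free response shape, no assumed HRF), one sustained block regressor, and an
intercept; the baseline is otherwise unmodelled. Rank deficiency is an
error that names the collinear columns. The deactivation contrast is the
mean of the 3rd and 4th post-onset betas over all conditions (cue conditions
included by default, excludable via `include_cues`), z-scored across
sessions as mean/SE of session-level estimates; single sessions or
zero-variance cases fall back to the raw contrast with a flag. The
across-subject DMN-vs-PMN comparison is a paired two-sided sign-flip
permutation (10,000 flips, seeded) — chosen as the assumption-light analogue
of the original (unnamed) test. No prewhitening: the synthetic noise is
white, and AR modelling of real task noise is out of scope.

## Synthetic cohort

The generator emulates the statistical structure of a densely sampled
subject, not its physiology. K latent network time courses are independent
unit-variance Gaussian AR(1) processes (φ = 0.3 by default) — the simplest
temporally smooth choice, standing in for BOLD autocorrelation. Cortical
vertices are their network's latent plus white noise (sd 1.0); hippocampal
voxels are loading-weighted mixtures of the DMN/PMN latents plus white noise
(sd 2.0 — set so a voxel's winner-network connectivity lands near
z(r) ≈ 0.3–0.5, comfortably above the 0.2 floor expected of real parcels).
Loadings along the axis follow the organisation mode: a one-hot step at
`border_position` (default 0.8 of the axis, matching the ~80/20
anterior/posterior split), a linear DMN-declining/PMN-rising gradient, or a
convex λ-combination of the two (mixed, λ = 0.5) that realises the
"both factors explain separate variance" regime.

Default geometry: two hemisphere boxes of 16 axis layers × 3×3 cross-section
on a 2.6 mm RAS grid (~42 mm axis), 15 networks × 40 vertices, of which 2
per network are deliberately placed inside the 20 mm exclusion radius so the
exclusion rule does real work. Default run length is 8180 frames at
TR 2.2 s (ten 30-minute sessions). Task runs inject the amplitude at
post-onset frames 3–4 only, scaled per unit by its network loading, so the
FIR contrast recovers the injected amplitude exactly in the noiseless limit.

What the generator does **not** emulate: haemodynamic response shapes,
physiological and motion noise, spatial autocorrelation of noise, cortical
mesh geometry, and between-network correlation structure. Passing tests
therefore certify the *rules and statistics* of the pipeline — assignment
logic, calibration of the permutation and empirical tests, exact algebra of
the variance partition — and recovery under a plausible SNR, not performance
on real densely sampled subjects. In particular, with ten 30-minute sessions the
synthetic SNR is high enough that border AUCs saturate near 1; the lower
AUC ranges seen in real subjects reflect sources of variability the
generator deliberately omits.

## Problem sizes and numerical choices

Tests run on reduced problem sizes (150–500 frames, 4–6 networks, 8–16 axis
layers) chosen so the whole suite completes in well under a minute of
compute per module while keeping every statistical check at the sample
sizes its calibration claim needs (≥ 500 subjects for null super-uniformity,
200 datasets for permutation calibration, 20 seeds for recovery CIs). The
acceptance script uses the full default conditions (10 subjects, 8180
frames, 999 permutations, 10,000 sign flips).

Numerical conventions: r clipped at 1 − 1e-7 before atanh; OLS via
statsmodels/lstsq with a normal-equations oracle in tests (agreement to
1e-10); empty borders, empty parcels, all-unassigned voxels, rank-deficient
designs and degenerate voxel clouds raise informative errors rather than
propagating NaNs; every permutation and simulation consumes an explicit
seed, and `run-all` writes a manifest (config, seed, versions, output
hashes) sufficient to reproduce a run bit-exactly.

## Known limitations

- The cortex is a point cloud; no geodesic operations or surface smoothing.
- Per-session connectivity, dynamic FC, partial correlation and
  mixed-effects pooling across subjects are out of scope.
- The landmark slice is consumed, never detected.
- The empirical null's resolution is limited by the number of usable
  networks; with few networks only coarse p-values are attainable.
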
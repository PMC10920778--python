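# Methods

`gliohab` analyses the internal structure of brain tumours ("habitats")
from co-registered diffusion-MRI feature maps, and relates those habitats
to post-surgical cognitive change and to resting-state functional coupling.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic cohort does and does not emulate.

## Feature spaces and normalization

Two per-voxel 2-D feature planes are used.

**p–q plane.** The diffusion tensor with eigenvalues λ1 ≥ λ2 ≥ λ3 is split
into an isotropic magnitude and its deviatoric complement:

    MD = (λ1 + λ2 + λ3) / 3,   p = √3·MD,   q = √Σᵢ(λᵢ − MD)²

This is the Euclidean decomposition of the tensor; it satisfies
p² + q² = Σλᵢ², which the tests verify numerically. Negative eigenvalues
(noise) are clamped to zero before MD with a logged count; the alternative
`negative_policy="error"` refuses them.

**ND–ODI plane.** Neurite density and orientation dispersion maps are
consumed as given (model fitting is out of scope).

Each raw feature is divided by its arithmetic mean over the *contralateral
region* — the tumour mask reflected across the mid-plane of the first
voxel axis — so a value of 1 means "like unaffected tissue". Reflection is
a stand-in for whatever registration- or drawing-based construction a
study might use; tumours overlapping their own mirror image by more than
5% (midline tumours) are refused and an explicit contralateral mask must
be supplied. Each feature is normalized by its own contralateral mean
(p by mean p, q by mean q, and likewise ND/ODI).

## Quadrant segmentation

The normalized p–q cloud of in-tumour voxels is split into four groups
around the (1, 1) point: I (p≤1, q≤1), II (p≤1, q>1), III (p>1, q>1),
IV (p>1, q<1... strictly: q≤1). Boundary values exactly at 1 go to the
"decreased" side — strict inequalities would leave measure-zero gaps that
finite-precision data can hit, and any fixed deterministic rule serves.
Labels are back-projected to the grid; occupancy is each group's share of
tumour voxels and always sums to 100%.

## Mixture segmentation and cross-subject matching

Per subject, the normalized ND–ODI cloud is first cleaned of outliers
(points outside median ± 3·normal-scaled MAD on either feature are
dropped; this removes ~0.5% of a clean Gaussian sample). Removal that
leaves fewer than 30 points, or strips more than half the sample, is
treated as pathological and refused.

A Gaussian mixture with **one shared full covariance** across components
is then fitted by EM: k-means++ seeding, 5 random replicates keeping the
best final log-likelihood, convergence when the relative log-likelihood
change falls below 1e-6 or after 500 iterations, covariance regularized by
1e-6·I. The log-likelihood trajectory is asserted non-decreasing on every
fit. The implementation is local (the shared-covariance M-step reduces to
X′X minus component-mean outer products); scikit-learn's tied-covariance
mixture serves as an independent cross-check in the tests, not as the
implementation.

The component count k ∈ 1…7 maximizes the mean silhouette of the hard
labelling (Euclidean distance; silhouette subsampled to 2000 points,
seeded, on larger samples). Silhouette is undefined at k = 1, so one
component is chosen only when no k ≥ 2 reaches a silhouette of 0.5
(configurable floor).

Because subjects need not share components, per-subject components are
merged into canonical cohort classes by greedy agglomeration on centroid
distance with threshold τ = 0.3 (normalized units): at each step the
globally closest admissible pair among (component, component),
(component, class) and (class, class with disjoint subject sets) merges,
class centroids are recomputed as member means, and no class may hold two
components of one subject. Class–class fusion is needed because pure
pairwise seeding can fragment one true cluster into several classes when
two pair-merges happen before a join. Ties break by subject/component
order, so the result does not depend on input ordering. Components never
merged are excluded and their voxels carry no label. Classes are named C1,
C2, … by descending number of member subjects.

## Cognition battery

Cognitive change per domain is Δ = pre − post z-score (positive =
decline); the overall score is the mean over available domains, and
participants with no post-operative scores are excluded from cognition
analyses only.

For the quadrant scheme, overall decline is regressed (OLS) on each
group's % occupancy with tumour volume as covariate; the four model
p-values form one Benjamini–Hochberg family. Groups surviving FDR trigger
per-domain follow-up regressions (their own 5-test family). For the
data-driven classes, decline is compared between subjects with and
without each class by a two-sided Mann–Whitney test (tie-corrected normal
approximation, effect size η² = z²/N), one FDR family across classes.
IDH-mutation association uses Mann–Whitney on occupancy and a 1-df
Pearson χ² without continuity correction on presence. A Pearson screen
correlates demographic/clinical characteristics (tumour grade encoded
ordinally 1–4) with overall decline. Every regression report asserts the
exact identity F = (R²/df1)/((1−R²)/df2).

## BOLD coupling

The global signal (GS) is the frame-wise mean BOLD over grey matter
excluding the tumour; for the contralateral region the mirror region is
excluded too, so the response never overlaps the regressor. All series
pass a zero-phase band-pass (0.03–0.12 Hz at TR = 1.06 s): an order-4
Butterworth run forward–backward over a mirror-extended copy of the
series, which cancels phase and tames the filter's edge transients.
Frames with framewise displacement above 0.5 mm (configurable) are
scrubbed; losing more than half the frames flags the subject.

Coupling β of a region with the GS is the OLS slope with both series
standardized to unit variance, making β symmetric in the two series,
equal to the Pearson correlation, and comparable across regions; a
raw-units mode is available (and is the unbiased estimator of a planted
slope under additive noise). Because band-limited series are strongly
autocorrelated, the slope t-test uses Bartlett's effective sample size
N_eff = N / (1 + 2·Σ ρₓ(k)ρ_y(k)); without it the naive test rejects a
true null ~4× too often at these settings. Within one segmentation
scheme, all (subject × region) estimates form a single FDR family and
slopes with adjusted p > 0.05 are set to 0, keeping the raw value in
provenance. Habitats are compared across subjects with a Friedman test
and pairwise Wilcoxon signed-rank post-hocs (FDR-corrected); rows with a
missing habitat are refused by name rather than silently dropped.

## Spatial similarity

Mask agreement uses the Sørensen–Dice coefficient 2|A∩B|/(|A|+|B|) and
the directional percent occupancy 100·|A∩B|/|denominator|. Both
directions are always reported — the single-direction convention differs
between studies — and when overlap is positive the three quantities obey
dice = 2/(100/occ_A + 100/occ_B), asserted internally.

## Synthetic cohort

The generator emulates exactly the statistical structure the pipeline
assumes, with study-scale defaults: 16 subjects, 64³ grids at 2 mm,
lateralized connected tumour blobs of 800–3000 voxels (perturbed
ellipsoids reduced to their largest connected component), and a
probabilistic tumour mask whose 0.5-binarization defines the ground-truth
support. Three of sixteen subjects lack post-operative scores.

In-tumour p–q points are drawn inside quadrants with cohort-level
occupancy weights (I, II, III, IV) = (0.112, 0.043, 0.279, 0.566) — the
ordering IV > III > I > II a glioma cohort typically shows. Per-subject
weights are Dirichlet draws around these (concentration 14, giving a
group-III occupancy SD of ≈11% across subjects): between-subject
occupancy variability is what makes the occupancy regression estimable,
and real cohorts show spreads of this order. ND–ODI points come
from Gaussian classes at centroids (0.34, 0.63), (0.41, 1.11),
(0.56, 0.79), (0.16, 0.46), (0.12, 0.28) with presence probabilities
0.875, 0.75, 0.3125, 0.3125, 0.125 — realistic normalized values for
glioma tissue. The within-cluster covariance defaults to 0.0025·I:
cluster *spread within one tumour* must be small enough for silhouette to
resolve the 0.25-unit gap between the two closest classes, while
*between-subject* centroid wobble is a separate knob (sd 0.03, safely
inside the τ = 0.3 matching radius). Healthy tissue is N(1, 0.05) per
feature and the mirror-region sample mean is recentred to exactly 1, so
normalization is exact and planted quadrant occupancies are recovered
exactly.

BOLD: the GS is unit-variance band-limited noise; each habitat's voxels
follow β·GS plus a shared band-limited regional noise (sd 0.3) plus voxel
white noise (sd 0.1). The regional term is what keeps region-mean series
noisy after voxel averaging — without it any non-zero β would standardize
to ≈1. Planted β: 0.2 (groups I, II), 0.6 (III, IV), 0.9 contralateral,
1.0 healthy grey matter. Cognition: Δ per domain is effect×(% occupancy
of group III) plus N(0, 0.45) noise, with the verbal-skills effect 0.037
and the others chosen so the mean effect is exactly 0.022; pre-scores are
standard normal and post = pre − Δ. The per-domain noise level puts the
overall-decline model in the moderate variance-explained regime
(R² ≈ 0.5–0.7 at 13 complete cases) rather than making the effect
trivially detectable.

What the generator does **not** emulate: MR physics, partial-volume and
susceptibility effects, registration error, spatially correlated feature
noise, physiological (cardiac/respiratory) BOLD structure, and
non-Gaussian cognitive score distributions. Passing recovery tests
therefore demonstrates the correctness of the estimators under the
assumed generative model, not robustness to real-data artefacts.

## Problem sizes and determinism

Every random stage takes one integer seed; subject streams are spawned
from a single SeedSequence, so a (spec, seed) pair reproduces a cohort
byte-for-byte. The test suite runs reduced sizes (8 subjects, 32³ grids,
120 frames; 20-seed/200–500-replicate simulations for the statistical
criteria); `scripts/acceptance.py` runs the full 16-subject, 64³,
300-frame configuration end to end.

## Known limitations

- The contralateral region is a pure voxel-space reflection; it is only
  meaningful for co-registered, roughly symmetric grids.
- The greedy matcher is one deterministic realization of iterative
  minimum-distance matching; other orderings of the same family can
  differ on data with centroid gaps near τ.
- Friedman comparison requires every habitat present in every subject;
  cohorts with missing habitats must be handled explicitly upstream.
- Mann–Whitney uses the asymptotic approximation; at very small group
  sizes an exact test would be preferable.
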
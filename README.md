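# gliohab

Intra-tumour **habitat** analysis for brain tumours: segment tumour voxels
into microstructural subregions from diffusion-MRI feature spaces, then ask
what those subregions mean — for a patient's cognitive outcome after
surgery, and for how the tumour couples to the brain's resting-state
activity.

## Who this is for

Neuro-oncology imaging groups with co-registered, per-subject NIfTI inputs:
DTI eigenvalue (or precomputed p/q) maps, NODDI neurite-density (ND) and
orientation-dispersion (ODI) maps, a probabilistic tumour mask, a
grey-matter mask, a 4-D BOLD series, and a cohort table of cognitive
z-scores with covariates. A fully specified synthetic-cohort generator with
known ground truth makes every stage testable without patient data.

## What it computes

**Quadrant habitats (p–q).** From tensor eigenvalues λ1 ≥ λ2 ≥ λ3,

    MD = (λ1+λ2+λ3)/3,  p = √3·MD,  q = √((λ1−MD)² + (λ2−MD)² + (λ3−MD)²)

(the Euclidean isotropic/deviatoric decomposition, p² + q² = Σλᵢ²). After
dividing each map by its mean over the mirrored (contralateral) tumour
region, every in-tumour voxel is a point in the p–q plane and falls in one
of four quadrants around (1, 1): I (p≤1, q≤1), II (p≤1, q>1),
III (p>1, q>1), IV (p>1, q≤1). Labels project back to the grid as four
subregion masks with % occupancy.

**Data-driven habitats (ND–ODI).** Per subject, outliers are removed
(median ± 3·scaled-MAD per feature) and a Gaussian mixture with one shared
full covariance is fitted by EM (5 replicates, k ∈ 1…7 chosen by the mean
silhouette). Components are then matched across subjects by greedy
centroid agglomeration with a Euclidean threshold of 0.3, yielding
canonical classes C1, C2, … ordered by prevalence; unmatched components
are excluded.

**Cognition.** Decline Δ = pre − post z-score per domain (positive =
decline). Overall decline is regressed on each quadrant's occupancy with
tumour volume as covariate (R², F(2, n−3), slope B; BH-FDR over the four
models; per-domain follow-ups for surviving models); class presence is
tested by Mann–Whitney (η² = z²/N); IDH mutation by Mann–Whitney and
Pearson χ²; plus a Pearson covariate screen.

**BOLD coupling.** The global signal (GS) is the mean BOLD over healthy
grey matter (tumour excluded; mirror region also excluded for the
contralateral analysis). After 0.03–0.12 Hz zero-phase band-passing and
motion scrubbing, each habitat's coupling β is the standardized regression
slope of its mean signal on the GS, with autocorrelation-corrected
p-values; non-significant β (FDR) are set to 0; habitats are compared by
Friedman + Wilcoxon post-hocs.

**Spatial similarity.** Sørensen–Dice 2|A∩B|/(|A|+|B|) and directional
percent occupancy between the two segmentations, both directions reported.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from gliohab import SyntheticCohortSpec, generate_cohort
from gliohab.pipeline import run_pipeline

spec = SyntheticCohortSpec(n_subjects=8, grid_shape=(32, 32, 32),
                           tumour_size_range=(250, 700), bold_length=120,
                           n_missing_post=2)
cohort = generate_cohort(spec, seed=7)
res = run_pipeline(cohort, seed=0)

print(res["pq_occupancy"].mean().round(1))
print("Friedman chi2 =", round(res["coupling"]["comparison"].chi2, 2))
rep = res["cognition"]["occupancy_regressions"]["III"]
print(f"group III: B = {rep.slope:.4f}, R2 = {rep.r_squared:.3f}, "
      f"p-FDR = {rep.p_fdr:.3f}")
```

prints (seeds as above):

```
occ_I      11.3
occ_II      2.7
occ_III    30.9
occ_IV     55.1
dtype: float64
Friedman chi2 = 27.7
group III: B = 0.0398, R2 = 0.523, p-FDR = 0.868
```

Cohort-mean occupancy is largest for group IV and smallest for group II
(the planted ordering); the Friedman statistic rejects equal coupling
across the four habitats and the contralateral region; and the group-III
occupancy slope is of the planted order (~0.02–0.04 decline-z per
% occupancy) but, with only 6 complete cases in this toy cohort, the
model is far from significant — run the study-scale configuration below
for stable estimates.

The same stages are available from the shell:

```bash
gliohab simulate --config cohort.yaml --seed 1 --out data/
gliohab report --config analysis.yaml --seed 1 --out results/
```

where `cohort.yaml` holds generator overrides under `spec:` and
`analysis.yaml` points at the data directory (`data_dir: data/`).

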
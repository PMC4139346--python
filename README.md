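# lbpbrain

Gray-level-invariant texture classification of linearly registered
structural brain MRI, with a synthetic multi-scanner phantom generator for
end-to-end validation.

## The problem and the method

In multicentre MRI studies, raw voxel intensities are not comparable across
scanners: every scanner/protocol applies its own (approximately strictly
increasing) transform to tissue gray levels — different units, different
contrast. This package implements a classification pipeline that is exactly
invariant to such transforms:

1. **Features.** For each registered volume, local binary pattern maps are
   computed slicewise on the three orthogonal planes (LBP-TOP). The LBP code
   of a pixel packs the signs of its 8 in-plane neighbour differences into
   one byte, `code = Σ_p s(I_p − I_c)·2^p` with `s(x) = 1 iff x ≥ 0`. Codes
   depend only on intensity *orderings*, so any strictly increasing
   gray-level transform leaves them bit-identical. The three code maps are
   Gaussian-smoothed (default FWHM 4 mm) to form feature images. Two
   reference feature types are provided for comparison: raw intensities
   (type 1) and histogram matching to a template (type 2); the LBP-TOP
   features are type 3.
2. **Two-step selection.** A voxelwise two-sample t-test (p < 0.001,
   uncorrected) on training subjects only, intersected with a binary
   anatomical mask (amygdala, entorhinal area, hippocampus, parahippocampal
   gyrus, temporal lobe, lateral ventricles, or their union).
3. **Classification.** A linear soft-margin SVM on the selected voxels,
   evaluated with stratified 10-fold cross-validation repeated 30 times.
   Selection and z-scoring are refit inside every training fold, so test
   subjects never leak into the model. Classifiers are compared with
   McNemar's test (z = |b−c|/√(b+c), significant at z > 1.960), and linear
   SVM weights are back-projected into template space as weight maps.

A phantom generator (`lbpbrain.phantom`) builds reproducible synthetic
cohorts — nested-ellipsoid "brains" with patient-specific atrophy, per-
subject anatomy, residual registration jitter, per-scanner gamma/gain
transforms and noise — so the whole pipeline can be validated without any
patient data. See `docs/methods.md` for the model and its limitations.

## Worked example

```python
from lbpbrain import (CVConfig, PhantomCohortSpec, SelectionCriteria,
                      SmoothingSpec, compute_metrics, make_cohort, run_cv)
from lbpbrain.experiment import load_cohort_features

cohort = make_cohort(PhantomCohortSpec(n_per_group=20, seed=0), "scratch/demo")
feats = load_cohort_features(cohort.manifest_path, feature_type=3,
                             template=cohort.template_path,
                             smoothing=SmoothingSpec())
result = run_cv(feats.X, feats.labels, feats.validity,
                SelectionCriteria(alpha=0.001, mask=cohort.masks["OVALL"]),
                CVConfig(n_folds=10, n_repeats=3, seed=707),
                subject_ids=feats.subject_ids)
print(compute_metrics(result).mean_auc)
```

On this 40-subject cohort (seed 0) the three feature types give, with the
union mask and 10-fold CV:

| feature type | mean AUC | mean accuracy |
|---|---|---|
| 1 — raw intensity | 0.454 | 0.475 |
| 2 — histogram-matched | 0.999 | 0.983 |
| 3 — smoothed LBP-TOP | 0.981 | 0.925 |

Raw intensities are at chance — the per-scanner gain/gamma transforms make
them incomparable across scanners — while both adjusted feature types
recover the disease signal. On this synthetic scanner model (a *global*
strictly increasing transform per subject) histogram matching is a
near-perfect normalizer and slightly exceeds the texture features; see
`docs/methods.md` for why real multicentre data (spatially varying bias,
non-monotone protocol differences) behaves differently.

The same pipeline is scriptable via the CLI:

```bash
lbpbrain phantom generate --out scratch/demo --seed 0 --n-per-group 20
lbpbrain classify run --manifest scratch/demo/manifest.tsv \
    --type 3 --mask scratch/demo/masks/OVALL.nii.gz \
    --repeats 3 --seed 707 --out scratch/demo/results
```

## Layout

- `src/lbpbrain/` — the library: `volumes_io`, `phantom`, `features`,
  `selection`, `classify`, `experiment`, `cli`.
- `examples/` — short narrative scripts (invariance demo, selection demo,
  full experiment).
- `docs/methods.md` — the statistical model, parameter reference, and
  limitations.
- `tests/` — unit, property, and acceptance tests.
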
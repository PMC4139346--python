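"""Full experiment: three feature types on a multi-scanner cohort.

Generates a 40-subject phantom cohort and runs the complete pipeline
(features -> per-fold selection -> repeated CV -> reports) for raw
intensity (type 1), histogram-matched intensity (type 2), and smoothed
LBP-TOP texture (type 3) features, all restricted to the anatomical union
mask. Writes metrics, predictions, ROC points, McNemar comparisons, and
type-3 weight maps under scratch/experiment_demo/.

Run:  python examples/03_full_experiment.py     (about a minute)
"""

from pathlib import Path

import pandas as pd

from lbpbrain import ExperimentConfig, PhantomCohortSpec, make_cohort, run_experiment

out = Path("scratch/experiment_demo")
cohort = make_cohort(PhantomCohortSpec(n_per_group=20, seed=0), out / "cohort")

config = ExperimentConfig(
    manifest=cohort.manifest_path,
    template=cohort.template_path,
    out_dir=out / "results",
    mask_paths={"OVALL": cohort.mask_paths["OVALL"]},
    feature_types=(1, 2, 3),
    mask_names=("OVALL",),
    n_folds=10,
    n_repeats=3,
    seed=707,
)
results = run_experiment(config)

summary = pd.read_csv(results / "summary.tsv", sep="\t")
print(summary.to_string(index=False))

mc = pd.read_csv(results / "mcnemar.tsv", sep="\t")
print("\nMcNemar comparisons (repeat 0):")
print(mc.to_string(index=False))

print("\nRaw intensities (type 1) sit at chance because each scanner "
      "applies its own gamma/gain transform; both adjusted feature types "
      "recover the atrophy signal. Weight maps for the texture features "
      f"are under {results}/weights_type3_OVALL_*.nii.gz.")
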
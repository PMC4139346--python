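"""End-to-end experiment: features -> per-fold selection -> CV -> reports.

Wires the pipeline together for a cohort on disk: load the manifest, build
the requested feature images, run repeated cross-validation with the
two-step selection for every (feature type, mask) combination, and write
metrics, predictions, ROC points, weight maps, and McNemar comparisons.

One global seed fans out to per-combination CV seeds through a
``numpy.random.SeedSequence`` spawned in a fixed order, so every stage is
individually reproducible from the experiment config alone.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import (CVConfig, CVResult, compute_metrics, correctness_by_subject,
                       mcnemar, weight_map)
from .features import SmoothingSpec, feature_image
from .selection import SelectionCriteria
from .volumes_io import (BinaryMask, Volume, ensure_same_grid, read_manifest,
                         read_mask, read_volume, write_volume)

__all__ = [
    "ExperimentConfig",
    "CohortFeatures",
    "load_cohort_features",
    "run_typed_cv",
    "run_experiment",
]

log = logging.getLogger("lbpbrain")


@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run bit-exactly."""

    manifest: Path
    template: Path
    out_dir: Path
    mask_paths: dict[str, Path] = dataclasses.field(default_factory=dict)
    feature_types: tuple[int, ...] = (3,)
    mask_names: tuple[str, ...] = ("none",)
    fwhm_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    alpha: float = 0.001
    n_folds: int = 10
    n_repeats: int = 30
    svm_c: float = 1.0
    standardize: bool = True
    seed: int = 0

    def to_flat(self) -> dict[str, str]:
        d = dataclasses.asdict(self)
        d["mask_paths"] = ";".join(f"{k}={v}" for k, v in self.mask_paths.items())
        return {k: str(v) for k, v in d.items()}


@dataclasses.dataclass
class CohortFeatures:
    """Feature images of a whole cohort, stacked for cross-validation.

    ``X`` has shape (n_subjects, n_planes, *grid) in float32; ``validity``
    is the intersection of every subject's validity grid.
    """

    X: np.ndarray
    validity: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    spacing: tuple[float, float, float]
    feature_type: int


def _with_mask(volume: Volume) -> Volume:
    if volume.brain_mask is None:
        volume.brain_mask = volume.data != 0
    return volume


def load_cohort_features(manifest: Union[pd.DataFrame, str, Path],
                         feature_type: int,
                         template: Optional[Union[Volume, str, Path]] = None,
                         smoothing: Optional[SmoothingSpec] = None,
                         volumes: Optional[Sequence[Volume]] = None) -> CohortFeatures:
    """Build the stacked feature array of a cohort for one feature type.

    ``manifest`` may be a TSV path or DataFrame; ``volumes`` may pre-supply
    loaded volumes (in manifest row order) to skip disk reads. Brain masks
    default to the non-zero support of each volume.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    if template is not None and not isinstance(template, Volume):
        template = _with_mask(read_volume(template))
    elif isinstance(template, Volume):
        template = _with_mask(template)

    planes_list = []
    validity = None
    spacing = None
    for i, row in enumerate(manifest.itertuples()):
        vol = volumes[i] if volumes is not None else read_volume(row.path)
        vol = _with_mask(vol)
        if spacing is None:
            spacing = vol.spacing
        fi = feature_image(vol, feature_type, template=template, smoothing=smoothing)
        planes = np.stack([np.asarray(p, dtype=np.float32) for p in fi.planes])
        planes_list.append(planes)
        validity = fi.validity if validity is None else (validity & fi.validity)

    X = np.stack(planes_list)
    ensure_same_grid([validity, *[p for p in X[0]]])
    return CohortFeatures(X=X, validity=validity,
                          labels=manifest["label"].to_numpy(),
                          subject_ids=manifest["subject_id"].tolist(),
                          spacing=spacing, feature_type=feature_type)


def run_typed_cv(feats: CohortFeatures, criteria: SelectionCriteria,
                 cfg: CVConfig) -> CVResult:
    """Run repeated CV on stacked cohort features."""
    from .classify import run_cv

    return run_cv(feats.X, feats.labels, feats.validity, criteria, cfg,
                  subject_ids=feats.subject_ids)


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)]


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the full pipeline and write a result directory.

    Outputs per (type, mask): metrics.tsv (per repeat + mean), roc.tsv,
    predictions.tsv; weight-map NIfTIs for the first listed combination of
    each type-3 run; mcnemar.tsv comparing every combination against the
    first one on the designated repeat 0; outputs.tsv listing every file;
    experiment.log with per-stage seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "experiment.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_experiment(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_experiment(config: ExperimentConfig, out: Path) -> Path:
    manifest = read_manifest(config.manifest)
    smoothing = SmoothingSpec(fwhm_mm=config.fwhm_mm)
    masks: dict[str, Optional[BinaryMask]] = {"none": None}
    for name, p in config.mask_paths.items():
        masks[name] = read_mask(p, name)

    combos = [(t, m) for t in config.feature_types for m in config.mask_names]
    seeds = _derived_seeds(config.seed, len(combos))
    log.info("experiment seed=%d combos=%s derived seeds=%s",
             config.seed, combos, seeds)

    outputs: list[dict] = []
    correctness: dict[str, np.ndarray] = {}
    summary_rows = []
    feats_cache: dict[int, CohortFeatures] = {}
    for (ftype, mask_name), cv_seed in zip(combos, seeds):
        tag = f"type{ftype}_{mask_name}"
        log.info("running %s with cv seed %d", tag, cv_seed)
        if ftype not in feats_cache:
            feats_cache[ftype] = load_cohort_features(
                manifest, ftype, template=config.template, smoothing=smoothing)
        feats = feats_cache[ftype]
        if mask_name != "none" and mask_name not in masks:
            raise KeyError(f"mask '{mask_name}' not in config.mask_paths")
        criteria = SelectionCriteria(alpha=config.alpha, mask=masks.get(mask_name))
        cfg = CVConfig(n_folds=config.n_folds, n_repeats=config.n_repeats,
                       seed=cv_seed, svm_c=config.svm_c,
                       standardize=config.standardize)
        result = run_typed_cv(feats, criteria, cfg)
        metrics = compute_metrics(result)

        mpath = out / f"metrics_{tag}.tsv"
        df = metrics.per_repeat.copy()
        mean_row = {"repeat": "mean", "accuracy": metrics.mean_accuracy,
                    "sensitivity": metrics.mean_sensitivity,
                    "specificity": metrics.mean_specificity,
                    "auc": metrics.mean_auc}
        pd.concat([df, pd.DataFrame([mean_row])]).to_csv(mpath, sep="\t", index=False)
        outputs.append({"stage": tag, "kind": "metrics", "path": str(mpath)})

        fpr, tpr = metrics.roc_curves[0]
        rpath = out / f"roc_{tag}.tsv"
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(rpath, sep="\t", index=False)
        outputs.append({"stage": tag, "kind": "roc", "path": str(rpath)})

        pred_rows = []
        for f in result.folds:
            for idx, yp, sc in zip(f.test_idx, f.y_pred, f.scores):
                pred_rows.append({"repeat": f.repeat, "fold": f.fold,
                                  "subject_id": result.subject_ids[idx],
                                  "label": int(result.labels[idx]),
                                  "predicted": int(yp), "score": float(sc)})
        ppath = out / f"predictions_{tag}.tsv"
        pd.DataFrame(pred_rows).to_csv(ppath, sep="\t", index=False)
        outputs.append({"stage": tag, "kind": "predictions", "path": str(ppath)})

        if ftype == 3:
            wm = weight_map(result, repeat=0)
            for plane_name, plane in zip(("yz", "xz", "xy"), wm.planes):
                wpath = out / f"weights_{tag}_{plane_name}.nii.gz"
                write_volume(Volume(plane, feats.spacing), wpath)
                outputs.append({"stage": tag, "kind": "weight_map", "path": str(wpath)})

        correctness[tag] = correctness_by_subject(result, repeat=0)
        summary_rows.append({"feature_type": ftype, "mask": mask_name,
                             "mean_accuracy": metrics.mean_accuracy,
                             "mean_sensitivity": metrics.mean_sensitivity,
                             "mean_specificity": metrics.mean_specificity,
                             "mean_auc": metrics.mean_auc,
                             "pooled_accuracy": metrics.pooled_accuracy,
                             "pooled_auc": metrics.pooled_auc})

    spath = out / "summary.tsv"
    pd.DataFrame(summary_rows).to_csv(spath, sep="\t", index=False)
    outputs.append({"stage": "all", "kind": "summary", "path": str(spath)})

    tags = list(correctness)
    mc_rows = []
    for a in tags:
        for b in tags:
            if a == b:
                continue
            r = mcnemar(correctness[a], correctness[b])
            mc_rows.append({"a": a, "b": b, "b_count": r.b, "c_count": r.c,
                            "z": r.z, "p": r.p})
    if mc_rows:
        cpath = out / "mcnemar.tsv"
        pd.DataFrame(mc_rows).to_csv(cpath, sep="\t", index=False)
        outputs.append({"stage": "all", "kind": "mcnemar", "path": str(cpath)})

    pd.DataFrame(outputs).to_csv(out / "outputs.tsv", sep="\t", index=False)
    (out / "config.txt").write_text(
        "".join(f"{k}={v}\n" for k, v in config.to_flat().items()))
    return out
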
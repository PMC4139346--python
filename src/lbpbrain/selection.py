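"""Two-step feature selection: voxelwise t-test, then anatomical masking.

Step 1 (data-driven): a pooled-variance two-sample Student's t-test per
voxel and per plane, computed over the *training* subjects only, retains
voxels with a two-sided p below ``alpha`` (default 0.001, uncorrected).
Step 2 (knowledge-driven): the surviving voxels are intersected with a
binary anatomical mask when one is given. The selected (plane, voxel)
coordinates are concatenated plane-major, then row-major (C order) into a
deterministic flat index used to build subject feature vectors and to
back-project SVM weights.

Voxels with zero pooled variance (e.g. exactly-constant background) have an
undefined p-value and are never selected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .volumes_io import BinaryMask, GridMismatchError

__all__ = [
    "SelectionCriteria",
    "SelectionModel",
    "fit_selection",
    "apply_selection",
    "save_selection_model",
    "load_selection_model",
]


@dataclasses.dataclass(frozen=True)
class SelectionCriteria:
    """First-step p-value threshold and optional second-step mask."""

    alpha: float = 0.001
    mask: Optional[BinaryMask] = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


@dataclasses.dataclass
class SelectionModel:
    """A fitted voxel-selection model.

    ``select`` has shape (n_planes, *grid); ``flat_index`` indexes the
    C-order flattening of that array (plane-major, voxel row-major).
    ``tstat``/``pval`` keep the full statistic grids (NaN where undefined)
    unless the model has been slimmed for storage.
    """

    select: np.ndarray
    flat_index: np.ndarray
    shape: tuple[int, int, int]
    n_planes: int
    criteria: SelectionCriteria
    tstat: Optional[np.ndarray] = None
    pval: Optional[np.ndarray] = None

    @property
    def n_selected(self) -> int:
        return int(self.flat_index.size)

    def slim(self) -> "SelectionModel":
        """Copy without the statistic grids (keeps only the flat index)."""
        return SelectionModel(select=None, flat_index=self.flat_index,
                              shape=self.shape, n_planes=self.n_planes,
                              criteria=self.criteria)


def _as_feature_array(images, n_planes: Optional[int] = None) -> np.ndarray:
    """Coerce per-subject plane images to shape (n_subjects, n_planes, *grid)."""
    if isinstance(images, np.ndarray) and images.ndim == 5:
        return images
    arrs = []
    for img in images:
        planes = img.planes if hasattr(img, "planes") else img
        arrs.append(np.stack([np.asarray(p) for p in planes]))
    out = np.stack(arrs)
    if n_planes is not None and out.shape[1] != n_planes:
        raise ValueError(f"expected {n_planes} planes, got {out.shape[1]}")
    return out


def fit_selection(train_images, labels: Sequence[int], validity: np.ndarray,
                  criteria: Optional[SelectionCriteria] = None) -> SelectionModel:
    """Fit the two-step selection on training subjects only.

    ``train_images`` is anything coercible to (n_subjects, n_planes, *grid):
    an ndarray, a list of FeatureImage, or a list of per-plane array lists.
    ``labels`` are +1/-1 with at least two subjects per class. The selection
    grid is ``(p < alpha) & validity & mask``; its flat C-order index is the
    feature ordering used by :func:`apply_selection`.
    """
    if criteria is None:
        criteria = SelectionCriteria()
    X = _as_feature_array(train_images)
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise ValueError(f"{X.shape[0]} images but {labels.size} labels")
    pos = labels == 1
    neg = labels == -1
    n1, n2 = int(pos.sum()), int(neg.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 training subjects per class, got {n1} and {n2}")
    validity = np.asarray(validity, dtype=bool)
    if validity.shape != X.shape[2:]:
        raise GridMismatchError(
            f"validity shape {validity.shape} != image grid {X.shape[2:]}")

    m1 = X[pos].mean(axis=0, dtype=np.float64)
    m2 = X[neg].mean(axis=0, dtype=np.float64)
    v1 = X[pos].var(axis=0, ddof=1, dtype=np.float64)
    v2 = X[neg].var(axis=0, ddof=1, dtype=np.float64)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    degenerate = ~(se > 0)
    t[degenerate] = np.nan
    p = np.full(t.shape, np.nan)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)

    select = np.zeros(t.shape, dtype=bool)
    select[ok] = p[ok] < criteria.alpha
    select &= validity[None]
    if criteria.mask is not None:
        mdata = np.asarray(criteria.mask.data, dtype=bool)
        if mdata.shape != validity.shape:
            raise GridMismatchError(
                f"mask '{criteria.mask.name}' shape {mdata.shape} != grid {validity.shape}")
        select &= mdata[None]

    return SelectionModel(select=select,
                          flat_index=np.flatnonzero(select),
                          shape=tuple(X.shape[2:]),
                          n_planes=X.shape[1],
                          criteria=criteria,
                          tstat=t, pval=p)


def apply_selection(model: SelectionModel, subject_images) -> np.ndarray:
    """Read one subject's values at the model's selected coordinates.

    Returns a vector of length ``model.n_selected`` in the model's
    deterministic plane-major, row-major order.
    """
    planes = subject_images.planes if hasattr(subject_images, "planes") else subject_images
    stacked = np.stack([np.asarray(p, dtype=np.float64) for p in planes])
    if stacked.shape != (model.n_planes, *model.shape):
        raise GridMismatchError(
            f"subject grid {stacked.shape} != model grid {(model.n_planes, *model.shape)}")
    return stacked.reshape(-1)[model.flat_index]


def save_selection_model(model: SelectionModel, out_dir: Union[str, Path],
                         spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> Path:
    """Serialize as one NIfTI selection grid per plane + a JSON sidecar."""
    from .volumes_io import Volume, write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    select = model.select
    if select is None:
        select = np.zeros((model.n_planes, *model.shape), dtype=bool)
        select.reshape(-1)[model.flat_index] = True
    for i in range(model.n_planes):
        write_volume(Volume(select[i].astype(np.uint8), spacing),
                     out_dir / f"select_plane{i}.nii.gz")
    meta = {
        "alpha": model.criteria.alpha,
        "mask": model.criteria.mask.name if model.criteria.mask is not None else None,
        "n_planes": model.n_planes,
        "shape": list(model.shape),
        "ordering": "plane-major, voxel C-order (row-major)",
    }
    sidecar = out_dir / "selection.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_selection_model(out_dir: Union[str, Path]) -> SelectionModel:
    from .volumes_io import read_volume

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "selection.json").read_text())
    planes = [read_volume(out_dir / f"select_plane{i}.nii.gz").data.astype(bool)
              for i in range(meta["n_planes"])]
    select = np.stack(planes)
    return SelectionModel(select=select, flat_index=np.flatnonzero(select),
                          shape=tuple(meta["shape"]), n_planes=meta["n_planes"],
                          criteria=SelectionCriteria(alpha=meta["alpha"]))
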
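"""Synthetic brain-phantom cohorts with the statistical structure the
classification method assumes.

Each subject is a nested-ellipsoid "brain": an outer CSF shell, a gray-matter
shell, a white-matter core, two bilateral medial-temporal "target" blobs
(stand-ins for hippocampus and amygdala), and one central CSF-filled
"ventricle". Patients (+1) receive a linear shrink of the target blobs and a
linear dilation of the ventricle, so disease shows up as boundary shifts —
the kind of rigid-registration residual signal the texture features are
meant to capture. Per subject the pipeline then applies, in order:

0. per-structure anatomical variability: the shell and blob radii are
   perturbed by a few percent independently per subject (group-independent),
   so tissue proportions — and hence intensity histograms — differ across
   subjects the way they do in a real registered cohort, while the outer
   head size stays fixed (affine registration normalizes global size),
1. an integer-voxel rigid translation (residual linear-registration jitter),
2. a gamma transform of the intensities (a strictly increasing gray-level
   change emulating scanner/protocol contrast differences such as
   flip-angle variation),
3. additive Gaussian noise inside the head,
4. a multiplicative gain (the arbitrary intensity units of each scanner;
   applied after the noise so the signal-to-noise ratio is gain-invariant).

Steps 2 and 4 together form a strictly increasing per-subject gray-level
transform: gamma changes the tissue contrast, gain the output units. The
gain spread is wide enough that raw intensity values of different tissues
overlap *across* scanners even though their ordering is preserved *within*
every scanner — the regime in which unadjusted multicentre intensities stop
being comparable while order-based features remain exact.

Base intensities are piecewise-constant per tissue, ordered CSF < GM < WM as
in T1-weighted contrast, plus a fixed low-amplitude smooth ramp added before
the gamma step so that intensity orderings inside any 3x3 neighbourhood are
strict; this makes the gray-level invariance of the LBP features exact and
verifiable. Noise is added after the gamma transform, so invariance
demonstrations use ``noise_sigma=0`` while classification experiments use
``noise_sigma>0``. The region-label grid is returned alongside the volume;
only the geometric jitter step moves it, so labels and intensities stay
exactly aligned.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .volumes_io import BinaryMask, Volume, write_manifest, write_mask, write_volume

__all__ = [
    "PhantomCohortSpec",
    "GeometryError",
    "REGION_LABELS",
    "TISSUE_INTENSITY",
    "TISSUE_CONTRAST",
    "make_subject",
    "make_cohort",
    "region_labels",
]


class GeometryError(ValueError):
    """Raised when the requested blob geometry does not fit the grid."""


#: Integer labels of the phantom regions.
REGION_LABELS = {
    "background": 0,
    "csf": 1,
    "gm": 2,
    "wm": 3,
    "target_left": 4,
    "target_right": 5,
    "ventricle": 6,
}

#: Base tissue intensities before the ramp/gamma/noise steps (arbitrary
#: units in [0, 1], ordered CSF < GM < WM as in T1-weighted images).
TISSUE_INTENSITY = {
    0: 0.0,   # background
    1: 0.20,  # CSF shell
    2: 0.50,  # gray matter
    3: 0.80,  # white matter
    4: 0.45,  # target blob (GM-like, inside WM)
    5: 0.45,
    6: 0.15,  # ventricle (CSF-like)
}

#: Reference tissue contrast (WM minus CSF); noise_sigma scales this.
TISSUE_CONTRAST = TISSUE_INTENSITY[3] - TISSUE_INTENSITY[1]

#: Amplitude of the deterministic smooth ramp that breaks intensity ties.
_RAMP_AMPLITUDE = 0.02


@dataclasses.dataclass(frozen=True)
class PhantomCohortSpec:
    """Parameters of a reproducible synthetic cohort.

    atrophy_fraction is the linear shrink of the target-blob radii in
    patients (0.85 = 15% radius reduction); ventricle_dilation the linear
    growth of the ventricle radii. scanner_gammas is the pool of gamma
    exponents sampled per subject; scanner_gain_range bounds the per-subject
    multiplicative gain, drawn log-uniformly (arbitrary scanner output
    units); noise_sigma is the additive Gaussian noise
    standard deviation relative to the WM-CSF contrast; jitter_mm bounds the
    per-axis rigid translation. Identical spec + seed gives a bit-identical
    cohort.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_per_group: int = 20
    atrophy_fraction: float = 0.70
    ventricle_dilation: float = 1.12
    anatomy_jitter: Union[float, tuple[float, float, float, float]] = (0.03, 0.03, 0.06, 0.12)
    texture_sigma: float = 0.0
    texture_smoothness_vox: float = 2.0
    scanner_gammas: tuple[float, ...] = (0.5, 0.8, 1.0, 1.4, 2.0)
    scanner_gain_range: tuple[float, float] = (0.25, 4.0)
    noise_sigma: float = 0.05
    jitter_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.atrophy_fraction <= 1):
            raise ValueError(f"atrophy_fraction must be in (0,1], got {self.atrophy_fraction}")
        if self.ventricle_dilation < 1:
            raise ValueError(f"ventricle_dilation must be >= 1, got {self.ventricle_dilation}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        aj = self.anatomy_sds
        if any(not (0 <= a < 0.2) for a in aj):
            raise ValueError(f"anatomy_jitter entries must be in [0, 0.2), got {self.anatomy_jitter}")
        if self.texture_sigma < 0 or self.texture_smoothness_vox <= 0:
            raise ValueError("texture_sigma must be >= 0 and texture_smoothness_vox > 0")
        if self.jitter_mm < 0:
            raise ValueError(f"jitter_mm must be >= 0, got {self.jitter_mm}")
        if not self.scanner_gammas or any(g <= 0 for g in self.scanner_gammas):
            raise ValueError("scanner_gammas must be positive")
        lo, hi = self.scanner_gain_range
        if not (0 < lo <= hi):
            raise ValueError(f"scanner_gain_range must be 0 < lo <= hi, got {self.scanner_gain_range}")
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValueError(f"shape must be 3 axes of at least 8 voxels, got {self.shape}")

    @property
    def anatomy_sds(self) -> tuple[float, float, float, float]:
        """Per-structure anatomical radius SDs in the order
        (csf_inner, gm_inner, target, ventricle); a scalar applies to all."""
        if isinstance(self.anatomy_jitter, (int, float)):
            return (float(self.anatomy_jitter),) * 4
        return tuple(float(a) for a in self.anatomy_jitter)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        if r <= 0:
            return np.zeros(shape, dtype=bool)
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


_STRUCTURE_SCALES = ("csf_inner", "gm_inner", "target", "ventricle")


def region_labels(spec: PhantomCohortSpec, group: int,
                  scales: Optional[dict[str, float]] = None) -> np.ndarray:
    """Build the noiseless region-label grid for one group (+1 patient,
    -1 control).

    ``scales`` optionally perturbs individual structure radii (keys of
    ``_STRUCTURE_SCALES``) to model inter-subject anatomical variability;
    the outer head radius is fixed because affine registration normalizes
    global brain size. Deterministic: no jitter, no intensity steps.
    """
    if group not in (+1, -1):
        raise ValueError(f"group must be +1 or -1, got {group}")
    scales = scales or {}
    shape = spec.shape
    scale = min(shape) / 64.0
    cx, cy, cz = (n / 2.0 - 0.5 for n in shape)

    head_r = tuple(0.40 * n for n in shape)
    csf_inner = tuple(0.36 * n * scales.get("csf_inner", 1.0) for n in shape)
    gm_inner = tuple(0.28 * n * scales.get("gm_inner", 1.0) for n in shape)
    if any(c + r >= n for (c, r, n) in zip((cx, cy, cz), head_r, shape)):
        raise GeometryError(f"head ellipsoid radii {head_r} exceed grid {shape}")

    target_r = 4.5 * scale * scales.get("target", 1.0)
    vent_scale = scales.get("ventricle", 1.0)
    vent_r = (5.0 * scale * vent_scale, 11.0 * scale * vent_scale,
              5.0 * scale * vent_scale)
    if group == +1:
        target_r *= spec.atrophy_fraction
        vent_r = tuple(r * spec.ventricle_dilation for r in vent_r)
    if any(r >= 0.28 * n for r, n in zip(vent_r, shape)):
        raise GeometryError(f"ventricle radii {vent_r} exceed the white-matter core")

    labels = np.zeros(shape, dtype=np.uint8)
    labels[_ellipsoid(shape, (cx, cy, cz), head_r)] = REGION_LABELS["csf"]
    labels[_ellipsoid(shape, (cx, cy, cz), csf_inner)] = REGION_LABELS["gm"]
    labels[_ellipsoid(shape, (cx, cy, cz), gm_inner)] = REGION_LABELS["wm"]

    dx = 10.0 * scale
    t_center_l = (cx - dx, cy + 4.0 * scale, cz - 4.0 * scale)
    t_center_r = (cx + dx, cy + 4.0 * scale, cz - 4.0 * scale)
    labels[_ellipsoid(shape, t_center_l, (target_r,) * 3)] = REGION_LABELS["target_left"]
    labels[_ellipsoid(shape, t_center_r, (target_r,) * 3)] = REGION_LABELS["target_right"]
    labels[_ellipsoid(shape, (cx, cy, cz), vent_r)] = REGION_LABELS["ventricle"]
    return labels


def _ramp(shape) -> np.ndarray:
    """Fixed smooth intensity ramp with incommensurate per-axis slopes, so
    no two voxels of one tissue tie within any in-plane neighbourhood."""
    x, y, z = np.ogrid[tuple(slice(0, n) for n in shape)]
    coeff = (1.0, np.sqrt(2.0), np.sqrt(3.0))
    denom = sum(c * (n - 1) for c, n in zip(coeff, shape))
    return _RAMP_AMPLITUDE * (coeff[0] * x + coeff[1] * y + coeff[2] * z) / denom


def make_subject(spec: PhantomCohortSpec, group: int, subject_seed: int,
                 gamma: Optional[float] = None,
                 gain: Optional[float] = None) -> tuple[Volume, np.ndarray]:
    """Generate one subject: (intensity volume, region-label grid).

    All randomness derives from ``subject_seed``: jitter translation, the
    gamma draw from ``spec.scanner_gammas``, the noise field, and the gain
    draw from ``spec.scanner_gain_range`` are consumed in that fixed order
    (``gamma``/``gain`` arguments override the draws without changing the
    stream, so scanner variants of one subject share jitter and noise). The
    label grid is moved by the jitter but untouched by the intensity steps.
    """
    rng = np.random.default_rng(subject_seed)

    z = np.clip(rng.standard_normal(len(_STRUCTURE_SCALES)), -2.0, 2.0)
    scales = {name: 1.0 + sd * zi
              for name, sd, zi in zip(_STRUCTURE_SCALES, spec.anatomy_sds, z)}
    labels = region_labels(spec, group, scales)
    intens = np.zeros(spec.shape, dtype=np.float64)
    for lab, base in TISSUE_INTENSITY.items():
        intens[labels == lab] = base
    head = labels > 0
    intens[head] += _ramp(spec.shape)[head]

    # per-subject smooth within-tissue heterogeneity (partial volume,
    # biological texture); part of the anatomy, so added before the scanner
    # steps and bounded by a smooth squash to keep intensities positive
    raw = rng.standard_normal(spec.shape)
    if spec.texture_sigma > 0:
        field = gaussian_filter(raw, sigma=spec.texture_smoothness_vox)
        field /= field.std()
        amp = spec.texture_sigma * TISSUE_CONTRAST
        intens[head] += 2.5 * amp * np.tanh(field[head] / 2.5)

    # continuous translation bounded by jitter_mm, rounded to whole voxels
    draw = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
    shift = tuple(int(np.rint(d / s)) for d, s in zip(draw, spec.spacing))
    if any(shift):
        intens = np.roll(intens, shift, axis=(0, 1, 2))
        labels = np.roll(labels, shift, axis=(0, 1, 2))
        head = labels > 0

    drawn_gamma = float(rng.choice(np.asarray(spec.scanner_gammas, dtype=np.float64)))
    if gamma is None:
        gamma = drawn_gamma
    intens = intens ** gamma

    noise = rng.standard_normal(spec.shape)
    if spec.noise_sigma > 0:
        intens = intens + head * (spec.noise_sigma * TISSUE_CONTRAST) * noise

    lo, hi = spec.scanner_gain_range
    drawn_gain = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if gain is None:
        gain = drawn_gain
    intens = intens * gain

    vol = Volume(data=intens, spacing=spec.spacing, brain_mask=head)
    return vol, labels


def _sector_masks(spec: PhantomCohortSpec) -> dict[str, np.ndarray]:
    """Seven binary masks as dilated envelopes of the noiseless template
    geometry (union of control and patient variants, so every subject's
    shifted boundaries fall inside)."""
    ctrl = region_labels(spec, -1)
    pat = region_labels(spec, +1)
    shape = spec.shape
    scale = min(shape) / 64.0
    cy = shape[1] / 2.0 - 0.5
    cz = shape[2] / 2.0 - 0.5
    x, y, z = np.ogrid[tuple(slice(0, n) for n in shape)]

    grow = max(2, int(round(2 * scale)) + int(spec.jitter_mm // min(spec.spacing)))

    def envelope(*labs):
        m = np.isin(ctrl, labs) | np.isin(pat, labs)
        return binary_dilation(m, iterations=grow)

    gm = (ctrl == 2) | (pat == 2)
    masks = {
        "AMG": envelope(REGION_LABELS["target_left"]),
        "HIP": envelope(REGION_LABELS["target_right"]),
        "ENT": binary_dilation(gm & (y > cy + 4 * scale) & (z < cz), iterations=grow),
        "PHG": binary_dilation(gm & (y < cy - 4 * scale) & (z < cz), iterations=grow),
        "TL": binary_dilation(
            ((ctrl >= 2) | (pat >= 2)) & (z < cz - 6 * scale), iterations=grow),
        "LV": envelope(REGION_LABELS["ventricle"]),
    }
    masks["OVALL"] = np.logical_or.reduce(list(masks.values()))
    return masks


@dataclasses.dataclass
class Cohort:
    """Paths and in-memory handles of a generated cohort."""

    manifest: pd.DataFrame
    manifest_path: Path
    template_path: Path
    masks: dict[str, BinaryMask]
    mask_paths: dict[str, Path]
    spec: PhantomCohortSpec


def make_cohort(spec: PhantomCohortSpec, out_dir: Union[str, Path]) -> Cohort:
    """Generate a full cohort on disk.

    Writes ``n_per_group`` patients (+1) and controls (-1) as NIfTI, a
    template volume (a disease-free subject at gamma 1, gain 1, no jitter,
    with its own anatomy and noise, like a single-subject atlas), the
    seven anatomical masks (OVALL = element-wise OR of the other six), and a
    TSV manifest. Per-subject seeds derive from ``spec.seed``.
    """
    out_dir = Path(out_dir)
    (out_dir / "subjects").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.generate_state(2 * spec.n_per_group + 1, dtype=np.uint32)
    template_seed, subject_seeds = int(seeds[0]), seeds[1:]

    # the template is itself a realistic image: a disease-free subject at
    # reference contrast (gamma 1, gain 1, no jitter) with its own texture
    # and noise, as single-subject atlas templates are real acquisitions
    tmpl_spec = dataclasses.replace(spec, jitter_mm=0.0)
    tmpl_vol, _ = make_subject(tmpl_spec, -1, template_seed, gamma=1.0, gain=1.0)
    template_path = write_volume(tmpl_vol, out_dir / "template.nii.gz")

    rows = []
    idx = 0
    for group, tag, prefix in ((+1, "patient", "P"), (-1, "control", "C")):
        for k in range(spec.n_per_group):
            sid = f"{prefix}{k:03d}"
            vol, _ = make_subject(spec, group, int(subject_seeds[idx]))
            path = write_volume(vol, out_dir / "subjects" / f"{sid}.nii.gz")
            rows.append({"subject_id": sid, "path": str(path), "label": group,
                         "group": tag})
            idx += 1
    manifest = pd.DataFrame(rows)
    manifest_path = write_manifest(manifest, out_dir / "manifest.tsv")

    masks: dict[str, BinaryMask] = {}
    mask_paths: dict[str, Path] = {}
    for name, arr in _sector_masks(spec).items():
        bm = BinaryMask(arr, name, spec.spacing)
        masks[name] = bm
        mask_paths[name] = write_mask(bm, out_dir / "masks" / f"{name}.nii.gz")

    return Cohort(manifest=manifest, manifest_path=manifest_path,
                  template_path=template_path, masks=masks,
                  mask_paths=mask_paths, spec=spec)
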
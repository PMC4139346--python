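"""Gray-level-invariant texture features for registered brain volumes.

Three feature-image types are supported:

* **Type 1** — the raw registered intensity volume, with no adjustment.
* **Type 2** — histogram matching of within-brain intensities to a template.
* **Type 3** — smoothed LBP-TOP code maps, the gray-level-invariant feature.

The local binary pattern (LBP) encodes, for every pixel, the sign pattern of
its 8 ring neighbours relative to the centre, packed into one byte:

    code = sum_{p=0}^{7} s(I_p - I_c) * 2**p,   s(x) = 1 iff x >= 0.

Because the code depends only on intensity *orderings*, it is unchanged by
any strictly increasing transform of the gray levels — the model used here
for cross-scanner variability in multicentre MRI. LBP-TOP applies the 2D
operator slicewise on the three orthogonal planes of a volume (sagittal y-z,
coronal x-z, axial x-y), giving three code volumes per subject.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes_io import Volume

__all__ = [
    "NeighborhoodSpec",
    "LBPTOPMaps",
    "SmoothingSpec",
    "FeatureImage",
    "PLANE_NAMES",
    "FWHM_TO_SIGMA",
    "lbp2d",
    "lbp_top",
    "smooth_codes",
    "histogram_equalize",
    "feature_image",
]

#: Plane order used everywhere downstream (feature concatenation, weight
#: back-projection): sagittal y-z, coronal x-z, axial x-y.
PLANE_NAMES = ("yz", "xz", "xy")

#: sigma = FWHM * FWHM_TO_SIGMA for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

# 3x3 ring enumerated clockwise from the top-left corner, in (row, col)
# offsets; offset position p contributes bit p. Any fixed order preserves
# the invariance properties; this one is fixed for bit-exact reproducibility.
_RING_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, 1),
    (1, 1), (1, 0), (1, -1),
    (0, -1),
)


@dataclasses.dataclass(frozen=True)
class NeighborhoodSpec:
    """The 8-neighbour ring and bit assignment for the LBP operator.

    ``offsets[p]`` is the in-plane (row, col) offset whose comparison result
    occupies bit ``bit_order[p]``. Defaults: clockwise ring from the top-left
    corner, identity bit order.
    """

    offsets: tuple[tuple[int, int], ...] = _RING_OFFSETS
    bit_order: tuple[int, ...] = tuple(range(8))

    def __post_init__(self) -> None:
        ring = {(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)} - {(0, 0)}
        if len(self.offsets) != 8 or set(self.offsets) != ring:
            raise ValueError("offsets must be the 8 distinct cells of the 3x3 ring")
        if sorted(self.bit_order) != list(range(8)):
            raise ValueError("bit_order must be a permutation of 0..7")

    @property
    def P(self) -> int:
        return 8


@dataclasses.dataclass
class LBPTOPMaps:
    """Per-subject LBP code volumes on the three orthogonal planes.

    ``valid`` marks voxels whose full 3x3 neighbourhood exists in all three
    planes; it is False on the one-voxel border of every axis. Border voxels
    carry code 0 and must be ignored via ``valid``.
    """

    map_yz: np.ndarray
    map_xz: np.ndarray
    map_xy: np.ndarray
    valid: np.ndarray

    @property
    def planes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.map_yz, self.map_xz, self.map_xy)


@dataclasses.dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing of code maps, parameterised by per-axis FWHM in mm.

    The boundary mode is fixed to 'reflect' so constant maps are preserved
    exactly. Default FWHM is 4 mm isotropic.
    """

    fwhm_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fwhm_mm):
            raise ValueError(f"fwhm_mm must be >= 0, got {self.fwhm_mm}")

    def sigma_voxels(self, spacing: Sequence[float]) -> tuple[float, ...]:
        return tuple(f * FWHM_TO_SIGMA / s for f, s in zip(self.fwhm_mm, spacing))


def _lbp_codes(data: np.ndarray, row_axis: int, col_axis: int,
               spec: NeighborhoodSpec) -> tuple[np.ndarray, np.ndarray]:
    """LBP codes over the (row_axis, col_axis) plane for a 2D or 3D array.

    Vectorised over all slices at once: each of the 8 neighbour comparisons
    is a single shifted-array comparison on the interior region.
    """
    ndim = data.ndim
    inner = [slice(None)] * ndim
    inner[row_axis] = slice(1, -1)
    inner[col_axis] = slice(1, -1)
    inner = tuple(inner)

    center = data[inner]
    codes_in = np.zeros(center.shape, dtype=np.uint8)
    for p, (dr, dc) in enumerate(spec.offsets):
        sl = [slice(None)] * ndim
        sl[row_axis] = slice(1 + dr, data.shape[row_axis] - 1 + dr)
        sl[col_axis] = slice(1 + dc, data.shape[col_axis] - 1 + dc)
        neighbor = data[tuple(sl)]
        bit = np.uint8(1 << spec.bit_order[p])
        codes_in |= np.where(neighbor >= center, bit, np.uint8(0))

    codes = np.zeros(data.shape, dtype=np.uint8)
    codes[inner] = codes_in
    valid = np.zeros(data.shape, dtype=bool)
    valid[inner] = True
    return codes, valid


def lbp2d(slice2d: np.ndarray,
          spec: Optional[NeighborhoodSpec] = None) -> tuple[np.ndarray, np.ndarray]:
    """Compute the LBP code grid of a single 2D slice.

    Returns ``(codes, valid)``: interior pixels carry the 8-bit code, border
    pixels carry 0 with ``valid`` False. With the ``s(0)=1`` tie convention a
    constant slice yields code 255 everywhere in the interior.
    """
    slice2d = np.asarray(slice2d)
    if slice2d.ndim != 2:
        raise ValueError(f"lbp2d expects a 2D slice, got shape {slice2d.shape}")
    if min(slice2d.shape) < 3:
        raise ValueError(f"slice must be at least 3x3, got {slice2d.shape}")
    if spec is None:
        spec = NeighborhoodSpec()
    return _lbp_codes(slice2d, 0, 1, spec)


def lbp_top(volume, spec: Optional[NeighborhoodSpec] = None) -> LBPTOPMaps:
    """Compute LBP-TOP code maps of a volume on the three orthogonal planes.

    ``map_yz`` is the slicewise LBP over sagittal y-z slices (fixed x),
    ``map_xz`` over coronal x-z slices (fixed y), ``map_xy`` over axial x-y
    slices (fixed z). In-plane axis order follows the volume's axis order, so
    cyclic axis permutations of the input permute the maps correspondingly.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if data.ndim != 3:
        raise ValueError(f"lbp_top expects a 3D volume, got shape {data.shape}")
    if min(data.shape) < 3:
        raise ValueError(f"volume must be at least 3x3x3, got {data.shape}")
    if spec is None:
        spec = NeighborhoodSpec()

    map_yz, valid_yz = _lbp_codes(data, 1, 2, spec)
    map_xz, valid_xz = _lbp_codes(data, 0, 2, spec)
    map_xy, valid_xy = _lbp_codes(data, 0, 1, spec)
    return LBPTOPMaps(
        map_yz=map_yz,
        map_xz=map_xz,
        map_xy=map_xy,
        valid=valid_yz & valid_xz & valid_xy,
    )


def smooth_codes(maps: LBPTOPMaps, spec: Optional[SmoothingSpec] = None,
                 spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> list[np.ndarray]:
    """Gaussian-smooth the three code maps, treating codes as real scalars.

    The per-axis sigma in voxels is ``fwhm_mm * FWHM_TO_SIGMA / spacing_mm``.
    Validity is unchanged; FWHM 0 is the identity.
    """
    if spec is None:
        spec = SmoothingSpec()
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    sigma = spec.sigma_voxels(spacing)
    out = []
    for m in maps.planes:
        field = np.asarray(m, dtype=np.float64)
        if all(s == 0 for s in sigma):
            out.append(field.copy())
        else:
            out.append(gaussian_filter(field, sigma=sigma, mode=spec.boundary))
    return out


def _mask_of(volume: Volume) -> np.ndarray:
    if volume.brain_mask is None:
        raise ValueError("histogram matching requires a brain mask on both images")
    if not volume.brain_mask.any():
        raise ValueError("brain mask is empty")
    return volume.brain_mask


def histogram_equalize(volume: Volume, template: Volume, n_bins: int = 256) -> Volume:
    """Match within-brain intensities of ``volume`` to ``template``.

    Classic histogram matching: input intensities are mapped through the
    input's within-mask CDF and then through the inverse of the template's
    within-mask CDF, each estimated on ``n_bins`` bins spanning that mask's
    intensity range. The composed mapping is non-decreasing. Voxels outside
    the brain mask are set to 0.
    """
    in_mask = _mask_of(volume)
    t_mask = _mask_of(template)
    src = np.asarray(volume.data, dtype=np.float64)[in_mask]
    ref = np.asarray(template.data, dtype=np.float64)[t_mask]

    src_edges = np.linspace(src.min(), src.max(), n_bins + 1)
    ref_edges = np.linspace(ref.min(), ref.max(), n_bins + 1)
    src_hist, _ = np.histogram(src, bins=src_edges)
    ref_hist, _ = np.histogram(ref, bins=ref_edges)
    src_cdf = np.cumsum(src_hist) / src.size
    ref_cdf = np.cumsum(ref_hist) / ref.size
    ref_centers = 0.5 * (ref_edges[:-1] + ref_edges[1:])

    # bin index of each source voxel -> CDF quantile -> template intensity
    idx = np.clip(np.searchsorted(src_edges, src, side="right") - 1, 0, n_bins - 1)
    quantile = src_cdf[idx]
    matched = np.interp(quantile, ref_cdf, ref_centers)

    out = np.zeros(volume.data.shape, dtype=np.float64)
    out[in_mask] = matched
    return Volume(data=out, spacing=volume.spacing, brain_mask=in_mask)


@dataclasses.dataclass
class FeatureImage:
    """Per-subject feature planes plus a shared validity grid.

    Types 1-2 have a single plane; type 3 has three (yz, xz, xy order).
    """

    planes: list[np.ndarray]
    validity: np.ndarray
    feature_type: int
    plane_names: tuple[str, ...]


def feature_image(volume: Volume, feature_type: int,
                  template: Optional[Volume] = None,
                  smoothing: Optional[SmoothingSpec] = None) -> FeatureImage:
    """Compute the feature image of one subject.

    ``feature_type`` 1 returns the registered intensities unchanged; 2 the
    histogram-matched intensities (``template`` required); 3 the smoothed
    LBP-TOP code maps. For types 1-2 validity is the brain mask when present,
    else the whole grid; for type 3 it is the LBP validity grid intersected
    with the brain mask when present.
    """
    if feature_type == 1:
        validity = volume.brain_mask if volume.brain_mask is not None \
            else np.ones(volume.data.shape, dtype=bool)
        return FeatureImage([np.asarray(volume.data, dtype=np.float64)],
                            validity, 1, ("intensity",))
    if feature_type == 2:
        if template is None:
            raise ValueError("feature type 2 requires a template volume")
        matched = histogram_equalize(volume, template)
        return FeatureImage([matched.data], matched.brain_mask, 2, ("histeq",))
    if feature_type == 3:
        maps = lbp_top(volume)
        smoothed = smooth_codes(maps, smoothing, volume.spacing)
        validity = maps.valid
        if volume.brain_mask is not None:
            validity = validity & volume.brain_mask
        return FeatureImage(smoothed, validity, 3, PLANE_NAMES)
    raise ValueError(f"unknown feature type {feature_type!r}; expected 1, 2 or 3")
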
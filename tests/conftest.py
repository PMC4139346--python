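"""Shared test helpers: an independent brute-force LBP oracle and small
deterministic phantom configurations.

The oracle is written as plain triple loops from the code definition

    code = sum_p s(I_p - I_c) * 2**p,   s(x) = 1 iff x >= 0,

with the ring enumerated clockwise from the top-left corner, and is kept
deliberately naive so it shares no code with the library implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from lbpbrain import PhantomCohortSpec

# clockwise ring from the top-left corner, (row, col) offsets; bit p is
# offset position p — the package's documented convention, restated here
# independently for the oracle
ORACLE_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, 1),
    (1, 1), (1, 0), (1, -1),
    (0, -1),
]


def oracle_lbp2d(img):
    """Brute-force 2D LBP: loop over every interior pixel and neighbour."""
    img = np.asarray(img)
    rows, cols = img.shape
    codes = np.zeros((rows, cols), dtype=np.uint8)
    valid = np.zeros((rows, cols), dtype=bool)
    for r in range(1, rows - 1):
        for c in range(1, cols - 1):
            code = 0
            for p, (dr, dc) in enumerate(ORACLE_OFFSETS):
                if img[r + dr, c + dc] >= img[r, c]:
                    code += 2 ** p
            codes[r, c] = code
            valid[r, c] = True
    return codes, valid


def oracle_lbp_top(vol):
    """Brute-force LBP-TOP: slice loops on the three orthogonal planes.

    Plane order (yz, xz, xy): sagittal slices vol[x, :, :], coronal slices
    vol[:, y, :], axial slices vol[:, :, z]; in-plane row/col order follows
    the volume's axis order.
    """
    vol = np.asarray(vol)
    nx, ny, nz = vol.shape
    map_yz = np.zeros(vol.shape, dtype=np.uint8)
    map_xz = np.zeros(vol.shape, dtype=np.uint8)
    map_xy = np.zeros(vol.shape, dtype=np.uint8)
    v_yz = np.zeros(vol.shape, dtype=bool)
    v_xz = np.zeros(vol.shape, dtype=bool)
    v_xy = np.zeros(vol.shape, dtype=bool)
    for x in range(nx):
        map_yz[x], v_yz[x] = oracle_lbp2d(vol[x, :, :])
    for y in range(ny):
        map_xz[:, y, :], v_xz[:, y, :] = oracle_lbp2d(vol[:, y, :])
    for z in range(nz):
        map_xy[:, :, z], v_xy[:, :, z] = oracle_lbp2d(vol[:, :, z])
    return (map_yz, map_xz, map_xy), (v_yz & v_xz & v_xy)


#: Strictly increasing gray-level transforms used by invariance tests.
MONOTONE_TRANSFORMS = (
    lambda x: 3.0 * x + 7.0,
    lambda x: np.exp(x),
    lambda x: x ** 3,
    lambda x: np.arctan(x),
    lambda x: np.log1p(x - x.min()) - 5.0,
)


def iid_null_spec(seed: int, n_per_group: int = 15) -> PhantomCohortSpec:
    """A cohort spec whose only variability is iid voxel noise.

    No anatomical variability, one gamma, unit gain, no jitter: raw
    intensities are constant-plus-iid-noise per voxel, so voxelwise t-test
    p-values are independent across voxels and the first-step selection
    count is exactly binomial under exchangeable groups.
    """
    return PhantomCohortSpec(
        n_per_group=n_per_group,
        anatomy_jitter=0.0,
        texture_sigma=0.0,
        scanner_gammas=(1.0,),
        scanner_gain_range=(1.0, 1.0),
        noise_sigma=0.10,
        jitter_mm=0.0,
        seed=seed,
    )


def small_spec(seed: int = 5, n_per_group: int = 3, **kw) -> PhantomCohortSpec:
    """A fast low-resolution cohort for smoke tests."""
    kw.setdefault("shape", (32, 32, 32))
    return PhantomCohortSpec(n_per_group=n_per_group, seed=seed, **kw)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """One small cohort on disk, shared across smoke tests."""
    from lbpbrain import make_cohort

    out = tmp_path_factory.mktemp("tiny_cohort")
    spec = small_spec(seed=5, n_per_group=3)
    return make_cohort(spec, out)
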
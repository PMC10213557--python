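"""Digital calibration phantoms with known analytic geometry.

Labeled volumes of balls, boxes and ellipsoids whose exact volumes,
surface areas and principal axes are known in closed form; used to
calibrate and validate the morphometric estimators.
"""

from __future__ import annotations

import numpy as np

from primordium3d.core_io import LabeledVolume


def digital_ball(radius_vox: int, voxel: float = 1.0,
                 label: int = 1) -> LabeledVolume:
    """A solid ball of the given radius (in voxels) on an isotropic grid."""
    n = 2 * radius_vox + 6
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = n / 2
    mask = (zz + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 + (xx + 0.5 - c) ** 2 \
        <= radius_vox**2
    return LabeledVolume((mask * label).astype(np.uint16),
                         (voxel,) * 3, base_plane=None)


def digital_box(shape_vox, voxel=(1.0, 1.0, 1.0), pad: int = 2,
                label: int = 1) -> LabeledVolume:
    """An axis-aligned solid box of the given (z, y, x) voxel extents."""
    dz, dy, dx = shape_vox
    arr = np.zeros((dz + 2 * pad, dy + 2 * pad, dx + 2 * pad), np.uint16)
    arr[pad:pad + dz, pad:pad + dy, pad:pad + dx] = label
    return LabeledVolume(arr, voxel, base_plane=None)


def digital_ellipsoid(semi_vox, voxel: float = 1.0,
                      label: int = 1) -> LabeledVolume:
    """A solid ellipsoid with (z, y, x) semi-axes given in voxels."""
    a, b, c = semi_vox
    shape = (2 * a + 6, 2 * b + 6, 2 * c + 6)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    cc = [s / 2 for s in shape]
    mask = ((zz + 0.5 - cc[0]) / a) ** 2 + ((yy + 0.5 - cc[1]) / b) ** 2 \
        + ((xx + 0.5 - cc[2]) / c) ** 2 <= 1
    return LabeledVolume((mask * label).astype(np.uint16),
                         (voxel,) * 3, base_plane=None)


def stacked_boxes(side: int = 20, offset: int = 0) -> LabeledVolume:
    """Two boxes stacked along z; the lower one laterally offset (voxels).

    With offset 0 the side walls of the two cells are exactly coplanar —
    the idealized signature of a fresh division; a lateral offset breaks
    the continuity by a step of known size.
    """
    pad = 4 + abs(offset)
    arr = np.zeros((2 * side + 2 * pad, side + 2 * pad, side + 2 * pad),
                   np.uint16)
    arr[pad:pad + side, pad + offset:pad + offset + side, pad:pad + side] = 2
    arr[pad + side:pad + 2 * side, pad:pad + side, pad:pad + side] = 1
    return LabeledVolume(arr, (1.0, 1.0, 1.0), base_plane=None)
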
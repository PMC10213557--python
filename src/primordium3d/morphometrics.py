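"""Per-cell size and shape descriptors.

Volume from voxel counts; surface area from smoothed iso-surface meshes
(raw voxel-face counting overestimates oblique surfaces by up to ~50% and
would corrupt sphericity); a fitting ellipsoid from second central moments
of the voxel cloud; and the derived normalized-axis, sphericity,
ellipticity and two-axis anisotropy descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from skimage import measure

from primordium3d import _geometry as geom
from primordium3d.core_io import CELL_TABLE_COLUMNS, LabeledVolume, SurfaceMesh

logger = logging.getLogger("primordium3d")


@dataclass
class EllipsoidFit:
    """Second-moment fitting ellipsoid of a cell.

    ``semi_axes`` are sorted ascending (a <= b <= c) in µm; ``axes`` holds
    the corresponding orthonormal direction vectors as columns. For a solid
    uniform ellipsoid the semi-axis along eigenvector i is sqrt(5 λ_i) of
    the covariance eigenvalue λ_i, which is the scale adopted here.
    """

    semi_axes: np.ndarray   # (a, b, c), ascending, µm
    axes: np.ndarray        # columns = unit vectors for a, b, c

    def __post_init__(self):
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        a, b, c = self.semi_axes
        if not (a <= b <= c):
            raise ValueError("semi-axes must be sorted ascending")
        if np.max(np.abs(self.axes.T @ self.axes - np.eye(3))) > 1e-6:
            raise ValueError("axis vectors must be orthonormal")

    @property
    def normalized(self) -> np.ndarray:
        """Axis lengths normalized by their sum; sums to 1."""
        return self.semi_axes / self.semi_axes.sum()

    @property
    def anisotropy2(self) -> float:
        """Two-axis anisotropy c/(a+c), in [0.5, 1)."""
        a, _, c = self.semi_axes
        return float(c / (a + c))

    @property
    def major_axis(self) -> np.ndarray:
        return self.axes[:, 2]


def measure_volume(volume: LabeledVolume, cell_label: int) -> float:
    """Cell volume in µm³: voxel count × voxel volume."""
    return float(volume.mask(cell_label).sum()) * volume.voxel_volume


def extract_cell_mesh(
    volume: LabeledVolume, cell_label: int, smoothing_iters: int = 10
) -> tuple[SurfaceMesh, float]:
    """Iso-surface mesh of one cell and its surface area (µm²).

    The mesh is marching cubes on the Gaussian-smoothed (σ = 1 voxel)
    binary mask, Taubin-smoothed. The reported area is not the mesh
    triangle sum (mesh smoothing shaves sharp cell corners) but the
    oblique-corrected boundary-face projection of
    :func:`primordium3d.walls.cell_surface_area`, which is exact on
    axis-aligned walls and unbiased on staircased oblique or curved ones.
    """
    from primordium3d.walls import _crop_around, cell_surface_area

    sub, offset = _crop_around(volume, [cell_label])
    mask = sub.labels == cell_label
    mesh, _ = _mask_mesh(mask, sub.voxel_size, smoothing_iters)
    mesh.vertices += offset
    return mesh, cell_surface_area(sub, cell_label)


def _mask_mesh(mask, voxel_size, smoothing_iters=10) -> tuple[SurfaceMesh, float]:
    thin = min(mask.any(axis=(1, 2)).sum(), mask.any(axis=(0, 2)).sum(),
               mask.any(axis=(0, 1)).sum()) < 2
    if thin:
        logger.warning("cell thinner than 2 voxels in some direction; "
                       "mesh left unsmoothed")
    padded = np.pad(mask, 2).astype(np.float32)
    if not thin:
        smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
        if smoothed.max() > 0.5:
            padded = smoothed
        else:  # cell too small to survive smoothing: mesh the raw mask
            thin = True
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(voxel_size)
    )
    verts -= 1.5 * np.asarray(voxel_size)  # undo padding, voxel-center origin
    tm = trimesh.Trimesh(verts, faces, process=False)
    if not thin and smoothing_iters > 0:
        trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=-0.53,
                                        iterations=smoothing_iters)
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       watertight=bool(tm.is_watertight))
    return mesh, float(tm.area)


def fit_ellipsoid(volume: LabeledVolume, cell_label: int) -> EllipsoidFit:
    """Fitting ellipsoid from second central moments of the voxel cloud.

    The per-voxel variance (d²/12 along each grid axis) is added to the
    voxel-center covariance so a w×h×d box yields side²/12 exactly.
    """
    mask = volume.mask(cell_label)
    if mask.sum() < 27:
        raise ValueError(f"cell {cell_label} has < 27 voxels; fit unreliable")
    pts = geom.voxel_centers(mask, volume.voxel_size)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    cov += np.diag(np.asarray(volume.voxel_size, dtype=float) ** 2) / 12.0
    w, v = np.linalg.eigh(cov)
    if w[0] <= 1e-12:
        raise ValueError(f"cell {cell_label}: degenerate (coplanar) voxel set")
    return EllipsoidFit(semi_axes=np.sqrt(5.0 * w), axes=v)


def shape_descriptors(
    volume_value: float, surface_area: float, fit: EllipsoidFit
) -> tuple[float, float, float]:
    """(sphericity, prolate ellipticity, oblate ellipticity).

    Sphericity ψ = π^(1/3) (6V)^(2/3) / A equals 1 for a perfect sphere.
    With semi-axes a ≤ b ≤ c, prolate ellipticity e_p = (c − b)/c measures
    elongation toward a rugby-ball spheroid and oblate ellipticity
    e_o = (b − a)/b flattening toward a disk; both are in [0, 1) and zero
    on the sphere.
    """
    if volume_value <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    psi = np.pi ** (1 / 3) * (6.0 * volume_value) ** (2 / 3) / surface_area
    a, b, c = fit.semi_axes
    e_p = (c - b) / c
    e_o = (b - a) / b
    return float(psi), float(e_p), float(e_o)


def measure_cells(volume: LabeledVolume, annotation, ovule_id="ovule",
                  smoothing_iters: int = 10) -> pd.DataFrame:
    """One row of descriptors per cell; deterministic given its inputs.

    Per-cell failures (degenerate fits, tiny cells) are logged and the row
    flagged with NaN descriptors; the run continues.
    """
    from primordium3d.walls import apical_basal_walls

    rows = []
    for lab in volume.cell_labels():
        lab = int(lab)
        row = {c: np.nan for c in CELL_TABLE_COLUMNS}
        row.update(
            ovule_id=ovule_id,
            cell_label=lab,
            layer=annotation.layers.get(lab),
            contact_class=annotation.contact_classes.get(lab, "other"),
        )
        try:
            vol = measure_volume(volume, lab)
            _, area = extract_cell_mesh(volume, lab, smoothing_iters)
            fit = fit_ellipsoid(volume, lab)
            psi, e_p, e_o = shape_descriptors(vol, area, fit)
            na, nb_, nc = fit.normalized
            row.update(
                volume_um3=vol, surface_area_um2=area,
                semi_a_um=fit.semi_axes[0], semi_b_um=fit.semi_axes[1],
                semi_c_um=fit.semi_axes[2],
                norm_a=na, norm_b=nb_, norm_c=nc,
                sphericity=psi, prolate_ellipticity=e_p,
                oblate_ellipticity=e_o, anisotropy2=fit.anisotropy2,
            )
        except (ValueError, KeyError) as exc:
            logger.warning("ovule %s cell %s: measurement failed (%s)",
                           ovule_id, lab, exc)
        rows.append(row)
    table = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
    try:
        apical, basal, ratio = apical_basal_walls(volume, annotation)
        sel = table["cell_label"] == annotation.central_L2
        table.loc[sel, "apical_wall_um2"] = apical
        if basal is not None:
            table.loc[sel, "basal_wall_um2"] = basal
    except ValueError as exc:
        logger.warning("ovule %s: apical/basal walls unavailable (%s)",
                       ovule_id, exc)
    return table
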
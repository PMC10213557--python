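"""Shared low-level geometry helpers (internal).

All physical coordinates are (z, y, x) in micrometres; voxel (k, j, i) has
its center at ((k+0.5)*dz, (j+0.5)*dy, (i+0.5)*dx).
"""

from __future__ import annotations

import numpy as np


def voxel_centers(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Physical (z,y,x) centers of True voxels, shape (n, 3)."""
    idx = np.argwhere(mask)
    return (idx + 0.5) * np.asarray(voxel_size, dtype=float)


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def angle_between_deg(a, b) -> float:
    """Unsigned angle between two vectors, in degrees, in [0, 180]."""
    a, b = unit(a), unit(b)
    return float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))


def fibonacci_half_sphere(n: int) -> np.ndarray:
    """Quasi-uniform directions on the half-sphere (z >= 0), shape (n, 3).

    Spherical Fibonacci lattice restricted to the upper hemisphere;
    antipodal directions are equivalent for plane normals.
    """
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n  # in (0, 1): upper hemisphere only
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([z, r * np.sin(phi), r * np.cos(phi)])


def tangent_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to n and to each other."""
    n = unit(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = unit(np.cross(n, helper))
    t2 = np.cross(n, t1)
    return t1, t2


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through a point cloud.

    Returns (centroid, unit normal, RMS orthogonal residual). The normal is
    the minor principal axis of the cloud.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("plane fit needs >= 3 points")
    c = points.mean(axis=0)
    d = points - c
    cov = d.T @ d / len(points)
    w, v = np.linalg.eigh(cov)
    normal = v[:, 0]
    rms = float(np.sqrt(max(w[0], 0.0)))
    return c, normal, rms


def principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors (columns) of the covariance."""
    points = np.asarray(points, dtype=float)
    c = points.mean(axis=0)
    d = points - c
    cov = d.T @ d / len(points)
    w, v = np.linalg.eigh(cov)
    return w, v


def exterior_faces(labels: np.ndarray, base_plane: str = "z_min"):
    """Centers and outward normals of foreground faces touching the exterior.

    The exterior is background plus the volume boundary, except the
    ``base_plane`` face, which is treated as tissue continuation. Returns
    (face_center_index_coords, outward_normals) where index coords are in
    voxel units (k, j, i) of the face center (offset by 0.5 from the voxel
    center toward the face).
    """
    padded = np.pad(labels, 1, constant_values=0)
    if base_plane is not None:
        ax, side = _parse_base_plane(base_plane)
        outer = [slice(1, -1)] * 3
        outer[ax] = 0 if side == "min" else -1
        inner = [slice(None)] * 3
        inner[ax] = 0 if side == "min" else -1
        # continue tissue through the base plane: mirror the first slab
        padded[tuple(outer)] = labels[tuple(inner)]
    centers = []
    normals = []
    for ax in range(3):
        for sign in (-1, 1):
            nb = np.roll(padded, -sign, axis=ax)[1:-1, 1:-1, 1:-1]
            fg = labels > 0
            ext = fg & (nb == 0)
            idx = np.argwhere(ext).astype(float)
            idx[:, ax] += 0.5 * sign
            centers.append(idx)
            nvec = np.zeros(3)
            nvec[ax] = sign
            normals.append(np.tile(nvec, (len(idx), 1)))
    return np.vstack(centers), np.vstack(normals)


def _parse_base_plane(base_plane: str) -> tuple[int, str]:
    axes = {"z": 0, "y": 1, "x": 2}
    ax_name, side = base_plane.split("_")
    if ax_name not in axes or side not in ("min", "max"):
        raise ValueError(f"invalid base_plane {base_plane!r}")
    return axes[ax_name], side


def local_radial_direction(labels: np.ndarray, voxel_size, point_um,
                           base_plane: str = "z_min",
                           neighborhood_um: float = 3.0) -> np.ndarray:
    """Outward surface normal at the exterior point nearest to ``point_um``.

    The local radial direction of the tissue: the mean outward normal of the
    exterior faces within ``neighborhood_um`` of the nearest exterior face.
    Used to define periclinal (wall normal parallel to it) vs anticlinal.
    """
    faces = exterior_faces(labels, base_plane)
    return radial_from_faces(faces, voxel_size, point_um, neighborhood_um)


def radial_from_faces(faces, voxel_size, point_um,
                      neighborhood_um: float = 3.0) -> np.ndarray:
    """As :func:`local_radial_direction`, from precomputed exterior faces."""
    centers_idx, normals = faces
    if len(centers_idx) == 0:
        raise ValueError("volume has no exterior surface")
    vs = np.asarray(voxel_size, dtype=float)
    centers = (centers_idx + 0.5) * vs
    d = np.sqrt(np.sum(
        (centers - np.asarray(point_um, dtype=float)) ** 2, axis=1))
    # all faces within `neighborhood_um` beyond the closest one: a surface
    # cap centered over the query point (centering on the single nearest
    # face would skew the cap by the staircase parity of the local surface)
    near = d <= d.min() + neighborhood_um
    return unit(normals[near].sum(axis=0))
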
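"""Data model and readers/writers for labeled volumes, meshes, tables, config.

Conventions fixed package-wide: axis order (z, y, x), 0-based indices,
voxel-center physical coordinates, all lengths in µm (areas µm², volumes µm³).
Anisotropic voxels are supported everywhere.
"""

from __future__ import annotations

import gzip
import logging
import zlib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

logger = logging.getLogger("primordium3d")

VALID_BASE_PLANES = ("z_min", "z_max", "y_min", "y_max", "x_min", "x_max", None)


@dataclass
class LabeledVolume:
    """A segmented 3D image: one integer label per cell, 0 = background.

    Parameters
    ----------
    labels : ndarray, shape (nz, ny, nx), integer
        Cell labels; 0 is background.
    voxel_size : tuple of float
        (dz, dy, dx) in µm, all > 0.
    base_plane : str or None
        Grid face treated as tissue continuation (the crop plane), default
        the minimum-z face. That face is not "exterior" for L1 detection.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    base_plane: str | None = "z_min"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be of integer dtype")
        if self.labels.min() < 0:
            raise ValueError("label values must be >= 0")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive floats (dz, dy, dx)")
        if self.base_plane not in VALID_BASE_PLANES:
            raise ValueError(f"invalid base_plane {self.base_plane!r}")

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def cell_labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    def mask(self, label: int) -> np.ndarray:
        m = self.labels == label
        if not m.any():
            raise KeyError(f"label {label} not present in volume")
        return m

    def centroid(self, label: int) -> np.ndarray:
        """Physical (z, y, x) centroid of a cell in µm."""
        idx = np.argwhere(self.mask(label))
        return (idx.mean(axis=0) + 0.5) * np.asarray(self.voxel_size)


@dataclass
class SurfaceMesh:
    """Triangulated surface in physical (z, y, x) µm coordinates."""

    vertices: np.ndarray
    triangles: np.ndarray
    scalar: np.ndarray | None = None
    watertight: bool | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise IndexError("triangle index out of range")
        if self.scalar is not None:
            self.scalar = np.asarray(self.scalar, dtype=float)
            if len(self.scalar) != len(self.vertices):
                raise ValueError("scalar channel length must match vertex count")
        if self.watertight is None:
            self.watertight = bool(self.to_trimesh().is_watertight)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)


# ---------------------------------------------------------------------------
# labeled volume IO

def read_labeled_volume(path, voxel_size=None, base_plane="z_min") -> LabeledVolume:
    """Read a labeled volume from multi-page TIFF or NRRD.

    The voxel size is taken from file metadata when present; the
    ``voxel_size`` argument overrides it. A missing voxel size without an
    override is an error — 1 µm is never silently assumed.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        labels, meta_vs = _read_tiff(path)
    elif suffix == ".nrrd":
        labels, meta_vs = _read_nrrd(path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise TypeError(
            f"{path.name}: labeled volumes must have integer pixel type, "
            f"got {labels.dtype}"
        )
    vs = tuple(voxel_size) if voxel_size is not None else meta_vs
    if vs is None:
        raise ValueError(
            f"{path.name}: no voxel size in file metadata and no override given"
        )
    return LabeledVolume(labels, vs, base_plane=base_plane)


def write_labeled_volume(volume: LabeledVolume, path) -> None:
    """Write to TIFF (voxel size in shaped-JSON metadata) or NRRD."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            volume.labels,
            metadata={"voxel_size_um": list(volume.voxel_size), "axes_order": "ZYX"},
        )
    elif suffix == ".nrrd":
        _write_nrrd(path, volume.labels, volume.voxel_size)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def _read_tiff(path):
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray()
        vs = None
        if tif.shaped_metadata:
            meta = tif.shaped_metadata[0]
            if "voxel_size_um" in meta:
                vs = tuple(float(v) for v in meta["voxel_size_um"])
        if vs is None and tif.imagej_metadata:
            # ImageJ: z spacing in metadata, x/y from resolution tags
            meta = tif.imagej_metadata
            dz = meta.get("spacing")
            page = tif.pages[0]
            try:
                xres = page.tags["XResolution"].value
                yres = page.tags["YResolution"].value
                dx = xres[1] / xres[0]
                dy = yres[1] / yres[0]
                if dz is not None:
                    vs = (float(dz), float(dy), float(dx))
            except KeyError:
                pass
    if labels.ndim == 2:
        labels = labels[None]
    return labels, vs


# Minimal NRRD support (attached header, raw/gzip encodings). The NRRD header
# lists sizes fastest-axis-first (x, y, z); the in-memory order is (z, y, x).

_NRRD_TYPES = {
    "uint8": np.uint8, "uint16": np.uint16, "uint32": np.uint32,
    "uint64": np.uint64, "int8": np.int8, "int16": np.int16,
    "int32": np.int32, "int64": np.int64, "float": np.float32,
    "double": np.float64,
    "unsigned char": np.uint8, "unsigned short": np.uint16,
    "unsigned int": np.uint32, "short": np.int16, "int": np.int32,
}


def _read_nrrd(path):
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        headers: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            headers[key.strip().lower()] = value.lstrip("=").strip()
        data = fh.read()
    dtype = _NRRD_TYPES.get(headers.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {headers.get('type')!r}")
    sizes = [int(s) for s in headers["sizes"].split()]
    encoding = headers.get("encoding", "raw")
    if encoding in ("gzip", "gz"):
        data = gzip.decompress(data)
    elif encoding in ("zlib",):
        data = zlib.decompress(data)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    endian = headers.get("endian", "little")
    dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
    arr = np.frombuffer(data, dtype=dt)[: int(np.prod(sizes))]
    # sizes are fastest-first (x, y, z) -> C-order shape is reversed
    arr = arr.reshape(sizes[::-1]).astype(dtype)
    vs = None
    if "space directions" in headers:
        dirs = [
            v for v in headers["space directions"].split(")") if v.strip(" (,")
        ]
        vecs = [
            [float(x) for x in v.strip(" (,").split(",")] for v in dirs
        ]
        # one vector per axis, fastest-first: (dx, dy, dz) diagonals
        spac = [float(np.linalg.norm(v)) for v in vecs]
        vs = (spac[2], spac[1], spac[0])
    elif "spacings" in headers:
        spac = [float(s) for s in headers["spacings"].split()]
        vs = (spac[2], spac[1], spac[0])
    return arr, vs


def _write_nrrd(path, labels, voxel_size):
    dz, dy, dx = voxel_size
    typename = {v: k for k, v in _NRRD_TYPES.items()}.get(labels.dtype.type)
    if typename is None:
        raise TypeError(f"cannot write dtype {labels.dtype} to NRRD")
    nz, ny, nx = labels.shape
    header = (
        "NRRD0004\n"
        f"type: {typename}\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {nx} {ny} {nz}\n"
        f"space directions: ({dx},0,0) (0,{dy},0) (0,0,{dz})\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: gzip\n"
        "\n"
    )
    payload = gzip.compress(np.ascontiguousarray(labels).astype(labels.dtype).tobytes())
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


# ---------------------------------------------------------------------------
# cell tables

LAYERS = ("L1", "L2", "L3", "L4")
CONTACT_CLASSES = (
    "central_L2", "central_L3", "contact1", "contact2", "contact_gt2", "other",
)

CELL_TABLE_COLUMNS = [
    "ovule_id", "cell_label", "layer", "contact_class",
    "volume_um3", "surface_area_um2",
    "semi_a_um", "semi_b_um", "semi_c_um",
    "norm_a", "norm_b", "norm_c",
    "sphericity", "prolate_ellipticity", "oblate_ellipticity",
    "anisotropy2",
    "apical_wall_um2", "basal_wall_um2", "stage",
]


def validate_cell_table(table: pd.DataFrame) -> None:
    """Raise ValueError naming offending columns on schema violations."""
    problems = []
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
    if not problems and len(table):
        bad_layer = ~table["layer"].isna() & ~table["layer"].isin(LAYERS)
        if bad_layer.any():
            problems.append("layer: values outside L1..L4")
        bad_cc = ~table["contact_class"].isna() & ~table["contact_class"].isin(
            CONTACT_CLASSES
        )
        if bad_cc.any():
            problems.append("contact_class: unknown class")
        abc = table[["semi_a_um", "semi_b_um", "semi_c_um"]].to_numpy(float)
        ok = np.isfinite(abc).all(axis=1)
        if np.any((abc[ok, 0] > abc[ok, 1] + 1e-12) | (abc[ok, 1] > abc[ok, 2] + 1e-12)):
            problems.append("semi_a_um/semi_b_um/semi_c_um: not sorted a <= b <= c")
        norms = table[["norm_a", "norm_b", "norm_c"]].to_numpy(float)
        okn = np.isfinite(norms).all(axis=1)
        if np.any(np.abs(norms[okn].sum(axis=1) - 1.0) > 1e-9):
            problems.append("norm_a/norm_b/norm_c: do not sum to 1")
    if problems:
        raise ValueError("cell table schema violation: " + "; ".join(problems))


def write_cell_table(table: pd.DataFrame, path) -> None:
    validate_cell_table(table)
    out = table.reindex(columns=CELL_TABLE_COLUMNS)
    out.to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_cell_table(table)
    return table


# ---------------------------------------------------------------------------
# mesh IO: OBJ (geometry only) and ASCII PLY (geometry + per-vertex scalar)

def export_mesh(mesh: SurfaceMesh, path, scalar_channel=None) -> None:
    """Write OBJ (geometry) or PLY (geometry plus per-vertex scalar)."""
    path = Path(path)
    scalar = scalar_channel if scalar_channel is not None else mesh.scalar
    if scalar is not None and len(scalar) != len(mesh.vertices):
        raise ValueError("scalar channel length must match vertex count")
    if path.suffix.lower() == ".obj":
        mesh.to_trimesh().export(path, file_type="obj")
    elif path.suffix.lower() == ".ply":
        _write_ply(path, mesh.vertices, mesh.triangles, scalar)
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")


def import_mesh(path) -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".obj":
        tm = trimesh.load(path, file_type="obj", process=False)
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if path.suffix.lower() == ".ply":
        verts, faces, scalar = _read_ply(path)
        return SurfaceMesh(verts, faces, scalar=scalar)
    raise ValueError(f"unsupported mesh format: {path.name}")


def _write_ply(path, vertices, triangles, scalar=None):
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vertices)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if scalar is not None:
            fh.write("property double quality\n")
        fh.write(f"element face {len(triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i, v in enumerate(vertices):
            line = f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}"
            if scalar is not None:
                line += f" {scalar[i]:.9g}"
            fh.write(line + "\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_ply(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    n_vert = n_face = 0
    has_scalar = False
    i = 0
    current = None
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
            current = "vertex"
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
            current = "face"
        elif parts[:1] == ["property"] and current == "vertex" and parts[-1] == "quality":
            has_scalar = True
        elif line.strip() == "end_header":
            break
    body = lines[i + 1:]
    vert_rows = np.array([[float(x) for x in body[j].split()] for j in range(n_vert)])
    vertices = vert_rows[:, :3]
    scalar = vert_rows[:, 3] if has_scalar else None
    faces = np.array(
        [[int(x) for x in body[n_vert + j].split()[1:4]] for j in range(n_face)],
        dtype=np.int64,
    ).reshape(n_face, 3)
    return vertices, faces, scalar


# ---------------------------------------------------------------------------
# configuration

@dataclass
class Config:
    """All pipeline tunables, one flat namespace; loadable from YAML.

    Unknown YAML keys are rejected so typos never silently fall back to a
    default. Every run logs the resolved configuration.
    """

    seed: int = 0
    # annotation
    min_contact_area: float = 1.0       # µm²; drop smaller contacts
    # division inference
    continuity_threshold: float = 160.0  # degrees; recent-division cutoff
    periclinal_max_angle: float = 30.0   # wall-normal vs radial, degrees
    anticlinal_min_angle: float = 60.0
    n_plane_directions: int = 500        # half-sphere grid for shortest wall
    plane_refine_passes: int = 2
    min_side_area: float = 4.0           # µm²; junction-angle side patches
    # morphometrics
    smoothing_iters: int = 10            # Taubin iterations on cell meshes
    # organ shape
    curvature_radius: float = 40.0       # µm neighborhood for curvature
    curvature_radius_small: float = 30.0
    small_ovule_diameter: float = 80.0   # µm; switch point for the radius
    # staging
    staging_k: int = 4
    elbow_k_max: int = 8

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def log(self) -> None:
        logger.info("resolved config: %s", self.to_dict())
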
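"""Two-level cell annotation: layers L1–L4 and radial contact classes.

Layers are derived from graph distance to the tissue exterior (L1 touches
the outside world); contact classes are graph distances to the central
subepidermal (L2) cell, the presumptive megaspore-mother-cell precursor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from primordium3d import _geometry as geom
from primordium3d.core_io import LabeledVolume

logger = logging.getLogger("primordium3d")

#: Virtual node representing everything outside the tissue (background and
#: volume boundary, excluding the base plane).
EXTERIOR = 0


@dataclass
class OvuleAnnotation:
    """Per-ovule annotation result."""

    central_L2: int
    central_L3: int | None
    layers: dict[int, str]
    contact_classes: dict[int, str]
    apical_axis: np.ndarray

    def __post_init__(self):
        if self.layers.get(self.central_L2) != "L2":
            raise ValueError("central_L2 must be an L2 cell")
        if self.central_L3 is not None and self.layers.get(self.central_L3) != "L3":
            raise ValueError("central_L3 must be an L3 cell")


def build_adjacency(volume: LabeledVolume, min_contact_area: float = 1.0) -> nx.Graph:
    """Cell-contact graph with per-edge interface areas.

    Edges connect labels sharing at least one voxel face (6-connectivity);
    edge attributes are ``area`` (µm², face count × face area) and ``faces``
    (voxel-face count). The virtual EXTERIOR node (0) collects contacts with
    background and the volume boundary, excluding the base_plane face. Edges
    with area below ``min_contact_area`` are dropped.
    """
    labels = volume.labels
    dz, dy, dx = volume.voxel_size
    face_area = {0: dy * dx, 1: dz * dx, 2: dz * dy}

    padded = np.pad(labels, 1, constant_values=0)
    if volume.base_plane is not None:
        ax, side = geom._parse_base_plane(volume.base_plane)
        outer = [slice(1, -1)] * 3
        outer[ax] = 0 if side == "min" else -1
        inner = [slice(None)] * 3
        inner[ax] = 0 if side == "min" else -1
        padded[tuple(outer)] = labels[tuple(inner)]  # not exterior there

    graph = nx.Graph()
    graph.add_node(EXTERIOR)
    for lab in volume.cell_labels():
        graph.add_node(int(lab))

    accum: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        a = padded[tuple(lo)].ravel()
        b = padded[tuple(hi)].ravel()
        diff = a != b
        fa = face_area[ax]
        pairs = np.stack([a[diff], b[diff]], axis=1)
        pairs.sort(axis=1)
        uniq, n = np.unique(pairs, axis=0, return_counts=True)
        for (la, lb), cnt in zip(uniq, n):
            key = (int(la), int(lb))
            accum[key] = accum.get(key, 0.0) + cnt * fa
            counts[key] = counts.get(key, 0) + int(cnt)

    for (la, lb), area in accum.items():
        if area >= min_contact_area:
            graph.add_edge(la, lb, area=float(area), faces=counts[(la, lb)])
    return graph


def assign_layers(graph: nx.Graph) -> dict[int, str]:
    """Layer per cell from graph distance to EXTERIOR.

    L1 = cells sharing an edge with EXTERIOR; L2/L3 peel inward; everything
    at distance > 3 is L4. Cells unreachable from the exterior get L4 with a
    warning.
    """
    if EXTERIOR not in graph:
        raise ValueError("graph lacks the EXTERIOR node")
    dist = nx.single_source_shortest_path_length(graph, EXTERIOR)
    layers: dict[int, str] = {}
    for node in graph.nodes:
        if node == EXTERIOR:
            continue
        d = dist.get(node)
        if d is None:
            logger.warning("cell %s unreachable from exterior; assigning L4", node)
            layers[node] = "L4"
        else:
            layers[node] = f"L{min(d, 4)}"
    return layers


def _apical_axis(volume: LabeledVolume) -> np.ndarray:
    """Dome axis: principal axis of the exterior-surface voxel cloud,
    oriented away from the base plane; falls back to the grid axis normal to
    the base plane when the cloud is near-isotropic in its top two
    eigenvalues (ratio < 1.2)."""
    centers_idx, _ = geom.exterior_faces(volume.labels, volume.base_plane)
    vs = np.asarray(volume.voxel_size)
    pts = (centers_idx + 0.5) * vs
    base_ax, side = geom._parse_base_plane(volume.base_plane or "z_min")
    up = np.zeros(3)
    up[base_ax] = 1.0 if side == "min" else -1.0
    if len(pts) < 10:
        return up
    w, v = geom.principal_axes(pts)
    if w[2] / max(w[1], 1e-12) < 1.2:
        axis = up
    else:
        axis = v[:, 2]
        if np.dot(axis, up) < 0:
            axis = -axis
    return geom.unit(axis)


def identify_central_L2(
    volume: LabeledVolume,
    layers: dict[int, str],
    apical_axis: np.ndarray | None = None,
) -> int:
    """The most apical central L2 cell.

    Returns the L2 cell whose centroid projects highest on the apical axis;
    near-ties (< 0.5 µm apart in height) are broken by distance to the axis
    line through the exterior-cloud centroid.
    """
    l2 = [lab for lab, lay in layers.items() if lay == "L2"]
    if not l2:
        raise ValueError("no L2 cell in volume")
    axis = geom.unit(apical_axis) if apical_axis is not None else _apical_axis(volume)
    centers_idx, _ = geom.exterior_faces(volume.labels, volume.base_plane)
    anchor = ((centers_idx + 0.5) * np.asarray(volume.voxel_size)).mean(axis=0)
    heights = {}
    radial = {}
    for lab in l2:
        c = volume.centroid(lab)
        rel = c - anchor
        h = float(np.dot(rel, axis))
        heights[lab] = h
        radial[lab] = float(np.linalg.norm(rel - h * axis))
    hmax = max(heights.values())
    contenders = [lab for lab in l2 if heights[lab] > hmax - 0.5]
    return min(contenders, key=lambda lab: radial[lab])


def assign_contact_degrees(graph: nx.Graph, central_label: int) -> dict[int, str]:
    """Contact class per cell: graph distance to the central L2 cell.

    contact1 = direct neighbors, contact2 = their neighbors, everything else
    contact_gt2. Classes cross-cut layers. The central cell itself is
    classed ``central_L2``.
    """
    if central_label not in graph:
        raise ValueError(f"central label {central_label} not in graph")
    sub = graph.subgraph([n for n in graph.nodes if n != EXTERIOR])
    dist = nx.single_source_shortest_path_length(sub, central_label, cutoff=2)
    classes: dict[int, str] = {}
    for node in sub.nodes:
        d = dist.get(node)
        if node == central_label:
            classes[node] = "central_L2"
        elif d == 1:
            classes[node] = "contact1"
        elif d == 2:
            classes[node] = "contact2"
        else:
            classes[node] = "contact_gt2"
    return classes


def select_central_L3(
    graph: nx.Graph,
    volume: LabeledVolume,
    central_L2: int,
    major_axis: np.ndarray,
    apical_axis: np.ndarray | None = None,
) -> int | None:
    """The L3 cell best aligned with the central L2 cell's major axis.

    Among L3 cells adjacent to the central L2 cell, returns the one whose
    offset direction (its centroid minus the central cell's centroid) makes
    the smallest angle with the basal-ward-oriented major ellipsoid axis;
    None when no adjacent L3 cell exists.
    """
    layers = assign_layers(graph)
    candidates = [
        n for n in graph.neighbors(central_L2)
        if n != EXTERIOR and layers.get(n) == "L3"
    ]
    if not candidates:
        return None
    axis = geom.unit(major_axis)
    up = geom.unit(apical_axis) if apical_axis is not None else _apical_axis(volume)
    if np.dot(axis, up) > 0:  # orient basal-ward
        axis = -axis
    c2 = volume.centroid(central_L2)
    best, best_angle = None, np.inf
    for lab in candidates:
        offset = volume.centroid(lab) - c2
        ang = geom.angle_between_deg(offset, axis)
        if ang < best_angle:
            best, best_angle = lab, ang
    return best


def annotate(
    volume: LabeledVolume,
    min_contact_area: float = 1.0,
    central_major_axis: np.ndarray | None = None,
) -> tuple[nx.Graph, OvuleAnnotation]:
    """Full annotation: adjacency, layers, central cells, contact classes.

    ``central_major_axis`` (the fitted major axis of the central L2 cell)
    steers central-L3 selection; when omitted it is computed from the
    second-moment ellipsoid of the central L2 cell.
    """
    graph = build_adjacency(volume, min_contact_area=min_contact_area)
    layers = assign_layers(graph)
    axis = _apical_axis(volume)
    central = identify_central_L2(volume, layers, apical_axis=axis)
    if central_major_axis is None:
        from primordium3d.morphometrics import fit_ellipsoid
        central_major_axis = fit_ellipsoid(volume, central).axes[:, 2]
    central3 = select_central_L3(graph, volume, central, central_major_axis,
                                 apical_axis=axis)
    classes = assign_contact_degrees(graph, central)
    if central3 is not None:
        classes[central3] = "central_L3"
    ann = OvuleAnnotation(
        central_L2=central,
        central_L3=central3,
        layers=layers,
        contact_classes=classes,
        apical_axis=axis,
    )
    return graph, ann
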
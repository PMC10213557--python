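"""Interface extraction, apical/basal walls, junction continuity angles."""

import numpy as np
import pytest

from primordium3d.annotation import annotate, build_adjacency
from primordium3d.core_io import LabeledVolume
from primordium3d.walls import (
    apical_basal_walls,
    cell_surface_area,
    interface_area,
    interface_mesh,
    junction_wall_angle,
)
from primordium3d import _geometry as geom
from tests.conftest import stacked_boxes


def test_stacked_cubes_interface():
    vol = stacked_boxes(20)
    iface = interface_mesh(vol, 1, 2)
    assert iface.area == pytest.approx(400.0, rel=0.10)
    assert geom.angle_between_deg(iface.plane_normal, [1, 0, 0]) \
        in (pytest.approx(0, abs=3), pytest.approx(180, abs=3))
    assert iface.planarity_rms < 0.5


def test_interface_symmetry():
    vol = stacked_boxes(12)
    assert interface_area(vol, 1, 2) == pytest.approx(
        interface_area(vol, 2, 1))


def test_curved_interface_flags_nonplanarity():
    # hemispherical cap interface between two labels
    n = 40
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = n / 2
    ball = (zz + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 + (xx + 0.5 - c) ** 2 \
        <= 15**2
    arr = np.zeros((n, n, n), np.uint16)
    arr[ball] = 1
    inner = (zz + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 + (xx + 0.5 - c) ** 2 \
        <= 10**2
    arr[inner] = 2  # label 2 = inner ball, interface = sphere of r=10
    vol = LabeledVolume(arr, (1, 1, 1), base_plane=None)
    curved = interface_mesh(vol, 1, 2)
    flat = interface_mesh(stacked_boxes(20), 1, 2)
    assert curved.planarity_rms > 5 * flat.planarity_rms


def test_non_adjacent_interface_errors():
    arr = np.zeros((10, 6, 6), np.uint16)
    arr[1:3, 1:5, 1:5] = 1
    arr[6:8, 1:5, 1:5] = 2
    vol = LabeledVolume(arr, (1, 1, 1), base_plane=None)
    with pytest.raises(ValueError):
        interface_mesh(vol, 1, 2)


def test_apical_wall_sums_l1_contacts():
    # central cell 4 capped by three L1 cells with known contact areas
    arr = np.zeros((12, 14, 26), np.uint16)
    arr[0:4, 2:12, 2:24] = 4                  # central cell on the base
    arr[4:8, 2:12, 2:12] = 1                  # L1 cap A: 10x10 contact
    arr[4:8, 2:12, 12:17] = 2                 # L1 cap B: 10x5
    arr[4:8, 2:12, 17:20] = 3                 # L1 cap C: 10x3
    arr[0:4, 2:12, 24:26] = 5                 # lateral seal (not L1 in test)
    vol = LabeledVolume(arr, (1, 1, 1), base_plane="z_min")

    class Ann:
        central_L2 = 4
        central_L3 = None
        layers = {1: "L1", 2: "L1", 3: "L1", 4: "L2", 5: "L2"}
    apical, basal, ratio = apical_basal_walls(vol, Ann())
    assert apical == pytest.approx(100 + 50 + 30, rel=0.02)
    assert basal is None and ratio is None


def test_trapezoid_apical_basal_ratio():
    # frustum-like central cell: apical face 14x14, basal face 10x10 via a
    # stepped profile; ratio close to the constructed 1.96
    arr = np.zeros((16, 24, 24), np.uint16)
    arr[2:5, 7:17, 7:17] = 4       # basal tier 10x10
    arr[5:8, 5:19, 5:19] = 4       # apical tier 14x14
    arr[8:11, 3:21, 3:21] = 1      # L1 cap
    arr[0:2, 7:17, 7:17] = 3       # central L3 below
    vol = LabeledVolume(arr, (1, 1, 1), base_plane=None)

    class Ann:
        central_L2 = 4
        central_L3 = 3
        layers = {1: "L1", 4: "L2", 3: "L3"}
    apical, basal, ratio = apical_basal_walls(vol, Ann())
    assert ratio == pytest.approx((14 * 14) / (10 * 10), rel=0.15)


def test_surface_area_additivity(coarse_dome):
    vol, gt = coarse_dome
    graph, ann = annotate(vol)
    lab = ann.central_L2
    total = cell_surface_area(vol, lab)
    parts = sum(interface_area(vol, lab, int(nb))
                for nb in graph.neighbors(lab))
    assert parts == pytest.approx(total, rel=0.05)


def test_coplanar_stacked_boxes_angle():
    vol = stacked_boxes(20)
    graph = build_adjacency(vol)
    records, mean_angle = junction_wall_angle(vol, graph, 1, 2)
    assert mean_angle >= 178.0
    assert all(0 < r.angle_deg <= 180 for r in records)


def test_offset_monotonically_bends_the_junction():
    means, mins = [], []
    for off_pct in (10, 20, 30):
        vol = stacked_boxes(20, offset=int(20 * off_pct / 100))
        graph = build_adjacency(vol)
        records, mean_angle = junction_wall_angle(vol, graph, 1, 2)
        means.append(mean_angle)
        mins.append(min(r.angle_deg for r in records))
    # the mean dilutes the step with the two still-coplanar flanks; both it
    # and the stepped walls themselves must fall monotonically
    assert means[0] > means[1] > means[2]
    assert mins[0] > mins[1] > mins[2]
    assert mins[2] < 165.0


def test_single_side_configuration():
    # seal all but one side so exactly one side context qualifies
    arr = np.zeros((24, 16, 16), np.uint16)
    arr[2:10, 2:10, 2:10] = 1
    arr[10:18, 2:10, 2:10] = 2
    arr[2:18, 10:14, 2:10] = 3   # the single shared lateral neighbor
    vol = LabeledVolume(arr, (1, 1, 1), base_plane=None)
    graph = build_adjacency(vol)
    records, mean_angle = junction_wall_angle(vol, graph, 1, 2,
                                              allowed_sides=[3])
    assert len(records) == 1
    assert mean_angle == pytest.approx(records[0].angle_deg)


def test_junction_angle_undefined_raises():
    # two isolated stacked boxes with no lateral side context
    arr = np.zeros((24, 10, 10), np.uint16)
    arr[2:10, 2:8, 2:8] = 1
    arr[10:18, 2:8, 2:8] = 2
    vol = LabeledVolume(arr, (1, 1, 1), base_plane=None)
    graph = build_adjacency(vol)
    with pytest.raises(ValueError, match="side context"):
        junction_wall_angle(vol, graph, 1, 2, allowed_sides=[])


def test_junction_angle_rotation_invariance():
    from scipy import ndimage
    vol = stacked_boxes(16, offset=4)
    graph = build_adjacency(vol)
    _, a0 = junction_wall_angle(vol, graph, 1, 2)
    rotated = LabeledVolume(np.rot90(vol.labels, axes=(0, 2)).copy(),
                            vol.voxel_size, base_plane=None)
    graph_r = build_adjacency(rotated)
    _, a1 = junction_wall_angle(rotated, graph_r, 1, 2)
    assert abs(a0 - a1) < 2.0
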
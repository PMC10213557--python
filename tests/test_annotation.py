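"""Layer assignment, contact degrees and central-cell identification."""

import networkx as nx
import numpy as np
import pytest

from primordium3d.annotation import (
    EXTERIOR,
    annotate,
    assign_contact_degrees,
    assign_layers,
    build_adjacency,
    identify_central_L2,
)
from primordium3d.core_io import LabeledVolume


def _stacked_cubes(side=20):
    arr = np.zeros((2 * side + 4, side + 4, side + 4), np.uint16)
    arr[2:2 + side, 2:2 + side, 2:2 + side] = 1
    arr[2 + side:2 + 2 * side, 2:2 + side, 2:2 + side] = 2
    return LabeledVolume(arr, (1.0, 1.0, 1.0), base_plane=None)


def test_stacked_cubes_contact_area_exact():
    graph = build_adjacency(_stacked_cubes(20))
    assert graph[1][2]["area"] == pytest.approx(400.0)
    assert graph[1][2]["faces"] == 400


def test_min_contact_area_threshold():
    arr = np.zeros((6, 6, 6), np.uint16)
    arr[1:3, 1:3, 1:3] = 1
    arr[3, 1, 1] = 2  # single shared voxel face
    vol = LabeledVolume(arr, (1, 1, 1), base_plane=None)
    assert build_adjacency(vol, min_contact_area=0.5).has_edge(1, 2)
    assert not build_adjacency(vol, min_contact_area=2.0).has_edge(1, 2)


def test_adjacency_symmetry():
    vol = _stacked_cubes(8)
    graph = build_adjacency(vol)
    for a, b, data in graph.edges(data=True):
        assert graph[b][a]["area"] == data["area"]


def test_onion_shells_layered_outside_in():
    # concentric boxes: outer shell exposed, then successive inner shells
    arr = np.zeros((16, 16, 16), np.uint16)
    arr[2:14, 2:14, 2:14] = 1
    arr[4:12, 4:12, 4:12] = 2
    arr[6:10, 6:10, 6:10] = 3
    vol = LabeledVolume(arr, (1, 1, 1), base_plane=None)
    layers = assign_layers(build_adjacency(vol))
    assert layers == {1: "L1", 2: "L2", 3: "L3"}


def test_base_plane_contact_is_not_exterior():
    # cell 1 sees only the base face, a sealing ring and the cell above
    arr2 = np.zeros((6, 8, 8), np.uint16)
    arr2[0:2, 2:6, 2:6] = 1
    arr2[0:2, 1, 1:7] = 3
    arr2[0:2, 6, 1:7] = 3
    arr2[0:2, 1:7, 1] = 3
    arr2[0:2, 1:7, 6] = 3
    arr2[2:4, 1:7, 1:7] = 2
    vol2 = LabeledVolume(arr2, (1, 1, 1), base_plane="z_min")
    layers = assign_layers(build_adjacency(vol2))
    assert layers[1] != "L1"  # only base-plane and cell contacts
    assert layers[2] == "L1"


def test_contact_degrees_chain():
    graph = nx.Graph()
    graph.add_node(EXTERIOR)
    graph.add_edges_from([("A", "B"), ("B", "C"), ("C", "D")])
    classes = assign_contact_degrees(graph, "A")
    assert classes == {"A": "central_L2", "B": "contact1",
                       "C": "contact2", "D": "contact_gt2"}


def test_central_cell_tie_break_on_axis():
    # three same-height L2 cells under a sealed L1 shell; the tie is broken
    # by distance to the apical axis line
    arr = np.zeros((8, 14, 20), np.uint16)
    arr[0:8, 0:14, 0:20] = 1          # shell
    arr[0:5, 2:12, 2:6] = 3           # off-axis L2
    arr[0:5, 2:12, 6:14] = 2          # on-axis L2 (centered in x)
    arr[0:5, 2:12, 14:18] = 4         # off-axis L2
    vol = LabeledVolume(arr, (1, 1, 1), base_plane="z_min")
    layers = assign_layers(build_adjacency(vol))
    assert layers[2] == layers[3] == layers[4] == "L2"
    picked = identify_central_L2(vol, layers, apical_axis=np.array([1.0, 0, 0]))
    assert picked == 2


def test_layer_and_contact_maps_are_partitions(coarse_dome):
    vol, gt = coarse_dome
    graph, ann = annotate(vol)
    cells = set(int(l) for l in vol.cell_labels())
    assert set(ann.layers) == cells
    assert set(ann.contact_classes) == cells


def test_label_permutation_equivariance(coarse_dome):
    vol, gt = coarse_dome
    _, ann = annotate(vol)
    rng = np.random.default_rng(3)
    labels = vol.cell_labels()
    perm = dict(zip(labels, rng.permutation(labels)))
    relabeled = np.zeros_like(vol.labels)
    for old, new in perm.items():
        relabeled[vol.labels == old] = new
    vol2 = LabeledVolume(relabeled, vol.voxel_size, vol.base_plane)
    _, ann2 = annotate(vol2)
    assert ann2.central_L2 == perm[ann.central_L2]
    for lab in labels:
        assert ann2.layers[perm[lab]] == ann.layers[lab]


def test_dome_ground_truth_recovery(coarse_dome):
    vol, gt = coarse_dome
    graph, ann = annotate(vol)
    truth_layers = dict(zip(gt.cells.cell_label, gt.cells.layer))
    layer_hits = np.mean([ann.layers.get(l) == truth_layers[l]
                          for l in truth_layers])
    assert layer_hits >= 0.95
    assert ann.central_L2 == gt.central_L2
    truth_cc = dict(zip(gt.cells.cell_label, gt.cells.contact_class))
    cc_hits = np.mean([
        ann.contact_classes.get(l) == truth_cc[l]
        for l in truth_cc if truth_cc[l] != "central_L2"
    ])
    assert cc_hits >= 0.95


def test_contact_degrees_match_bfs_distance(coarse_dome):
    vol, gt = coarse_dome
    graph, ann = annotate(vol)
    sub = graph.subgraph([n for n in graph if n != EXTERIOR])
    dist = nx.single_source_shortest_path_length(sub, ann.central_L2)
    for lab, cls in ann.contact_classes.items():
        if cls in ("central_L2", "central_L3"):
            continue
        d = dist.get(lab, 99)
        expected = {1: "contact1", 2: "contact2"}.get(d, "contact_gt2")
        assert cls == expected
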
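"""Whole-organ shape: bounding box, aspect ratio, dome curvature, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from primordium3d.core_io import CELL_TABLE_COLUMNS, LabeledVolume
from primordium3d.organ import (
    OvuleShape,
    correlate_cell_organ_shape,
    curvature_map,
    measure_ovule_shape,
    oriented_bounding_box,
    ovule_mesh,
)
from primordium3d.synthetic import generate_dome_tessellation
from tests.conftest import digital_ball


def _hemisphere(radius=20.0, voxel=0.5):
    n = int(2 * radius / voxel) + 8
    nz = int(radius / voxel) + 4
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(n), np.arange(n),
                             indexing="ij")
    c = n / 2
    mask = ((zz + 0.5) * voxel) ** 2 + ((yy + 0.5 - c) * voxel) ** 2 \
        + ((xx + 0.5 - c) * voxel) ** 2 <= radius**2
    return LabeledVolume(mask.astype(np.uint16), (voxel,) * 3,
                         base_plane="z_min")


def test_hemisphere_aspect_ratio():
    lengths, _ = oriented_bounding_box(_hemisphere())
    aspect = lengths[0] / lengths.sum()
    assert aspect == pytest.approx(0.2, abs=0.01)


def test_sphere_aspect_is_one_third():
    lengths, _ = oriented_bounding_box(digital_ball(16))
    assert lengths[0] / lengths.sum() == pytest.approx(1 / 3, abs=0.01)


def test_rotated_box_lengths():
    rot = Rotation.from_euler("zyx", [30, 20, 10], degrees=True).as_matrix()
    g = 64
    zz, yy, xx = np.meshgrid(*[np.arange(g)] * 3, indexing="ij")
    pts = np.stack([zz + 0.5 - g / 2, yy + 0.5 - g / 2, xx + 0.5 - g / 2],
                   -1) @ rot
    arr = ((np.abs(pts[..., 0]) <= 5) & (np.abs(pts[..., 1]) <= 10)
           & (np.abs(pts[..., 2]) <= 20)).astype(np.uint16)
    vol = LabeledVolume(arr, (1, 1, 1), base_plane=None)
    lengths, _ = oriented_bounding_box(vol)
    np.testing.assert_allclose(lengths, [10, 20, 40], rtol=0.05)


def test_hemisphere_mesh_watertight_and_area():
    mesh, base_flags = ovule_mesh(_hemisphere(radius=20.0, voxel=1.0))
    assert mesh.watertight
    r = 20.0
    assert mesh.area == pytest.approx(2 * np.pi * r**2 + np.pi * r**2,
                                      rel=0.10)
    assert base_flags.any() and not base_flags.all()


def test_sphere_curvature_map():
    mesh, flags = ovule_mesh(digital_ball(25))
    curv, used = curvature_map(mesh, exclude=flags)
    ok = np.isfinite(curv)
    assert np.nanmean(curv[ok]) == pytest.approx(1 / 25, rel=0.05)


def test_plane_patch_zero_curvature():
    slab = np.zeros((12, 60, 60), np.uint16)
    slab[:6, 2:58, 2:58] = 1
    vol = LabeledVolume(slab, (1, 1, 1), base_plane="z_min")
    mesh, _ = ovule_mesh(vol)
    v = mesh.vertices
    top = (np.abs(v[:, 0] - 6) < 1.2) & (v[:, 1] > 15) & (v[:, 1] < 45) \
        & (v[:, 2] > 15) & (v[:, 2] < 45)
    curv, _ = curvature_map(mesh, exclude=~top)
    assert np.nanmax(np.abs(curv)) < 0.002


def test_pointed_dome_has_higher_apex_curvature():
    apex = {}
    for squareness in (2.0, 6.0):
        vol, _ = generate_dome_tessellation(
            H=30, Rx=18, Ry=18, n=squareness,
            layer_thicknesses=(5.0, 8.0, 7.0), voxel_size=(1.0, 1.0, 1.0),
            rng_seed=2)
        shape = measure_ovule_shape(vol, ovule_id=f"n{squareness}")
        apex[squareness] = shape.apex_curvature
    assert apex[2.0] > apex[6.0]


def _fake_table_and_shapes(norm_c, aspects):
    rows = []
    shapes = []
    for i, (nc, asp) in enumerate(zip(norm_c, aspects)):
        row = {c: np.nan for c in CELL_TABLE_COLUMNS}
        row.update(ovule_id=f"ov{i}", cell_label=1,
                   contact_class="central_L2", norm_c=nc)
        rows.append(row)
        shapes.append(OvuleShape(
            ovule_id=f"ov{i}", box_lengths=np.array([asp, 1.0, 1.0]),
            box_axes=np.eye(3), aspect_ratio=asp / (asp + 2.0)))
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS), shapes


def test_coupled_anisotropy_gives_high_rank_correlation():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.35, 0.6, 20)
    table, shapes = _fake_table_and_shapes(
        base + rng.normal(0, 0.01, 20), base)
    pairs, rho, p = correlate_cell_organ_shape(table, shapes, seed=0)
    assert rho > 0.8
    assert p < 0.01


def test_independent_draws_give_low_correlation():
    rng = np.random.default_rng(1)
    table, shapes = _fake_table_and_shapes(
        rng.uniform(0.35, 0.6, 40), rng.uniform(0.3, 0.6, 40))
    _, rho, _ = correlate_cell_organ_shape(table, shapes, seed=0)
    assert abs(rho) < 0.3


def test_permutation_p_matches_exact_enumeration_n5():
    import itertools

    from scipy import stats as sps
    rng = np.random.default_rng(2)
    x = rng.uniform(size=5)
    y = rng.uniform(size=5)
    table, shapes = _fake_table_and_shapes(x, y)
    _, rho, p = correlate_cell_organ_shape(table, shapes, seed=0)
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    obs = abs(np.corrcoef(xr, sps.rankdata([s.aspect_ratio for s in shapes]))[0, 1])
    count = total = 0
    for perm in itertools.permutations(range(5)):
        total += 1
        if abs(np.corrcoef(xr, yr[list(perm)])[0, 1]) >= obs - 1e-12:
            count += 1
    assert p == pytest.approx(count / total)


def test_too_few_ovules_errors():
    table, shapes = _fake_table_and_shapes([0.4, 0.5], [0.2, 0.25])
    with pytest.raises(ValueError):
        correlate_cell_organ_shape(table, shapes)
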
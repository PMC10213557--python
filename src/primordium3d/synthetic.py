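"""Synthetic labeled ovule domes with known ground truth.

The generator emulates the geometry the analysis modules consume: a
dome-shaped primordium (superellipsoid cap of ~30–60 µm diameter),
tessellated into concentric cell layers (L1 outermost), with one central
subepidermal (L2) cell on the dome axis whose volume is controlled, and
optionally planted divisions (periclinal / anticlinal / oblique) whose
plane normal, volume split and wall jitter are recorded so inference can
be scored against truth.

Cells are built by additively-weighted nearest-seed (power-diagram-like)
assignment on the voxel grid, restricted per layer; this is label-image
native and guarantees every foreground voxel belongs to exactly one cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from primordium3d import _geometry as geom
from primordium3d.core_io import LabeledVolume

logger = logging.getLogger("primordium3d")

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class GroundTruth:
    """Planted truth for one synthetic ovule.

    ``cells`` has one row per label: true layer, true contact class,
    divided flag, division orientation, planted plane normal, volume-offset
    fraction f and wall-jitter magnitude (µm). Per-ovule fields hold the
    stage index, dome geometry and the identities of the central cells.
    """

    cells: pd.DataFrame
    stage: int = 1
    dome_height: float = 0.0          # H, µm
    dome_radii: tuple = (0.0, 0.0)    # (Rx, Ry), µm
    squareness: float = 2.0           # superellipsoid exponent n
    central_L2: int | None = None
    central_L3: int | None = None     # basal daughter after planted division
    ovule_id: str = "ovule"

    @property
    def ovule_type(self) -> str:
        """Type2 iff the central cell carries a recent (jitter-free)
        periclinal division; Type1 otherwise."""
        if self.central_L3 is None:
            return "Type1"
        row = self.cells.loc[self.cells["cell_label"] == self.central_L3]
        if not len(row) or not bool(row["divided"].iloc[0]):
            return "Type1"
        return "Type2" if float(row["jitter_um"].iloc[0]) == 0.0 else "Type1"

    def __post_init__(self):
        if not 0 <= self.stage <= 4:
            raise ValueError("stage must be in 0..4")
        normals = self.cells[["normal_z", "normal_y", "normal_x"]].to_numpy(float)
        ok = np.isfinite(normals).all(axis=1)
        lens = np.linalg.norm(normals[ok], axis=1)
        if np.any(np.abs(lens - 1.0) > 1e-9):
            raise ValueError("planted plane normals must be unit length")
        f = self.cells["f"].to_numpy(float)
        okf = np.isfinite(f)
        if np.any((f[okf] <= 0) | (f[okf] >= 1)):
            raise ValueError("volume-offset fraction f must lie in (0, 1)")


_TRUTH_COLUMNS = [
    "cell_label", "layer", "contact_class", "divided", "orientation",
    "normal_z", "normal_y", "normal_x", "f", "jitter_um", "sibling",
]


def _empty_truth_row(label, layer):
    return {
        "cell_label": int(label), "layer": layer, "contact_class": "other",
        "divided": False, "orientation": None,
        "normal_z": np.nan, "normal_y": np.nan, "normal_x": np.nan,
        "f": np.nan, "jitter_um": np.nan, "sibling": -1,
    }


def generate_dome_tessellation(
    H: float,
    Rx: float,
    Ry: float,
    n: float = 2.0,
    layer_thicknesses=(5.0, 6.0, 6.0),
    seeds_per_layer=(24, 12, 8, 5),
    central_L2_target_volume: float | None = None,
    voxel_size=(1.0, 1.0, 1.0),
    rng_seed: int = 0,
    stage: int = 1,
    ovule_id: str = "ovule",
) -> tuple[LabeledVolume, GroundTruth]:
    """Voxelized dome { (x/Rx)² + (y/Ry)² + (z/H)^n ≤ 1, z ≥ 0 }, tessellated.

    The dome interior is peeled into layers by depth from the free surface
    (the base plane at z = 0 is tissue continuation, not surface):
    ``layer_thicknesses`` gives the L1..L3 shell thicknesses in µm and the
    remaining core is L4. Each layer is partitioned among
    ``seeds_per_layer`` seeds by weighted nearest-seed assignment; exactly
    one L2 seed sits on the dome axis near the apex, and when
    ``central_L2_target_volume`` is given its weight is tuned by bisection
    until the resulting cell volume is within 15% of the target (an
    infeasible target raises, reporting the attained volume).
    """
    if H <= 0 or Rx <= 0 or Ry <= 0:
        raise ValueError("dome dimensions must be positive")
    if sum(layer_thicknesses) >= H:
        raise ValueError("layer thicknesses must sum to less than the dome height")
    rng = np.random.default_rng(rng_seed)
    vs = np.asarray(voxel_size, dtype=float)
    dz, dy, dx = vs
    pad = 2
    nz = int(np.ceil(H / dz)) + pad
    ny = int(np.ceil(2 * Ry / dy)) + 2 * pad
    nx = int(np.ceil(2 * Rx / dx)) + 2 * pad
    zc = (np.arange(nz) + 0.5) * dz
    yc = (np.arange(ny) + 0.5) * dy - (ny * dy) / 2
    xc = (np.arange(nx) + 0.5) * dx - (nx * dx) / 2
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    inside = (X / Rx) ** 2 + (Y / Ry) ** 2 + (Z / H) ** n <= 1.0

    # depth from the free surface; mirror-pad below the base plane so the
    # base face does not count as surface
    mirrored = np.concatenate([inside[:pad][::-1], inside], axis=0)
    depth = ndimage.distance_transform_edt(mirrored, sampling=vs)[pad:]

    cum = np.concatenate([[0.0], np.cumsum(layer_thicknesses), [np.inf]])
    n_layers = len(layer_thicknesses) + 1
    if len(seeds_per_layer) != n_layers:
        raise ValueError(
            f"seeds_per_layer must have {n_layers} entries "
            "(one per thickness plus the L4 core)"
        )
    layer_idx = np.full(inside.shape, -1, dtype=int)
    for li in range(n_layers):
        sel = inside & (depth > cum[li]) & (depth <= cum[li + 1])
        layer_idx[sel] = li
    # deep voxels left unassigned when a thin dome lacks a core: push to last
    leftover = inside & (layer_idx == -1)
    layer_idx[leftover] = n_layers - 1

    labels = np.zeros(inside.shape, dtype=np.uint16)
    rows = []
    next_label = 1
    central_label = None
    coords = np.stack([Z, Y, X], axis=-1)
    for li in range(n_layers):
        sel = layer_idx == li
        if not sel.any():
            continue
        pts = coords[sel]
        mid = 0.5 * (cum[li] + min(cum[li + 1], depth[sel].max()))
        band = sel & (np.abs(depth - mid) <= max(0.25 * (cum[li + 1] - cum[li]
                      if np.isfinite(cum[li + 1]) else 4.0), dz))
        cand = coords[band] if band.any() else pts
        k = int(seeds_per_layer[li])
        if k < 1 or len(cand) == 0:
            continue
        seeds, central_seed_idx = _place_seeds(cand, k, rng,
                                               on_axis_first=(li == 1))
        d2 = np.sum((pts[:, None, :] - seeds[None, :, :]) ** 2, axis=2)
        weights = np.zeros(len(seeds))
        if li == 1 and central_L2_target_volume is not None:
            weights[central_seed_idx] = _tune_central_weight(
                d2, central_seed_idx, central_L2_target_volume,
                float(np.prod(vs)),
            )
        assign = np.argmin(d2 - weights[None, :], axis=1)
        lab_values = next_label + assign
        flat = np.zeros(inside.shape, dtype=np.int64)
        flat[sel] = lab_values
        labels[sel] = flat[sel]
        for s in range(len(seeds)):
            rows.append(_empty_truth_row(next_label + s, f"L{li + 1}"))
        if li == 1:
            central_label = next_label + central_seed_idx
        next_label += len(seeds)

    labels = _relabel_connected(labels)
    volume = LabeledVolume(labels, tuple(vs), base_plane="z_min")
    truth = pd.DataFrame(
        [r for r in rows if (labels == r["cell_label"]).any()],
        columns=_TRUTH_COLUMNS,
    )
    gt = GroundTruth(
        cells=truth.reset_index(drop=True), stage=stage, dome_height=H,
        dome_radii=(Rx, Ry), squareness=n, central_L2=int(central_label)
        if central_label is not None else None, ovule_id=ovule_id,
    )
    _fill_truth_contacts(volume, gt)
    if central_L2_target_volume is not None and central_label is not None:
        attained = float((labels == central_label).sum()) * float(np.prod(vs))
        if abs(attained - central_L2_target_volume) > 0.15 * central_L2_target_volume:
            raise ValueError(
                f"central L2 target volume {central_L2_target_volume:.0f} µm³ "
                f"infeasible for this dome; attained {attained:.0f} µm³"
            )
    return volume, gt


def _place_seeds(candidates, k, rng, on_axis_first=False):
    """Farthest-point seed placement; optionally force the first seed onto
    the dome axis (x = y = 0) at the most apical candidate."""
    cand = np.asarray(candidates)
    if on_axis_first:
        lateral = cand[:, 1] ** 2 + cand[:, 2] ** 2
        near_axis = lateral <= np.quantile(lateral, 0.05) + 1e-9
        first = np.argmax(np.where(near_axis, cand[:, 0], -np.inf))
    else:
        first = int(rng.integers(len(cand)))
    chosen = [first]
    d2 = np.sum((cand - cand[first]) ** 2, axis=1)
    for _ in range(1, min(k, len(cand))):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((cand - cand[nxt]) ** 2, axis=1))
    seeds = cand[chosen]
    central_idx = 0 if on_axis_first else None
    return seeds, central_idx


def _tune_central_weight(d2, central_idx, target_volume, voxel_volume,
                         max_iters: int = 30):
    """Bisection on the central seed's additive weight so its cell volume
    approaches the target. Monotone: larger weight, larger cell."""
    target_count = target_volume / voxel_volume

    def count(w):
        eff = d2.copy()
        eff[:, central_idx] -= w
        return np.sum(np.argmin(eff, axis=1) == central_idx)

    span = float(d2.max())
    lo, hi = -span, span
    if count(hi) < target_count:
        return hi  # everything the layer allows; feasibility checked later
    if count(lo) > target_count:
        return lo
    for _ in range(max_iters):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_count:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _relabel_connected(labels):
    """Keep each label's largest 6-connected component; reassign stray
    fragments to the neighboring label with the most shared faces."""
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        comp, n_comp = ndimage.label(labels == lab, structure=_FACE_STRUCT)
        if n_comp <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   index=np.arange(1, n_comp + 1))
        keep = 1 + int(np.argmax(sizes))
        for c in range(1, n_comp + 1):
            if c == keep:
                continue
            frag = comp == c
            dil = ndimage.binary_dilation(frag, structure=_FACE_STRUCT)
            nbrs = out[dil & ~frag]
            nbrs = nbrs[(nbrs != lab) & (nbrs != 0)]
            if len(nbrs):
                vals, cnts = np.unique(nbrs, return_counts=True)
                out[frag] = vals[np.argmax(cnts)]
    return out


def _fill_truth_contacts(volume: LabeledVolume, gt: GroundTruth) -> None:
    """True contact classes by breadth-first distance from the central cell
    on the face-adjacency relation (the class definition itself)."""
    if gt.central_L2 is None:
        return
    adj = _face_adjacency(volume.labels)
    dist = {gt.central_L2: 0}
    frontier = [gt.central_L2]
    while frontier:
        nxt = []
        for lab in frontier:
            for nb in adj.get(lab, ()):  # noqa: B905
                if nb not in dist:
                    dist[nb] = dist[lab] + 1
                    nxt.append(nb)
        frontier = nxt
    def cls(lab):
        d = dist.get(lab)
        if lab == gt.central_L2:
            return "central_L2"
        if d == 1:
            return "contact1"
        if d == 2:
            return "contact2"
        return "contact_gt2"
    gt.cells["contact_class"] = [cls(l) for l in gt.cells["cell_label"]]


def _face_adjacency(labels):
    adj: dict[int, set] = {}
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        a = labels[tuple(lo)].ravel()
        b = labels[tuple(hi)].ravel()
        sel = (a != b) & (a > 0) & (b > 0)
        for la, lb in {(int(x), int(y)) for x, y in zip(a[sel], b[sel])}:
            adj.setdefault(la, set()).add(lb)
            adj.setdefault(lb, set()).add(la)
    return adj


def plant_division(
    volume: LabeledVolume,
    truth: GroundTruth,
    cell_label: int,
    orientation: str = "periclinal",
    f: float = 0.5,
    jitter: float = 0.0,
    rng_seed: int = 0,
    split_by: str = "extent",
) -> tuple[LabeledVolume, GroundTruth]:
    """Split one cell by a plane, emulating a recent (or older) division.

    The plane passes through the point dividing the cell's extent along the
    division normal at fraction ``f`` (with ``split_by="volume"``, the
    point below which fraction f of the cell volume lies — useful when a
    target daughter volume ratio matters more than the cut position);
    periclinal planes have their normal along the local radial
    (surface-normal) direction, anticlinal normals are perpendicular to
    it, oblique at 45°. ``jitter`` > 0 displaces each
    daughter's free (non-shared) walls by independent smooth random fields
    of that amplitude, emulating the wall deformation accumulated by
    independent daughter growth after an older division; jitter = 0 leaves
    the daughters' free walls geometrically continuous.

    The apical daughter keeps the original label; the basal daughter gets a
    fresh label. Daughters smaller than 27 voxels are an error.
    """
    rng = np.random.default_rng(rng_seed)
    labels = volume.labels.copy()
    mask = labels == cell_label
    if not mask.any():
        raise KeyError(f"cell {cell_label} not in volume")
    if ndimage.label(mask, structure=_FACE_STRUCT)[1] != 1:
        raise ValueError(f"cell {cell_label} is not 6-connected")
    vs = np.asarray(volume.voxel_size)
    pts = geom.voxel_centers(mask, vs)
    centroid = pts.mean(axis=0)
    radial = geom.local_radial_direction(labels, vs, centroid,
                                         volume.base_plane)
    normal = _division_normal(orientation, radial, rng)

    d = (pts - centroid) @ normal
    if split_by == "volume":
        cut = np.quantile(d, f)
    elif split_by == "extent":
        cut = d.min() + f * (d.max() - d.min())
    else:
        raise ValueError("split_by must be 'extent' or 'volume'")
    apical_side = d >= cut
    n_ap, n_ba = int(apical_side.sum()), int((~apical_side).sum())
    if min(n_ap, n_ba) < 27:
        raise ValueError(
            f"split at f={f} produces a degenerate daughter "
            f"({min(n_ap, n_ba)} voxels < 27)"
        )
    new_label = int(labels.max()) + 1
    idx = np.argwhere(mask)
    basal_idx = idx[~apical_side]
    labels[tuple(basal_idx.T)] = new_label

    # pull the basal daughter's rim off shallower layers: a periclinal
    # division wall meets the old outer wall at the rim, it does not leave
    # the basal daughter touching the layer above the mother cell
    parent_layer_row = truth.cells.loc[truth.cells["cell_label"] == cell_label,
                                       "layer"]
    if len(parent_layer_row) and isinstance(parent_layer_row.iloc[0], str):
        parent_depth = int(parent_layer_row.iloc[0][1])
        shallower = set(
            truth.cells.loc[
                truth.cells["layer"].str[1].astype(int) < parent_depth,
                "cell_label",
            ].astype(int)
        )
        labels = _pull_rim_up(labels, new_label, cell_label, shallower)
        if min((labels == cell_label).sum(), (labels == new_label).sum()) < 27:
            raise ValueError(
                f"split at f={f} produces a degenerate daughter after rim "
                "cleanup (< 27 voxels)"
            )

    if jitter > 0:
        labels = _jitter_free_walls(labels, cell_label, new_label, vs,
                                    jitter, rng)
        labels = _jitter_free_walls(labels, new_label, cell_label, vs,
                                    jitter, rng)
        if parent_layer_row.size and isinstance(parent_layer_row.iloc[0], str):
            labels = _pull_rim_up(labels, new_label, cell_label, shallower)

    new_volume = LabeledVolume(labels, volume.voxel_size, volume.base_plane)
    cells = truth.cells.copy()
    parent_row = cells.loc[cells["cell_label"] == cell_label]
    parent_layer = parent_row["layer"].iloc[0] if len(parent_row) else None
    basal_layer = parent_layer
    if orientation == "periclinal" and parent_layer in ("L1", "L2", "L3"):
        basal_layer = f"L{int(parent_layer[1]) + 1}"
    for lab, layer in ((cell_label, parent_layer), (new_label, basal_layer)):
        row = _empty_truth_row(lab, layer)
        row.update(
            divided=True, orientation=orientation,
            normal_z=normal[0], normal_y=normal[1], normal_x=normal[2],
            f=f, jitter_um=float(jitter),
            sibling=new_label if lab == cell_label else cell_label,
        )
        cells = cells[cells["cell_label"] != lab]
        cells = pd.concat([cells, pd.DataFrame([row])], ignore_index=True)
    new_truth = GroundTruth(
        cells=cells.sort_values("cell_label").reset_index(drop=True),
        stage=truth.stage, dome_height=truth.dome_height,
        dome_radii=truth.dome_radii, squareness=truth.squareness,
        central_L2=truth.central_L2, central_L3=truth.central_L3,
        ovule_id=truth.ovule_id,
    )
    if cell_label == truth.central_L2 and orientation == "periclinal":
        new_truth.central_L3 = new_label
    _fill_truth_contacts(new_volume, new_truth)
    return new_volume, new_truth


def _pull_rim_up(labels, basal, apical, shallower_labels, max_rounds=6):
    """Reassign basal-daughter voxels that touch any shallower-layer cell to
    the apical daughter, until none remain (bounded rounds)."""
    out = labels.copy()
    shallow_mask = np.isin(out, list(shallower_labels)) if shallower_labels \
        else np.zeros(out.shape, dtype=bool)
    for _ in range(max_rounds):
        touch = ndimage.binary_dilation(shallow_mask, structure=_FACE_STRUCT)
        rim = (out == basal) & touch
        if not rim.any():
            break
        out[rim] = apical
    return out


def _division_normal(orientation, radial, rng):
    t1, t2 = geom.tangent_basis(radial)
    phi = rng.uniform(0, 2 * np.pi)
    tangent = np.cos(phi) * t1 + np.sin(phi) * t2
    if orientation == "periclinal":
        return geom.unit(radial)
    if orientation == "anticlinal":
        return geom.unit(tangent)
    if orientation == "oblique":
        return geom.unit(radial + tangent)
    raise ValueError(f"unknown orientation {orientation!r}")


def _jitter_free_walls(labels, daughter, sibling, voxel_size, jitter, rng):
    """Displace the daughter's free walls by a band-limited Gaussian field.

    A smooth scalar field (white noise, Gaussian-filtered at σ = 2 voxels,
    rescaled to RMS = ``jitter`` µm) drives voxel transfers across the
    daughter's boundary with neighboring cells (never the sibling, never
    the background): positive field grows the daughter locally, negative
    shrinks it, by up to the field amplitude in µm. Each round transfers
    equal numbers of voxels in and out, so the deformation is
    volume-preserving: the daughter's measured size — the quantity
    staging and ratio clustering rest on — is untouched by wall age.
    """
    out = labels.copy()
    field_ = ndimage.gaussian_filter(
        rng.standard_normal(labels.shape), sigma=2.0
    )
    rms = np.sqrt(np.mean(field_**2))
    if rms > 0:
        field_ *= jitter / rms
    step = float(np.min(voxel_size))
    n_rounds = max(int(np.ceil(jitter / step)), 1)
    for round_i in range(n_rounds):
        thresh = (round_i + 0.5) * step
        dmask = out == daughter
        dil = ndimage.binary_dilation(dmask, structure=_FACE_STRUCT)
        grow = dil & ~dmask & (out != sibling) & (out != 0) & (field_ > thresh)
        dmask = out == daughter
        ero = ndimage.binary_erosion(dmask, structure=_FACE_STRUCT)
        rim = dmask & ~ero & (field_ < -thresh)
        # volume balance: transfer the same count each way, keeping the
        # most strongly driven voxels on each side
        n_grow, n_rim = int(grow.sum()), int(rim.sum())
        n_move = min(n_grow, n_rim)
        if n_move == 0:
            continue
        if n_grow > n_move:
            g_idx = np.argwhere(grow)
            order = np.argsort(-field_[tuple(g_idx.T)])
            drop = g_idx[order[n_move:]]
            grow[tuple(drop.T)] = False
        if n_rim > n_move:
            r_idx = np.argwhere(rim)
            order = np.argsort(field_[tuple(r_idx.T)])
            drop = r_idx[order[n_move:]]
            rim[tuple(drop.T)] = False
        out[grow] = daughter
        if rim.any():
            # cede rim voxels to the dominant non-sibling neighbor
            nb_labels = _majority_neighbor(out, rim, daughter, sibling)
            out[rim] = np.where(nb_labels[rim] > 0, nb_labels[rim], out[rim])
        # keep the daughter connected and non-degenerate
        comp, n_comp = ndimage.label(out == daughter, structure=_FACE_STRUCT)
        if n_comp == 0 or (out == daughter).sum() < 27:
            return labels  # too aggressive: revert entirely
        if n_comp > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                       index=np.arange(1, n_comp + 1))
            keep = 1 + int(np.argmax(sizes))
            stray = (comp > 0) & (comp != keep)
            nb_labels = _majority_neighbor(out, stray, daughter, sibling)
            out[stray] = np.where(nb_labels[stray] > 0, nb_labels[stray],
                                  out[stray])
    return out


def _majority_neighbor(labels, region, daughter, sibling):
    """Per-voxel: the most frequent 6-neighbor label excluding the daughter,
    its sibling and background (0 where none exists)."""
    result = np.zeros(labels.shape, dtype=labels.dtype)
    idx = np.argwhere(region)
    shape = labels.shape
    for k, j, i in idx:
        votes = {}
        for dk, dj, di in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            kk, jj, ii = k + dk, j + dj, i + di
            if 0 <= kk < shape[0] and 0 <= jj < shape[1] and 0 <= ii < shape[2]:
                lab = labels[kk, jj, ii]
                if lab not in (0, daughter, sibling):
                    votes[lab] = votes.get(lab, 0) + 1
        if votes:
            result[k, j, i] = max(votes, key=votes.get)
    return result


def _plant_with_ratio(volume, truth, r, f0, jitter, rng_seed, tries=3,
                      tol=0.05):
    """Plant a central periclinal division targeting daughter ratio ``r``.

    The rim cleanup after the cut transfers some basal volume apically, so
    the volume-quantile fraction is recalibrated from the measured ratio
    (bounded retries; the best attempt is kept).
    """
    f = f0
    best = None
    for _ in range(tries):
        v2, t2 = plant_division(volume, truth, truth.central_L2,
                                orientation="periclinal", f=f,
                                jitter=jitter, rng_seed=rng_seed,
                                split_by="volume")
        va = float((v2.labels == t2.central_L2).sum())
        vb = float((v2.labels == t2.central_L3).sum())
        measured = max(va, vb) / min(va, vb)
        err = abs(measured - r) / r
        if best is None or err < best[0]:
            best = (err, v2, t2)
        if err <= tol:
            break
        # basal share correction: scale by the attained/target share ratio
        share_target = 1.0 / (1.0 + r)
        share_measured = min(va, vb) / (va + vb)
        f = float(np.clip(f * share_target / max(share_measured, 1e-6),
                          0.05, 0.6))
    return best[1], best[2]


# ---------------------------------------------------------------------------
# cohorts

#: Default per-stage cohort conditions. Central L2 volumes grow roughly
#: geometrically across stages (means 500/1000/2000/4000 µm³, 10% sd,
#: log-normal); dome size grows with stage within the 30–60 µm diameter
#: range; Type 2 (recent central periclinal division, continuous walls)
#: dominates at Stage 1 and declines afterwards.
DEFAULT_STAGE_PARAMS = {
    1: dict(n_ovules=10, central_volume_mean=500.0, central_volume_sd=0.10,
            dome=dict(H=26.0, Rx=16.0, Ry=16.0, n=2.0), type2_fraction=0.7,
            plant_old_division=True),
    2: dict(n_ovules=10, central_volume_mean=1000.0, central_volume_sd=0.10,
            dome=dict(H=30.0, Rx=18.0, Ry=18.0, n=2.0), type2_fraction=0.4,
            plant_old_division=True),
    3: dict(n_ovules=10, central_volume_mean=2000.0, central_volume_sd=0.10,
            dome=dict(H=36.0, Rx=20.0, Ry=20.0, n=2.0), type2_fraction=0.0),
    4: dict(n_ovules=10, central_volume_mean=4000.0, central_volume_sd=0.10,
            dome=dict(H=44.0, Rx=23.0, Ry=23.0, n=2.0), type2_fraction=0.0),
}

#: Wall jitter separating recent (Type 2) from old (Type 1) divisions, µm.
#: Calibrated within this package: 0 leaves walls coplanar, 3 µm reliably
#: breaks continuity below the 160° threshold.
JITTER_RECENT = 0.0
JITTER_OLD = 3.0


def generate_cohort(
    stage_params: dict | None = None,
    rng_seed: int = 0,
    voxel_size=(0.5, 0.5, 0.5),
    ratio_means=(1.0, 2.3),
    ratio_sds=(0.05, 0.1),
    ratio2_fraction: float = 0.4,
) -> list[tuple[LabeledVolume, GroundTruth]]:
    """Generate a multi-stage cohort of synthetic ovules.

    Central-L2 volumes are drawn log-normally around the per-stage means.
    In each Type 2 ovule the central L2 cell receives a periclinal division
    with continuous walls (jitter 0) whose volume split is drawn from a
    two-component ratio mixture (symmetric ~1.0 and asymmetric ~2.3, the
    asymmetric component with probability ``ratio2_fraction``); Type 1
    ovules receive the same division with large wall jitter, emulating an
    older, deformed division — or, at stages with no division plan, none.
    """
    params = stage_params if stage_params is not None else DEFAULT_STAGE_PARAMS
    rng = np.random.default_rng(rng_seed)
    cohort = []
    for stage in sorted(params):
        sp = params[stage]
        n_ovules = int(sp.get("n_ovules", 0))
        for i in range(n_ovules):
            ov_seed = int(rng.integers(2**31 - 1))
            ov_rng = np.random.default_rng(ov_seed)
            mean = sp["central_volume_mean"]
            sd = sp.get("central_volume_sd", 0.10)
            sigma = np.sqrt(np.log(1 + sd**2))
            target = float(mean * np.exp(
                ov_rng.normal(-0.5 * sigma**2, sigma)))
            type2 = ov_rng.uniform() < sp.get("type2_fraction", 0.0)
            plant = type2 or sp.get("plant_old_division", False)
            r = None
            if plant:
                comp = int(ov_rng.uniform() < ratio2_fraction)
                r = max(float(ov_rng.normal(ratio_means[comp],
                                            ratio_sds[comp])), 1.0)
                # the staged quantity is the apical daughter's volume: grow
                # the mother so the larger (apical) daughter hits the target
                mother_target = target * (1.0 + 1.0 / r)
            else:
                mother_target = target
            dome = sp["dome"]
            ovule_id = f"stage{stage}_ov{i}"
            volume, truth = generate_dome_tessellation(
                H=dome["H"], Rx=dome["Rx"], Ry=dome["Ry"],
                n=dome.get("n", 2.0),
                layer_thicknesses=sp.get("layer_thicknesses", (5.0, 8.0, 7.0)),
                seeds_per_layer=sp.get("seeds_per_layer", (24, 12, 8, 5)),
                central_L2_target_volume=mother_target,
                voxel_size=voxel_size,
                rng_seed=ov_seed,
                stage=stage,
                ovule_id=ovule_id,
            )
            if plant:
                f_split = 1.0 / (1.0 + r)  # basal share of the volume
                jitter = JITTER_RECENT if type2 else JITTER_OLD
                div_seed = int(ov_rng.integers(2**31 - 1))
                try:
                    volume, truth = _plant_with_ratio(
                        volume, truth, r, f_split, jitter, div_seed)
                except ValueError as exc:
                    logger.warning("%s: planted division failed (%s)",
                                   ovule_id, exc)
            cohort.append((volume, truth))
    return cohort
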
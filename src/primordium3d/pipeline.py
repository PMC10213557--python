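"""End-to-end orchestration: simulate → annotate → measure → stage →
divisions → organ → stats, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import primordium3d
from primordium3d.annotation import annotate
from primordium3d.core_io import (
    Config,
    LabeledVolume,
    read_labeled_volume,
    write_cell_table,
    write_labeled_volume,
    export_mesh,
)
from primordium3d.divisions import classify_ovule_type, detect_recent_divisions
from primordium3d.morphometrics import measure_cells
from primordium3d.organ import measure_ovule_shape
from primordium3d.staging import assign_stages, group_summary, wss_curve_and_elbow
from primordium3d.synthetic import generate_cohort

logger = logging.getLogger("primordium3d")


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: dict = field(default_factory=dict)  # stage -> path
    version: str = primordium3d.__version__
    started: str = ""
    finished: str = ""
    failure: str | None = None

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _analyze_one(volume, ovule_id, config: Config):
    graph, ann = annotate(volume, min_contact_area=config.min_contact_area)
    cells = measure_cells(volume, ann, ovule_id=ovule_id,
                          smoothing_iters=config.smoothing_iters)
    calls = detect_recent_divisions(
        volume, graph, ann,
        continuity_threshold=config.continuity_threshold,
        min_side_area=config.min_side_area,
        n_directions=config.n_plane_directions,
    )
    type_call = classify_ovule_type(
        volume, graph, ann,
        continuity_threshold=config.continuity_threshold,
        min_side_area=config.min_side_area, ovule_id=ovule_id,
    )
    shape = measure_ovule_shape(
        volume, ann.layers, ovule_id=ovule_id,
        curvature_radius=config.curvature_radius,
        small_radius=config.curvature_radius_small,
        small_diameter=config.small_ovule_diameter,
        smoothing_iters=config.smoothing_iters,
    )
    return graph, ann, cells, calls, type_call, shape


def _division_rows(ovule_id, calls, type_call):
    rows = []
    for c in calls:
        rows.append({
            "ovule_id": ovule_id, "label_a": c.pair[0], "label_b": c.pair[1],
            "continuity_angle_deg": c.continuity_angle,
            "is_recent": c.is_recent,
            "op_angle_deg": c.op_angle_deg,
            "orientation": c.orientation,
            "volume_ratio": c.volume_ratio,
            "ovule_type": type_call.ovule_type,
        })
    if not rows:
        rows.append({
            "ovule_id": ovule_id, "label_a": np.nan, "label_b": np.nan,
            "continuity_angle_deg": np.nan, "is_recent": False,
            "op_angle_deg": np.nan, "orientation": None,
            "volume_ratio": np.nan, "ovule_type": type_call.ovule_type,
        })
    return rows


def run_pipeline(
    config: Config,
    out_dir,
    volume_paths=None,
    simulate: bool = False,
    stage_params=None,
) -> RunManifest:
    """Run every stage and emit the six output tables plus a manifest.

    Inputs are either labeled-volume files (``volume_paths``) or, with
    ``simulate``, a synthetic cohort generated from ``stage_params`` (the
    package defaults when omitted). Outputs: cells_measured.csv,
    stages.csv, divisions.csv, ovule_shape.csv, summary.csv, manifest.json.
    A stage failure keeps partial outputs and marks the failure point.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.log()
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    stage_name = "load"
    try:
        volumes = []
        if simulate:
            cohort = generate_cohort(stage_params, rng_seed=config.seed)
            truths = {}
            for vol, truth in cohort:
                volumes.append((truth.ovule_id, vol))
                truths[truth.ovule_id] = truth
        else:
            for p in volume_paths or []:
                manifest.inputs[str(p)] = _sha256(p)
                volumes.append((Path(p).stem, read_labeled_volume(p)))
        if not volumes:
            raise ValueError("no input volumes")

        stage_name = "analyze"
        all_cells, div_rows, shape_rows, shapes = [], [], [], []
        for ovule_id, vol in volumes:
            _, ann, cells, calls, type_call, shape = _analyze_one(
                vol, ovule_id, config)
            all_cells.append(cells)
            div_rows.extend(_division_rows(ovule_id, calls, type_call))
            shapes.append(shape)
            shape_rows.append({
                "ovule_id": ovule_id,
                "box_a_um": shape.box_lengths[0],
                "box_b_um": shape.box_lengths[1],
                "box_c_um": shape.box_lengths[2],
                "aspect_ratio": shape.aspect_ratio,
                "apex_curvature_per_um": shape.apex_curvature,
                "curvature_radius_um": shape.curvature_radius,
            })
        cells = pd.concat(all_cells, ignore_index=True)

        stage_name = "stage"
        central = cells[cells["contact_class"] == "central_L2"].copy()
        central = central.set_index("ovule_id")["volume_um3"]
        k = min(config.staging_k, max(len(central), 1))
        model = assign_stages(central.to_numpy(), k, log_scale=True)
        stage_of = dict(zip(central.index, model.assignments))
        cells["stage"] = cells["ovule_id"].map(stage_of)
        stages_df = pd.DataFrame({
            "ovule_id": central.index,
            "central_L2_volume_um3": central.to_numpy(),
            "stage": model.assignments,
        })
        elbow = wss_curve_and_elbow(central.to_numpy(), log_scale=True,
                                    k_max=min(config.elbow_k_max, len(central)))

        stage_name = "write"
        write_cell_table(cells, out_dir / "cells_measured.csv")
        manifest.outputs["cells"] = str(out_dir / "cells_measured.csv")
        stages_df.to_csv(out_dir / "stages.csv", index=False)
        manifest.outputs["stages"] = str(out_dir / "stages.csv")
        pd.DataFrame(div_rows).to_csv(out_dir / "divisions.csv", index=False)
        manifest.outputs["divisions"] = str(out_dir / "divisions.csv")
        pd.DataFrame(shape_rows).to_csv(out_dir / "ovule_shape.csv", index=False)
        manifest.outputs["ovule_shape"] = str(out_dir / "ovule_shape.csv")

        stage_name = "stats"
        summary = group_summary(cells, seed=config.seed)
        summary.to_csv(out_dir / "summary.csv", index=False)
        manifest.outputs["summary"] = str(out_dir / "summary.csv")
        manifest.outputs["elbow_wss"] = json.dumps(
            {"suggested_k": elbow.suggested_k,
             "wss": list(map(float, elbow.wss_curve))})
    except Exception as exc:
        manifest.failure = f"{stage_name}: {exc}"
        logger.error("pipeline failed at %s: %s", stage_name, exc)
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.save(out_dir / "manifest.json")
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out_dir / "manifest.json")
    return manifest


def make_report(out_dir) -> dict:
    """Pivot the pipeline outputs into figure-style tables.

    Emits per-(cell class × stage) descriptor pivots (mean value tables
    for volume, normalized major axis, sphericity) as CSV. Empty inputs
    produce a note, not a crash. Regeneration is idempotent.
    """
    out_dir = Path(out_dir)
    cells = pd.read_csv(out_dir / "cells_measured.csv")
    report_dir = out_dir / "report"
    report_dir.mkdir(exist_ok=True)
    written = {}
    for value in ("volume_um3", "norm_c", "sphericity"):
        if cells.empty or cells[value].dropna().empty:
            (report_dir / f"pivot_{value}.csv").write_text(
                "empty: no measurable cells\n")
            written[value] = "empty"
            continue
        pivot = cells.pivot_table(index="contact_class", columns="stage",
                                  values=value, aggfunc="mean")
        pivot.to_csv(report_dir / f"pivot_{value}.csv")
        written[value] = str(report_dir / f"pivot_{value}.csv")
    return written
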
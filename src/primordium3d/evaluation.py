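"""Parameter-recovery evaluation of the pipeline on synthetic cohorts.

Generates a multi-stage cohort with planted ground truth and scores how
well the analysis modules recover it: staging accuracy and the elbow's
cluster count, Type 1/Type 2 classification, division detection
sensitivity/specificity, division-orientation classification, and the
daughter volume-ratio mixture. This is the package's own validation
harness; every number it reports is recomputed from a fresh cohort.
"""

from __future__ import annotations

import logging

import numpy as np

from primordium3d import _geometry as geom
from primordium3d.annotation import annotate
from primordium3d.divisions import (
    classify_orientation,
    classify_ovule_type,
    cluster_volume_ratios,
    detect_recent_divisions,
)
from primordium3d.morphometrics import measure_volume
from primordium3d.staging import assign_stages, wss_curve_and_elbow
from primordium3d.synthetic import DEFAULT_STAGE_PARAMS, generate_cohort
from primordium3d.walls import interface_mesh

logger = logging.getLogger("primordium3d")


def evaluate_cohort(
    seed: int = 0,
    stage_params: dict | None = None,
    detect_stages=(1, 2),
    n_negative_controls: int = 2,
    continuity_threshold: float = 160.0,
) -> dict:
    """Generate a cohort and score ground-truth recovery.

    Returns a flat dict of recovery metrics. Division detection runs on
    the ovules of ``detect_stages`` (the stages that carry planted
    divisions) plus ``n_negative_controls`` undivided late-stage ovules
    as a false-positive control.
    """
    params = stage_params if stage_params is not None else DEFAULT_STAGE_PARAMS
    cohort = generate_cohort(params, rng_seed=seed)

    volumes, true_stages = [], []
    type_true, type_pred = [], []
    type_counts: dict[int, list] = {}
    sens_num = sens_den = 0
    spec_num = spec_den = 0
    neg_fp = neg_total = 0
    neg_done = 0
    peri_hits = peri_total = 0
    fresh_ratios = []

    for vol, gt in cohort:
        graph, ann = annotate(vol)
        volumes.append(measure_volume(vol, ann.central_L2))
        true_stages.append(gt.stage)

        stage_cfg = params.get(gt.stage, {})
        planted = gt.central_L3 is not None
        fresh = planted and gt.ovule_type == "Type2"

        if gt.stage in detect_stages:
            call = classify_ovule_type(
                vol, graph, ann, continuity_threshold=continuity_threshold,
                ovule_id=gt.ovule_id)
            type_true.append(gt.ovule_type)
            type_pred.append(call.ovule_type)
            rec = type_counts.setdefault(gt.stage, [0, 0])
            rec[0] += call.ovule_type == "Type2"
            rec[1] += 1

            calls = detect_recent_divisions(
                vol, graph, ann, continuity_threshold=continuity_threshold)
            sisters = frozenset((gt.central_L2, gt.central_L3)) \
                if planted else None
            for c in calls:
                pair = frozenset(c.pair)
                if fresh and pair == sisters:
                    sens_den += 1
                    sens_num += c.is_recent
                else:
                    spec_den += 1
                    spec_num += not c.is_recent
        elif not planted and neg_done < n_negative_controls:
            calls = detect_recent_divisions(
                vol, graph, ann, continuity_threshold=continuity_threshold)
            neg_fp += sum(c.is_recent for c in calls)
            neg_total += len(calls)
            neg_done += 1

        if planted:
            peri_total += 1
            iface = interface_mesh(vol, gt.central_L2, gt.central_L3)
            radial = geom.local_radial_direction(
                vol.labels, vol.voxel_size, iface.plane_point,
                vol.base_plane)
            if classify_orientation(iface.plane_normal, radial) == "periclinal":
                peri_hits += 1
        if fresh:
            va = float((vol.labels == gt.central_L2).sum())
            vb = float((vol.labels == gt.central_L3).sum())
            fresh_ratios.append(max(va, vb) / min(va, vb))

    volumes = np.asarray(volumes)
    true_stages = np.asarray(true_stages)
    n_stages = len(np.unique(true_stages))
    model = assign_stages(volumes, n_stages, log_scale=True)
    elbow = wss_curve_and_elbow(volumes, k_max=min(8, len(volumes)),
                                log_scale=True)
    # map truth stage ids (possibly non-contiguous) onto rank order
    stage_rank = {s: i + 1 for i, s in enumerate(sorted(np.unique(true_stages)))}
    ranked_truth = np.array([stage_rank[s] for s in true_stages])

    results = {
        "n_ovules": len(cohort),
        "stage_accuracy": float(np.mean(model.assignments == ranked_truth)),
        "stage_means_um3": model.means.tolist(),
        "elbow_k": int(elbow.suggested_k),
        "elbow_low_confidence": bool(elbow.low_confidence),
        "type_agreement": float(np.mean([a == b for a, b in
                                         zip(type_true, type_pred)]))
        if type_true else float("nan"),
        "type2_recovered": {s: tuple(v) for s, v in type_counts.items()},
        "sensitivity": sens_num / sens_den if sens_den else float("nan"),
        "specificity": spec_num / spec_den if spec_den else float("nan"),
        "negative_control_fp_rate": neg_fp / neg_total if neg_total
        else float("nan"),
        "periclinal_fraction": peri_hits / peri_total if peri_total
        else float("nan"),
        "n_ratio_pairs": len(fresh_ratios),
        "ratios": fresh_ratios,
    }
    if len(fresh_ratios) >= 4 and len(np.unique(fresh_ratios)) >= 2:
        _, means = cluster_volume_ratios(fresh_ratios, k=2)
        results["ratio_cluster_means"] = [float(m) for m in means]
    else:
        results["ratio_cluster_means"] = None
    return results
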
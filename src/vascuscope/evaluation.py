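"""Ground-truth evaluation harness.

Scores the detection and classification stages against the synthetic
generator's truth tables, measures recovery of a planted group effect on
the target channel, and calibrates the group test's type-I error under the
no-effect condition.  Used by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .detect import detect_cells, detect_spots
from .pipeline import RunConfig, run_pipeline
from .stats import group_compare
from .synth import SceneConfig, generate_scene, quantize_u16

SPOT_CHANNELS = ("CD31", "TARGET1")


def greedy_match(detected_pts, truth_pts, rmax: float) -> list[tuple[int, int]]:
    """1-1 greedy nearest-neighbour matching within ``rmax`` pixels."""
    pairs = []
    for i, d in enumerate(detected_pts):
        for j, t in enumerate(truth_pts):
            dist = float(np.hypot(d[0] - t[0], d[1] - t[1]))
            if dist <= rmax:
                pairs.append((dist, i, j))
    pairs.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            matches.append((i, j))
    return matches


def score_detection(n_scenes: int = 10, base_seed: int = 0,
                    nucleus_match_px: float = 10.0,
                    spot_match_px: float = 5.0) -> dict[str, float]:
    """Recall/precision of nucleus and spot detection, and endothelial
    classification accuracy, against truth over seeded default scenes."""
    n_true_nuc = n_det_nuc = n_match_nuc = 0
    n_true_spot = n_det_spot = n_match_spot = 0
    n_endo_correct = n_endo_total = 0
    for rep in range(n_scenes):
        cfg = SceneConfig(seed=base_seed + rep)
        truth, images, _ = generate_scene(cfg)
        q = {ch: quantize_u16(im) for ch, im in images.items()}
        cells = detect_cells(q["DAPI"])
        truth_centers = [(n.cy, n.cx) for n in truth.nuclei]
        matches = greedy_match([c.centroid for c in cells], truth_centers,
                               nucleus_match_px)
        n_true_nuc += len(truth.nuclei)
        n_det_nuc += len(cells)
        n_match_nuc += len(matches)

        spots_by_channel = {
            ch: detect_spots(q[ch], ecc_direction="keep_at_most")
            for ch in SPOT_CHANNELS}
        for ch in SPOT_CHANNELS:
            truth_pts = [(p.y, p.x) for p in truth.puncta
                         if p.channel == ch]
            det_pts = [s.centroid for s in spots_by_channel[ch]]
            m = greedy_match(det_pts, truth_pts, spot_match_px)
            n_true_spot += len(truth_pts)
            n_det_spot += len(det_pts)
            n_match_spot += len(m)

        # endothelial flag of each matched cell: >=1 CD31 cluster whose
        # pixel majority overlaps the detected nucleus
        from .quantify import build_cell_records, classify_endothelial

        records, _ = build_cell_records(cells, {"CD31":
                                                spots_by_channel["CD31"]})
        classify_endothelial(records)
        flags = {r.cell_id: r.is_endothelial for r in records}
        for ci, tj in matches:
            n_endo_total += 1
            n_endo_correct += (flags[cells[ci].label]
                               == truth.nuclei[tj].is_endothelial)
    return {
        "nucleus_recall": n_match_nuc / n_true_nuc,
        "nucleus_precision": n_match_nuc / n_det_nuc,
        "spot_recall": n_match_spot / n_true_spot,
        "spot_precision": n_match_spot / n_det_spot,
        "endothelial_accuracy": n_endo_correct / n_endo_total,
        "n_scenes": n_scenes,
        "n_true_spots": n_true_spot,
    }


def planted_effect_experiment(n_replicates: int = 10, base_seed: int = 0,
                              ctrl_mean: float = 4.0, ss_mean: float = 4.0,
                              res_mean: float = 2.4,
                              scenes_per_group: int = 4) -> dict:
    """Recover a planted reduction of the RES group's target-puncta mean.

    Each replicate runs the full pipeline on three groups of rendered
    scenes and reports whether the CTRL-RES Bonferroni posttest is
    significant and the estimated percent reduction of the per-endothelial-
    cell mean cluster count.
    """
    significant = []
    reductions = []
    conservation_violations = 0
    for rep in range(n_replicates):
        run = RunConfig(
            seed=base_seed + rep,
            scenes_per_group=scenes_per_group,
            groups={
                "CTRL": {"puncta_mean_per_cell": {"CD31": 5.0,
                                                  "TARGET1": ctrl_mean}},
                "SS": {"puncta_mean_per_cell": {"CD31": 5.0,
                                                "TARGET1": ss_mean}},
                "RES": {"puncta_mean_per_cell": {"CD31": 5.0,
                                                 "TARGET1": res_mean}},
            })
        result = run_pipeline(run)
        ct = result.cell_table
        for ch in result.detected:
            if (ct[f"count_{ch}"].sum() + result.unassigned[ch]
                    != result.detected[ch]):
                conservation_violations += 1
        for summary in result.group_summaries.values():
            if sum(summary.bins.values()) != summary.n_endothelial:
                conservation_violations += 1
        endo = ct[ct["is_endothelial"]]
        means = endo.groupby("group")["count_TARGET1"].mean()
        reductions.append(100.0 * (1.0 - means["RES"] / means["CTRL"]))
        post = {tuple(sorted(p["pair"])): p
                for p in result.stats_report["posttests"]}
        significant.append(post[("CTRL", "RES")]["significant"])
    reductions = np.asarray(reductions)
    return {
        "significant_fraction": float(np.mean(significant)),
        "mean_reduction_pct": float(reductions.mean()),
        "se_reduction_pct": float(reductions.std(ddof=1)
                                  / np.sqrt(len(reductions))),
        "reductions": reductions.tolist(),
        "conservation_violations": conservation_violations,
        "n_replicates": n_replicates,
    }


def type1_calibration(n_replicates: int = 100, base_seed: int = 0,
                      mean: float = 4.0, scenes_per_group: int = 4,
                      cells_per_scene: int = 9, alpha: float = 0.05) -> dict:
    """Type-I error of the group test under the no-effect condition.

    Per-endothelial-cell counts are drawn from the generator's count model
    (Poisson with a common mean for all three groups) at the pipeline's
    group sizes; the rendering and detection stages, which the planted-
    effect experiment exercises, are bypassed so that 100 replicates stay
    cheap.
    """
    n_cells = scenes_per_group * cells_per_scene
    rejections = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(base_seed + rep)
        groups = {g: rng.poisson(mean, n_cells).astype(float)
                  for g in ("CTRL", "SS", "RES")}
        report = group_compare(groups, posthoc=False, alpha=alpha)
        rejections += report["significant"]
    return {"rejection_rate": rejections / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}
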
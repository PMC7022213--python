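"""Per-cell quantification: cluster assignment, endothelial classification,
anatomical region labels, and group summaries.

RNA clusters are measured "on the DAPI-positive cells": each detected
cluster is attributed to the nucleus owning the largest share of its pixels
(majority overlap, the default) or to the nucleus containing its centroid.
Cells co-labeled with at least ``min_cd31`` CD31 clusters are classified
endothelial, and every cell receives a shell/core label from the region
mask at its nucleus centroid.  Group summaries bin endothelial cells by
their cluster count per channel, split by region, with the non-endothelial
cell count kept as the complementary denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import RegionObject

REGION_LABELS = {1: "shell", 2: "core"}


@dataclass(frozen=True)
class AssignmentRule:
    method: str = "majority_overlap"  # or "centroid_in_mask"

    def __post_init__(self) -> None:
        if self.method not in ("majority_overlap", "centroid_in_mask"):
            raise ValueError("unknown assignment method")


@dataclass
class ChannelStats:
    cluster_count: int = 0
    total_cluster_area: int = 0
    mean_cluster_intensity: float | None = None


@dataclass
class CellRecord:
    cell_id: int
    nucleus: RegionObject
    region_label: str = "unassigned"
    is_endothelial: bool = False
    per_channel: dict[str, ChannelStats] = field(default_factory=dict)


def _owner_map(cells: list[RegionObject]) -> dict[tuple[int, int], int]:
    owners: dict[tuple[int, int], int] = {}
    for cell in cells:
        for r, c in cell.coords:
            key = (int(r), int(c))
            if key in owners:
                raise ValueError(
                    f"cell masks overlap at pixel {key}; nuclei must be "
                    "pairwise disjoint")
            owners[key] = cell.label
    return owners


def assign_clusters(cells: list[RegionObject], clusters: list[RegionObject],
                    rule: AssignmentRule = AssignmentRule()) -> list[int | None]:
    """Map each cluster to a cell id or None (unassigned).

    majority_overlap: the cell owning the largest share of the cluster's
    pixels, requiring at least one overlapping pixel; ties break to the
    lower cell id.  centroid_in_mask: the cell containing the cluster's
    rounded centroid.
    """
    owners = _owner_map(cells)
    assignment: list[int | None] = []
    for cluster in clusters:
        if rule.method == "centroid_in_mask":
            key = (int(round(cluster.centroid[0])),
                   int(round(cluster.centroid[1])))
            assignment.append(owners.get(key))
            continue
        votes: dict[int, int] = {}
        for r, c in cluster.coords:
            cid = owners.get((int(r), int(c)))
            if cid is not None:
                votes[cid] = votes.get(cid, 0) + 1
        if not votes:
            assignment.append(None)
        else:
            best = max(votes.values())
            assignment.append(min(cid for cid, v in votes.items()
                                  if v == best))
    return assignment


def build_cell_records(
    cells: list[RegionObject],
    clusters_by_channel: dict[str, list[RegionObject]],
    rule: AssignmentRule = AssignmentRule(),
) -> tuple[list[CellRecord], dict[str, int]]:
    """Assemble per-cell records and per-channel unassigned-cluster counts.

    Conservation holds by construction: for every channel, the summed
    per-cell counts plus the unassigned count equal the number of detected
    clusters.
    """
    records = {c.label: CellRecord(cell_id=c.label, nucleus=c)
               for c in cells}
    unassigned: dict[str, int] = {}
    for channel, clusters in clusters_by_channel.items():
        for rec in records.values():
            rec.per_channel[channel] = ChannelStats()
        assignment = assign_clusters(cells, clusters, rule)
        n_un = 0
        member_means: dict[int, list[float]] = {}
        for cluster, cid in zip(clusters, assignment):
            if cid is None:
                n_un += 1
                continue
            st = records[cid].per_channel[channel]
            st.cluster_count += 1
            st.total_cluster_area += cluster.area
            member_means.setdefault(cid, []).append(cluster.mean_intensity)
        for cid, means in member_means.items():
            records[cid].per_channel[channel].mean_cluster_intensity = (
                float(np.mean(means)))
        unassigned[channel] = n_un
    return [records[k] for k in sorted(records)], unassigned


def classify_endothelial(records: list[CellRecord],
                         min_cd31: int = 1) -> list[CellRecord]:
    """Flag cells with >= min_cd31 CD31 clusters as endothelial."""
    for rec in records:
        st = rec.per_channel.get("CD31")
        rec.is_endothelial = bool(st is not None
                                  and st.cluster_count >= min_cd31)
    return records


def assign_region(records: list[CellRecord],
                  region_mask: np.ndarray | None,
                  image_shape: tuple[int, int] | None = None,
                  ) -> list[CellRecord]:
    """Label each cell by the mask value at its nucleus centroid (rounded to
    the nearest pixel); mask value 0 or out-of-bounds -> 'unassigned'."""
    if region_mask is None:
        for rec in records:
            rec.region_label = "unassigned"
        return records
    mask = np.asarray(region_mask)
    if image_shape is not None and mask.shape != tuple(image_shape):
        raise ValueError("region mask shape does not match the image")
    h, w = mask.shape
    for rec in records:
        r = int(round(rec.nucleus.centroid[0]))
        c = int(round(rec.nucleus.centroid[1]))
        if 0 <= r < h and 0 <= c < w:
            rec.region_label = REGION_LABELS.get(int(mask[r, c]),
                                                 "unassigned")
        else:
            rec.region_label = "unassigned"
    return records


@dataclass
class GroupSummary:
    group_label: str
    channel: str
    bins: dict[str, int]
    bins_by_region: dict[str, dict[str, int]]
    bin_fractions: dict[str, float]
    n_endothelial: int
    n_nonendothelial: int
    endothelial_fraction: float


def _bin_key(count: int, max_bin: int) -> str:
    return str(count) if count < max_bin else f">={max_bin}"


def summarize_groups(records_by_group: dict[str, list[CellRecord]],
                     channel: str, max_bin: int = 8) -> dict[str, GroupSummary]:
    """Bin endothelial cells by cluster count (0 .. max_bin-1, >=max_bin),
    split by region; fractions are normalized within each group."""
    keys = [str(i) for i in range(max_bin)] + [f">={max_bin}"]
    out: dict[str, GroupSummary] = {}
    for group, records in records_by_group.items():
        if not records:
            warnings.warn(f"group {group!r} has no cells", stacklevel=2)
            out[group] = GroupSummary(group, channel, dict.fromkeys(keys, 0),
                                      {}, dict.fromkeys(keys, 0.0), 0, 0, 0.0)
            continue
        endo = [r for r in records if r.is_endothelial]
        bins = dict.fromkeys(keys, 0)
        by_region: dict[str, dict[str, int]] = {}
        for rec in endo:
            st = rec.per_channel.get(channel, ChannelStats())
            key = _bin_key(st.cluster_count, max_bin)
            bins[key] += 1
            reg = by_region.setdefault(rec.region_label,
                                       dict.fromkeys(keys, 0))
            reg[key] += 1
        n_endo = len(endo)
        fracs = {k: (v / n_endo if n_endo else 0.0) for k, v in bins.items()}
        out[group] = GroupSummary(
            group_label=group, channel=channel, bins=bins,
            bins_by_region=by_region, bin_fractions=fracs,
            n_endothelial=n_endo,
            n_nonendothelial=len(records) - n_endo,
            endothelial_fraction=n_endo / len(records))
    return out


CELL_TABLE_PREFIX = ["scene_id", "cell_id", "group", "region",
                     "is_endothelial", "nucleus_area", "nucleus_ecc",
                     "nucleus_cy", "nucleus_cx"]


def records_to_frame(records: list[CellRecord], group: str = "",
                     scene_id: str = "") -> pd.DataFrame:
    """Per-cell table (one row per DAPI-positive cell, documented header)."""
    channels = sorted({ch for r in records for ch in r.per_channel})
    rows = []
    for rec in records:
        row = {
            "scene_id": scene_id, "cell_id": rec.cell_id, "group": group,
            "region": rec.region_label,
            "is_endothelial": rec.is_endothelial,
            "nucleus_area": rec.nucleus.area,
            "nucleus_ecc": rec.nucleus.eccentricity,
            "nucleus_cy": rec.nucleus.centroid[0],
            "nucleus_cx": rec.nucleus.centroid[1],
        }
        for ch in channels:
            st = rec.per_channel.get(ch, ChannelStats())
            row[f"count_{ch}"] = st.cluster_count
            row[f"area_{ch}"] = st.total_cluster_area
            row[f"intensity_{ch}"] = st.mean_cluster_intensity
        rows.append(row)
    cols = CELL_TABLE_PREFIX + [f"{p}_{ch}" for ch in channels
                                for p in ("count", "area", "intensity")]
    return pd.DataFrame(rows, columns=cols)
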
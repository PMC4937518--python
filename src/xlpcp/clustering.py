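"""Whole-profile hierarchical clustering with a correlation-targeted cut.

Mean elution profiles are clustered agglomeratively (Euclidean distance,
complete linkage) and the dendrogram is cut at the largest merge height whose
clusters reach a grand mean intra-cluster pairwise Pearson correlation of
~0.95.  Singleton clusters carry no pairwise correlation and are excluded
from the mean; if no height qualifies, every profile becomes its own cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .features import pearson
from .profile_io import InputError, MeanProfile


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # group_id -> cluster label
    mean_pcc_per_cluster: dict[int, float]  # clusters of size >= 2 only
    achieved_mean_pcc: float | None  # grand mean over intra-cluster pairs
    cut_height: float


def hierarchical_cluster(mean_profiles: list[MeanProfile]) -> np.ndarray:
    """Complete-linkage dendrogram (scipy linkage matrix) of mean profiles."""
    if len(mean_profiles) < 2:
        raise InputError("need at least 2 profiles to cluster")
    lengths = {len(p.mean) for p in mean_profiles}
    if len(lengths) > 1:
        raise InputError("profiles differ in length")
    conditions = {p.condition for p in mean_profiles}
    if len(conditions) > 1:
        raise InputError(f"mixed conditions {sorted(conditions)}")
    mat = np.vstack([p.mean for p in mean_profiles])
    return linkage(mat, method="complete", metric="euclidean")


def _grand_mean_intra_pcc(
    labels: np.ndarray, mat: np.ndarray
) -> tuple[float | None, dict[int, float]]:
    """Mean pairwise PCC pooled over all intra-cluster pairs (size >= 2)."""
    per_cluster: dict[int, float] = {}
    all_pccs: list[float] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) < 2:
            continue
        pccs = [
            pearson(mat[i], mat[j]) for i, j in combinations(members, 2)
        ]
        per_cluster[int(lab)] = float(np.mean(pccs))
        all_pccs.extend(pccs)
    if not all_pccs:
        return None, per_cluster
    return float(np.mean(all_pccs)), per_cluster


def cut_by_mean_pcc(
    dendrogram: np.ndarray,
    mean_profiles: list[MeanProfile],
    target_pcc: float = 0.95,
) -> ClusterAssignment:
    """Cut at the largest height whose clusters reach the target mean PCC.

    Scans the distinct merge heights in decreasing order and returns the
    first (largest) cut whose grand mean intra-cluster pairwise PCC (over
    clusters of size >= 2) reaches ``target_pcc``.  Falls back to singleton
    clusters when no height qualifies.
    """
    mat = np.vstack([p.mean for p in mean_profiles])
    gids = [p.group_id for p in mean_profiles]
    heights = sorted(set(dendrogram[:, 2]), reverse=True)
    for h in heights:
        labels = fcluster(dendrogram, t=h, criterion="distance")
        grand, per_cluster = _grand_mean_intra_pcc(labels, mat)
        if grand is not None and grand >= target_pcc:
            return ClusterAssignment(
                labels=dict(zip(gids, (int(x) for x in labels))),
                mean_pcc_per_cluster=per_cluster,
                achieved_mean_pcc=grand,
                cut_height=float(h),
            )
    return ClusterAssignment(
        labels={g: i + 1 for i, g in enumerate(gids)},
        mean_pcc_per_cluster={},
        achieved_mean_pcc=None,
        cut_height=0.0,
    )


def clusters_as_sets(assignment: ClusterAssignment) -> list[set[str]]:
    """Member sets of all clusters with >= 2 members."""
    by_label: dict[int, set[str]] = {}
    for gid, lab in assignment.labels.items():
        by_label.setdefault(lab, set()).add(gid)
    return [s for s in by_label.values() if len(s) >= 2]
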
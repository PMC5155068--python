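"""IPD-ratio time courses and Ward clustering into temporal patterns A-D.

The IPD ratio at a site and time point is the mean raw sample IPD divided
by the mean raw dam-control IPD at the same stranded position; 1 means no
kinetic shift, larger values mean a larger methylated fraction.  Sites
passing the temporal screen are clustered on their ratio trajectories
(Euclidean distance, Ward minimum-variance linkage), the tree is cut into
four clusters, and each cluster is labeled with the temporal template its
centroid best matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment

from .synthetic import PATTERN_ANCHORS, PATTERN_LABELS, pattern_fraction


@dataclass
class IpdRatioMatrix:
    """Sites x time points grid of mean-IPD ratios (dense, all > 0)."""

    sites: list[tuple[int, str]]
    timepoints_h: list[float]
    ratios: np.ndarray  # shape (n_sites, n_timepoints)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (len(self.sites), len(self.timepoints_h)):
            raise ValueError("ratio grid shape does not match sites x timepoints")
        if not np.all(np.isfinite(self.ratios)) or np.any(self.ratios <= 0):
            raise ValueError("ratios must be finite and positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.ratios, columns=[f"ratio_{t:g}h" for t in self.timepoints_h]
        )
        df.insert(0, "position", [s[0] for s in self.sites])
        df.insert(1, "strand", [s[1] for s in self.sites])
        return df


def ipd_ratio(sample_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Mean raw sample IPD over mean raw dam-control IPD at one site."""
    x = np.asarray(sample_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both observation sets must be non-empty")
    cm = y.mean()
    if cm == 0.0:
        raise ValueError("control mean IPD is zero (corrupt input: IPDs are positive)")
    return float(x.mean() / cm)


def build_ratio_matrix(
    raw_by_site_sample: Mapping[tuple[int, str], Mapping[str, np.ndarray]],
    significant_sites: Sequence[tuple[int, str]],
    timepoint_samples: Sequence[tuple[float, str]],
    dam_sample_id: str,
) -> tuple[IpdRatioMatrix, list[tuple[int, str]]]:
    """Ratio trajectory per significant site, in genome-position order.

    ``timepoint_samples`` pairs each hour with its sample id, in the
    configured time order.  Sites missing any cell (or the dam control) are
    dropped with a warning and returned for the record.
    """
    order = sorted(set(significant_sites))
    times = [t for t, _ in timepoint_samples]
    kept: list[tuple[int, str]] = []
    dropped: list[tuple[int, str]] = []
    rows = []
    for key in order:
        per_sample = raw_by_site_sample.get(key, {})
        if dam_sample_id not in per_sample or any(
            sid not in per_sample for _, sid in timepoint_samples
        ):
            dropped.append(key)
            continue
        ctrl = per_sample[dam_sample_id]
        rows.append([ipd_ratio(per_sample[sid], ctrl) for _, sid in timepoint_samples])
        kept.append(key)
    if dropped:
        warnings.warn(
            f"{len(dropped)} site(s) dropped from the ratio matrix for missing cells",
            stacklevel=2,
        )
    matrix = IpdRatioMatrix(sites=kept, timepoints_h=list(times), ratios=np.array(rows).reshape(len(kept), len(times)))
    return matrix, dropped


def ward_cluster(matrix: IpdRatioMatrix) -> np.ndarray:
    """Agglomerative Ward (minimum-variance) linkage on Euclidean distances.

    Returns the standard 4-column linkage matrix; merge heights are
    monotone non-decreasing.  Deterministic: scipy's implementation breaks
    distance ties by the smaller cluster index.
    """
    if len(matrix.sites) < 2:
        raise ValueError("clustering needs at least 2 sites")
    if not np.all(np.isfinite(matrix.ratios)):
        raise ValueError("non-finite ratio entries")
    return hierarchy.linkage(matrix.ratios, method="ward")


def cut_to_patterns(linkage_matrix: np.ndarray, k: int = 4) -> np.ndarray:
    """Cut the dendrogram into k clusters (labels 1..k, one per site)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = linkage_matrix.shape[0] + 1
    if k > n:
        raise ValueError(f"cannot cut {n} sites into {k} clusters")
    return hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")


def _znorm(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def label_patterns(
    assignments: np.ndarray,
    matrix: IpdRatioMatrix,
    linkage_matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """Label clusters A-D by matching centroid shape to the four templates.

    Template trajectories (A: flat 8-16 h then monotone rise; B: 24-72 h
    decline then recovery; C: peak at 72 h; D: peak at 24 h and late rise)
    and cluster centroids are z-normalized — ratio scale is irrelevant, the
    shape is what is labeled — and matched one-to-one by minimum total
    Euclidean cost.  With fewer than four clusters the best-fitting subset
    of labels is used (warning emitted); with more, extra clusters get
    their nearest template.
    """
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    t = np.asarray(matrix.timepoints_h, dtype=float)
    templates = np.stack([_znorm(pattern_fraction(lab, t)) for lab in PATTERN_LABELS])

    centroids = np.stack(
        [matrix.ratios[assignments == c].mean(axis=0) for c in clusters]
    )
    zc = np.stack([_znorm(c) for c in centroids])
    cost = np.linalg.norm(zc[:, None, :] - templates[None, :, :], axis=2)

    labels: dict[int, str] = {}
    if len(clusters) < len(PATTERN_LABELS):
        warnings.warn(
            f"only {len(clusters)} cluster(s); assigning best-fitting subset of pattern labels",
            stacklevel=2,
        )
    if len(clusters) <= len(PATTERN_LABELS):
        ri, ci = linear_sum_assignment(cost)
        for r, c in zip(ri, ci):
            labels[int(clusters[r])] = PATTERN_LABELS[c]
    else:
        warnings.warn("more clusters than pattern templates; labels may repeat", stacklevel=2)
        ri, ci = linear_sum_assignment(cost[:, : len(PATTERN_LABELS)][: len(PATTERN_LABELS)])
        for r, c in zip(ri, ci):
            labels[int(clusters[r])] = PATTERN_LABELS[c]
        for idx, c in enumerate(clusters):
            if int(c) not in labels:
                labels[int(c)] = PATTERN_LABELS[int(np.argmin(cost[idx]))]

    heights = _cluster_heights(assignments, clusters, linkage_matrix)
    out = pd.DataFrame(
        {
            "position": [s[0] for s in matrix.sites],
            "strand": [s[1] for s in matrix.sites],
            "cluster_index": assignments,
            "pattern_label": [labels[int(c)] for c in assignments],
            "linkage_height": [heights[int(c)] for c in assignments],
        }
    )
    return pd.concat([out, matrix.to_frame().iloc[:, 2:]], axis=1)


def _cluster_heights(
    assignments: np.ndarray, clusters: np.ndarray, linkage_matrix: np.ndarray | None
) -> dict[int, float]:
    """Height at which each cut cluster is fully merged (0 for singletons)."""
    if linkage_matrix is None:
        return {int(c): float("nan") for c in clusters}
    n = linkage_matrix.shape[0] + 1
    # membership of each internal node, bottom-up
    member_cluster: list[set[int]] = [{int(assignments[i])} for i in range(n)]
    node_height = [0.0] * n
    heights = {int(c): 0.0 for c in clusters}
    for a, b, h, _ in linkage_matrix:
        merged = member_cluster[int(a)] | member_cluster[int(b)]
        member_cluster.append(merged)
        node_height.append(float(h))
        if len(merged) == 1:
            c = next(iter(merged))
            heights[c] = max(heights[c], float(h))
    return heights


def linkage_to_newick(linkage_matrix: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Export the dendrogram as a Newick string with branch lengths."""
    n = linkage_matrix.shape[0] + 1
    node_str = list(leaf_names)
    node_h = [0.0] * n
    for a, b, h, _ in linkage_matrix:
        a, b = int(a), int(b)
        la = (float(h) - node_h[a]) / 2.0
        lb = (float(h) - node_h[b]) / 2.0
        node_str.append(f"({node_str[a]}:{la:.6g},{node_str[b]}:{lb:.6g})")
        node_h.append(float(h))
    return node_str[-1] + ";"
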
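"""Per-cluster size and two-channel intensity statistics, pooling and
group comparison, plus per-cell total fluorescence.

Intensity means are computed on the raw (unscaled) channel images: the
percentile-scaled image exists only to build the mask, and ratios of scaled
values would be distorted by per-image normalization. The per-cluster
CFP/YFP ratio is the ratio of channel means over the cluster's pixels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import GroupCountError, IncompatibleTablesError
from .segmentation import (
    LabeledClusters,
    NO_FOREGROUND,
    SegmentationParams,
    otsu_threshold,
    scale_uniform,
)
from .types import CFP, YFP, FieldOfView, Image2D

__all__ = [
    "ClusterTable",
    "GroupComparison",
    "cluster_metrics",
    "pool_clusters",
    "compare_groups",
    "metric_histogram",
    "segment_cells",
    "total_cell_fluorescence",
    "spot_recovery",
]

#: Columns of a cluster table; one row per detected cluster.
CLUSTER_COLUMNS = [
    "cluster_id",
    "cell_id",
    "condition",
    "area_px",
    "mean_cfp",
    "mean_yfp",
    "ratio_cfp_yfp",
    "centroid_row",
    "centroid_col",
]


@dataclass
class ClusterTable:
    """Cluster records plus the segmentation parameters that produced them."""

    records: pd.DataFrame
    params: SegmentationParams

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GroupComparison:
    """Two-group comparison of one per-cluster (or per-cell) metric."""

    metric: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    median: tuple[float, float]
    sem: tuple[float, float]
    test_name: str
    statistic: float
    p_value: float
    direction: int  # sign of mean(group2) - mean(group1)

    def as_dict(self) -> dict:
        d = {"metric": self.metric, "test": self.test_name,
             "statistic": self.statistic, "p_value": self.p_value,
             "direction": self.direction}
        for i, g in enumerate(self.group_labels):
            d[f"n_{g}"] = self.n[i]
            d[f"mean_{g}"] = self.mean[i]
            d[f"median_{g}"] = self.median[i]
            d[f"sem_{g}"] = self.sem[i]
        return d


def cluster_metrics(labels: LabeledClusters, fov: FieldOfView) -> ClusterTable:
    """Per-cluster area, mean raw CFP/YFP intensity, ratio and centroid.

    The cluster mask (built on one channel) is applied to both raw channel
    images; the ratio is ``mean_cfp / mean_yfp`` and is NaN for the
    degenerate case ``mean_yfp == 0``.
    """
    lab = labels.labels
    cfp = fov[CFP].pixels
    yfp = fov[YFP].pixels
    if lab.shape != cfp.shape or lab.shape != yfp.shape:
        raise ValueError(
            f"label grid {lab.shape} and channel images {cfp.shape}/{yfp.shape} "
            f"must share dimensions (cell {fov.cell_id!r})"
        )
    n = labels.n_clusters
    if n == 0:
        return ClusterTable(pd.DataFrame(columns=CLUSTER_COLUMNS), labels.params)
    index = np.arange(1, n + 1)
    area = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    mean_cfp = ndimage.mean(cfp, labels=lab, index=index)
    mean_yfp = ndimage.mean(yfp, labels=lab, index=index)
    centroids = np.asarray(ndimage.center_of_mass(np.ones_like(lab), labels=lab, index=index))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_yfp > 0, mean_cfp / mean_yfp, np.nan)
    df = pd.DataFrame(
        {
            "cluster_id": index,
            "cell_id": fov.cell_id,
            "condition": fov.condition,
            "area_px": area.astype(int),
            "mean_cfp": mean_cfp,
            "mean_yfp": mean_yfp,
            "ratio_cfp_yfp": ratio,
            "centroid_row": centroids[:, 0],
            "centroid_col": centroids[:, 1],
        }
    )
    return ClusterTable(df, labels.params)


def pool_clusters(tables: Sequence[ClusterTable]) -> ClusterTable:
    """Concatenate per-cell cluster tables, preserving every record.

    All tables must share identical segmentation parameters so pooled
    records are like-for-like comparable.
    """
    if len(tables) == 0:
        raise IncompatibleTablesError("cannot pool an empty list of cluster tables")
    params = tables[0].params
    for t in tables[1:]:
        if t.params != params:
            raise IncompatibleTablesError(
                f"cannot pool tables with different segmentation parameters: {t.params} != {params}"
            )
    records = pd.concat([t.records for t in tables], ignore_index=True)
    return ClusterTable(records, params)


def _midrank_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of sample x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration of group assignments.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to the
    first group and counts assignments whose U deviates from the null mean
    n1*n2/2 at least as much as the observed U. Midranks handle ties.
    """
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    d_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - offset)
        if abs(u - mu) >= d_obs - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total


def compare_groups(
    pooled: ClusterTable | pd.DataFrame,
    metric: str,
    test: str = "mannwhitney",
    group_order: Optional[tuple[str, str]] = None,
    group_column: str = "condition",
) -> GroupComparison:
    """Two-sided two-group comparison of one metric.

    The default test is Mann-Whitney U: exact full enumeration when both
    groups have n <= 8, otherwise the normal approximation with tie and
    continuity correction. ``test='welch'`` selects Welch's t instead.
    ``direction`` is the sign of mean(group2) - mean(group1) with groups in
    ``group_order`` (default: sorted label order).
    """
    df = pooled.records if isinstance(pooled, ClusterTable) else pooled
    if metric not in df.columns:
        raise KeyError(f"metric {metric!r} not in table columns {list(df.columns)}")
    groups = sorted(df[group_column].unique())
    if len(groups) != 2:
        raise GroupCountError(f"need exactly 2 groups, found {len(groups)}: {groups}")
    if group_order is not None:
        if sorted(group_order) != groups:
            raise GroupCountError(f"group_order {group_order} does not match labels {groups}")
        groups = list(group_order)
    samples = []
    for g in groups:
        vals = df.loc[df[group_column] == g, metric].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 1:
            raise GroupCountError(f"group {g!r} has no finite values for metric {metric!r}")
        samples.append(vals)
    x, y = samples
    if test == "mannwhitney":
        if x.size <= 8 and y.size <= 8:
            statistic, p = _exact_mannwhitney(x, y)
            test_name = "mannwhitney-exact"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            statistic, p = float(res.statistic), float(res.pvalue)
            test_name = "mannwhitney-asymptotic"
    elif test == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
        test_name = "welch-t"
    else:
        raise ValueError(f"unknown test {test!r}; use 'mannwhitney' or 'welch'")
    means = (float(np.mean(x)), float(np.mean(y)))
    sems = tuple(
        float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        for v in (x, y)
    )
    diff = means[1] - means[0]
    return GroupComparison(
        metric=metric,
        group_labels=(str(groups[0]), str(groups[1])),
        n=(x.size, y.size),
        mean=means,
        median=(float(np.median(x)), float(np.median(y))),
        sem=sems,  # type: ignore[arg-type]
        test_name=test_name,
        statistic=statistic,
        p_value=min(1.0, p),
        direction=int(np.sign(diff)),
    )


def metric_histogram(
    pooled: ClusterTable | pd.DataFrame,
    metric: str,
    bins: np.ndarray | Sequence[float],
    group_column: str = "condition",
) -> pd.DataFrame:
    """Per-group binned counts of one metric over explicit bin edges."""
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be monotonically increasing edges with >= 2 values")
    df = pooled.records if isinstance(pooled, ClusterTable) else pooled
    out = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for g in sorted(df[group_column].unique()):
        vals = df.loc[df[group_column] == g, metric].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        counts, _ = np.histogram(vals, bins=edges)
        out[f"count_{g}"] = counts
    return pd.DataFrame(out)


def segment_cells(marker: Image2D | np.ndarray, min_cell_area_px: int = 200) -> LabeledClusters:
    """Segment whole cell bodies from a marker (YFP) image.

    Global Otsu on the uniformly scaled marker, hole filling, then a
    minimum-area filter; intended for large objects such as cell bodies,
    where a single global threshold suffices.
    """
    px = marker.pixels if isinstance(marker, Image2D) else np.asarray(marker, dtype=float)
    scaled = scale_uniform(px)
    thr = otsu_threshold(scaled)
    params = SegmentationParams(min_area_px=max(1, min_cell_area_px), tile_px=max(px.shape[0], px.shape[1], 8))
    if thr is NO_FOREGROUND:
        return LabeledClusters(np.zeros(px.shape, dtype=int), 0, params)
    mask = ndimage.binary_fill_holes(scaled > thr)
    from .segmentation import label_clusters

    return label_clusters(mask, connectivity=8, min_area_px=min_cell_area_px, params=params)


def total_cell_fluorescence(
    cells: LabeledClusters, target: Image2D | np.ndarray, background: float = 0.0
) -> pd.DataFrame:
    """Background-subtracted total fluorescence per segmented cell.

    Per cell: sum over its pixels of (intensity - background), without
    clamping — the unbiased estimator may go negative, in which case the
    row is flagged.
    """
    px = target.pixels if isinstance(target, Image2D) else np.asarray(target, dtype=float)
    lab = cells.labels
    if lab.shape != px.shape:
        raise ValueError(f"cell labels {lab.shape} and target image {px.shape} must share dimensions")
    n = cells.n_clusters
    if n == 0:
        return pd.DataFrame(columns=["cell_id", "cell_area_px", "total_fluorescence", "flagged_negative"])
    index = np.arange(1, n + 1)
    area = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    totals = ndimage.sum_labels(px - background, labels=lab, index=index)
    return pd.DataFrame(
        {
            "cell_id": index,
            "cell_area_px": area.astype(int),
            "total_fluorescence": totals,
            "flagged_negative": totals < 0,
        }
    )


def spot_recovery(labels: LabeledClusters, centers: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Spot-level (precision, recall) of a labeling against true centers.

    A ground-truth spot is recovered if some cluster contains its center
    pixel; a cluster is a true positive if it contains at least one center.
    Returns (precision, recall); precision is NaN when there are no
    clusters, recall is NaN when there are no spots.
    """
    if isinstance(centers, pd.DataFrame):
        pts = centers[["center_row", "center_col"]].to_numpy(dtype=int)
    else:
        pts = np.asarray(centers, dtype=int).reshape(-1, 2)
    lab = labels.labels
    hit_labels = set()
    recovered = 0
    for r, c in pts:
        lv = int(lab[r, c])
        if lv > 0:
            recovered += 1
            hit_labels.add(lv)
    n_clusters = labels.n_clusters
    precision = len(hit_labels) / n_clusters if n_clusters else float("nan")
    recall = recovered / len(pts) if len(pts) else float("nan")
    return precision, recall
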
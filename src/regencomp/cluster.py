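"""Temporal clustering of fold-change and comparator expression profiles.

The focal-species route clusters the gene x 6-contrast log2 fold-change
matrix with Euclidean distance and Ward's minimum-variance criterion in the
"D2" convention (merge height = sqrt of twice the increase in total
within-cluster sum of squares, as produced by R's hclust ward.D2 on
unsquared Euclidean input). The cut height is chosen automatically by
scanning a grid of heights and taking the smallest at which the cluster
count plateaus; highly correlated clusters are then consolidated and the
survivors classified into the five focal temporal classes (I: up early in
both fragments, II: down early in both, III: anterior-up/posterior-down,
IV: the mirror, V: up late in both).

Comparator datasets arrive either as normalized counts (log2 + z-score, then
ward2) or as range-binned z-scores in {0,1,2} (average linkage), and are cut
to exactly three coarse classes: up_early, down_early, other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .expr import CONTRASTS, DEGTable

_SCIPY_METHOD = {"ward2": "ward", "average": "average"}


@dataclass(frozen=True)
class ClusteringParams:
    metric: str = "euclidean"  # fixed; kept for the record
    linkage: str = "ward2"
    cut_height: float | str = "auto"
    plateau_window: float | None = None  # None -> 5% of the merge-height span
    consolidation_correlation: float = 0.95
    k_coarse: int = 3
    delta: float = 0.25  # log2 threshold for centroid sign calls
    #: temporal log2-SD below which a normalized-count comparator gene is
    #: treated as non-regulated and left out of the coarse clustering,
    #: mirroring comparator datasets that ship a differential-expression call
    comparator_min_sd: float = 0.35

    def __post_init__(self):
        if self.linkage not in _SCIPY_METHOD:
            raise ValueError("linkage must be 'ward2' or 'average'")
        if self.plateau_window is not None and self.plateau_window <= 0:
            raise ValueError("plateau_window must be positive")
        if isinstance(self.cut_height, (int, float)) and self.cut_height <= 0:
            raise ValueError("numeric cut_height must be positive")
        if not 0 < self.consolidation_correlation <= 1:
            raise ValueError("consolidation_correlation must lie in (0, 1]")


@dataclass
class ClusterAssignment:
    """A partition of profiled genes with centroids and optional class labels."""

    labels: pd.Series  # gene -> integer cluster label (1-based, size-ordered)
    data: pd.DataFrame  # the clustered profile matrix (genes x columns)
    classes: dict[int, str] = field(default_factory=dict)

    @property
    def centroids(self) -> pd.DataFrame:
        return self.data.groupby(self.labels).mean()

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def members(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]

    def genes_by_class(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for label, cls in self.classes.items():
            out.setdefault(cls, set()).update(self.members(label))
        return out

    def genes_by_cluster(self) -> dict[str, set]:
        """Per-cluster gene sets keyed "c<label>:<class>" (class if assigned)."""
        out = {}
        for label in sorted(self.labels.unique()):
            cls = self.classes.get(label, "unlabeled")
            out[f"c{label}:{cls}"] = set(self.members(label))
        return out


def build_foldchange_matrix(deg: DEGTable, union: pd.Index) -> pd.DataFrame:
    """Fold-change profiles for the DEG union: every DEG contributes its
    log2FC in all six contrasts, significant or not."""
    if len(union) == 0:
        raise ValueError("DEG union is empty; nothing to cluster")
    return deg.log2fc.loc[union, list(CONTRASTS)].copy()


def euclidean_distance(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between rows."""
    values = np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise ValueError("profile matrix contains missing values")
    return squareform(pdist(values, metric="euclidean"))


def hierarchical_cluster(dist: np.ndarray, linkage: str = "ward2") -> np.ndarray:
    """Agglomerate a distance matrix; returns the scipy merge table Z.

    ``ward2`` applies Ward's minimum-variance update treating the input as
    unsquared Euclidean distances (heights equal sqrt(2 * increase in
    within-cluster SS)); ``average`` is UPGMA. Ties are broken by scipy's
    deterministic nearest-neighbor chain order for a fixed input order.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim == 2:
        if dist.shape[0] < 2:
            raise ValueError("need at least two observations to cluster")
        condensed = squareform(dist, checks=False)
    else:
        condensed = dist
        if condensed.size == 0:
            raise ValueError("need at least two observations to cluster")
    return hierarchy.linkage(condensed, method=_SCIPY_METHOD[linkage])


def select_cut_height(
    Z: np.ndarray, plateau_window: float | None = None, n_grid: int = 200
) -> float:
    """Smallest grid height at which the cluster count is constant over
    [h, h + plateau_window]; the grid spans the merge heights."""
    heights = np.sort(Z[:, 2])
    h_min, h_max = float(heights[0]), float(heights[-1])
    if h_max - h_min <= 1e-12:
        warnings.warn("degenerate dendrogram: all merge heights equal")
        return h_max
    if plateau_window is None:
        plateau_window = 0.05 * (h_max - h_min)
    grid = np.linspace(h_min, h_max, n_grid)
    n_leaves = Z.shape[0] + 1
    counts = n_leaves - np.searchsorted(heights, grid, side="right")
    for i, h in enumerate(grid):
        in_win = counts[(grid >= h) & (grid <= h + plateau_window)]
        if len(in_win) and (in_win == in_win[0]).all():
            return float(h)
    return h_max


def cut_dendrogram(Z: np.ndarray, h: float, data: pd.DataFrame) -> ClusterAssignment:
    """Cut at height h; labels are renumbered by cluster size, descending."""
    raw = hierarchy.fcluster(Z, t=h, criterion="distance")
    return _assignment_from_raw(raw, data)


def _assignment_from_raw(raw: np.ndarray, data: pd.DataFrame) -> ClusterAssignment:
    counts = pd.Series(raw).value_counts()
    order = sorted(counts.index, key=lambda l: (-counts[l], l))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[l] for l in raw], index=data.index, name="cluster")
    return ClusterAssignment(labels=labels, data=data)


def consolidate_clusters(
    assignment: ClusterAssignment, min_correlation: float = 0.95
) -> ClusterAssignment:
    """Iteratively merge the most-correlated centroid pair while its Pearson
    correlation stays at or above ``min_correlation``."""
    labels = assignment.labels.copy()
    while labels.nunique() > 1:
        cent = assignment.data.groupby(labels).mean()
        ids = list(cent.index)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(cent.to_numpy())
        np.fill_diagonal(corr, -np.inf)
        corr = np.nan_to_num(corr, nan=-np.inf)  # constant centroids never merge
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < min_correlation:
            break
        keep, drop = sorted((ids[i], ids[j]))
        labels[labels == drop] = keep
    return _assignment_from_raw(labels.to_numpy(), assignment.data)


_FOCAL_CLASSES = ("I", "II", "III", "IV", "V")


def classify_focal_clusters(
    assignment: ClusterAssignment, delta: float = 0.25
) -> dict[int, str]:
    """Label consolidated focal clusters I-V from centroid signs.

    Centroid columns follow the contrast order (ANT-T0..T2, POST-T0..T2).
    I/II: both fragments up/down early; III/IV: opposite signs between
    fragments (mean over timepoints); V: up late with flat early means;
    anything else is "other".
    """
    classes: dict[int, str] = {}
    for label, c in assignment.centroids.iterrows():
        ant = c.iloc[0:3].to_numpy()
        post = c.iloc[3:6].to_numpy()
        early = 0.5 * (ant[0] + post[0])
        late = 0.5 * (ant[2] + post[2])
        if early > delta and ant[0] > 0 and post[0] > 0:
            cls = "I"
        elif early < -delta and ant[0] < 0 and post[0] < 0:
            cls = "II"
        elif ant.mean() > delta and post.mean() < -delta:
            cls = "III"
        elif ant.mean() < -delta and post.mean() > delta:
            cls = "IV"
        elif late > delta and abs(early) <= delta:
            cls = "V"
        else:
            cls = "other"
        classes[label] = cls
    assignment.classes = classes
    return classes


def zscore_transform(normalized_counts: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), then per-gene z-scores (population SD).

    Constant genes produce all-zero rows (with a warning) rather than NaN.
    """
    logged = np.log2(normalized_counts.astype(float) + 1.0)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s) z-scored to all zeros")
    z = logged.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def bin_zscores(z: pd.DataFrame) -> pd.DataFrame:
    """Per-gene equal-width thirds of the [min, max] range -> bins {0, 1, 2}.

    Boundary ties fall to the lower bin; constant genes map to all 1s.
    """
    values = z.to_numpy(float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = lo + span / 3.0
        e2 = lo + 2.0 * span / 3.0
        bins = np.where(values <= e1, 0, np.where(values <= e2, 1, 2))
    const = (span == 0).ravel()
    bins[const] = 1
    return pd.DataFrame(bins, index=z.index, columns=z.columns)


def coarse_classify_comparator(
    table: pd.DataFrame,
    linkage: str,
    k_coarse: int = 3,
    delta: float = 0.25,
) -> ClusterAssignment:
    """Cluster a transformed comparator table into exactly ``k_coarse``
    clusters and label each by its centroid: up_early when the first half of
    the time course sits above the second half by more than ``delta``,
    down_early for the mirror, otherwise other."""
    if k_coarse > len(table):
        raise ValueError("k_coarse exceeds the number of genes")
    Z = hierarchical_cluster(euclidean_distance(table), linkage=linkage)
    raw = hierarchy.fcluster(Z, t=k_coarse, criterion="maxclust")
    assignment = _assignment_from_raw(raw, table)
    half = table.shape[1] // 2
    classes = {}
    for label, c in assignment.centroids.iterrows():
        drop = c.iloc[:half].mean() - c.iloc[-half:].mean()
        if drop > delta:
            classes[label] = "up_early"
        elif drop < -delta:
            classes[label] = "down_early"
        else:
            classes[label] = "other"
    assignment.classes = classes
    return assignment
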
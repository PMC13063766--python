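"""Bisecting k-means tissue segmentation and plaque object extraction.

The pixel grid is partitioned on per-pixel peptide feature vectors by
divisive clustering: starting from a single cluster, the leaf with the
largest within-cluster sum of squared Euclidean deviations (SSE) is
repeatedly split by 2-means until the requested number of clusters is
reached. Clusters enriched in reference species (canonical A-beta 1-42 and
1-40 by default) are flagged as plaque class, and 4-connected components of
plaque-class pixels become individual plaque objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spectral import AnnotationResult

__all__ = [
    "FeatureMatrix",
    "SplitNode",
    "SegmentationMap",
    "PlaqueObject",
    "PlaqueObjectSet",
    "build_feature_matrix",
    "bisecting_kmeans",
    "cut_hierarchy",
    "label_plaque_clusters",
    "extract_plaque_objects",
]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class FeatureMatrix:
    """Pixels x features matrix with grid coordinates.

    Rows map bijectively to pixel coordinates (1-based imzML convention);
    absent signal is stored as 0, never as missing.
    """

    X: np.ndarray
    coords: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.X.shape != (len(self.coords), len(self.feature_names)):
            raise ValueError("feature matrix shape inconsistent")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class SplitNode:
    node_id: int
    parent: int | None
    sse: float
    n_members: int
    children: tuple[int, int] | None = None
    depth: int = 0


@dataclass
class SegmentationMap:
    """Cluster labels per pixel plus the bisecting-split hierarchy."""

    labels: np.ndarray
    coords: np.ndarray
    k: int
    hierarchy: list[SplitNode] = field(default_factory=list)
    leaf_nodes: dict[int, int] = field(default_factory=dict)  # label -> node id

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")


@dataclass
class PlaqueObject:
    object_id: int
    pixel_rows: np.ndarray
    coords: np.ndarray
    centroid_um: tuple[float, float]
    area_um2: float
    mean_features: np.ndarray


@dataclass
class PlaqueObjectSet:
    objects: list[PlaqueObject]
    feature_names: list[str]
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.objects)


def build_feature_matrix(annotations: AnnotationResult, coords: np.ndarray) -> FeatureMatrix:
    """One column per mass-list variant, TIC-normalised abundances as values.

    Column order follows the mass list; variants undetected everywhere keep
    their all-zero column so feature indices stay aligned across datasets.
    """
    if annotations.abundance.shape[0] == 0:
        raise ValueError("no processed pixels")
    return FeatureMatrix(
        X=annotations.abundance.copy(),
        coords=np.asarray(coords),
        feature_names=list(annotations.variant_names),
    )


def _sse(X: np.ndarray) -> float:
    if len(X) == 0:
        return 0.0
    mu = X.mean(axis=0)
    return float(((X - mu) ** 2).sum())


def _two_means(
    X: np.ndarray, rng: np.random.Generator, n_restarts: int, max_iter: int = 100
) -> np.ndarray:
    """Best-of-restarts Lloyd 2-means with farthest-point seeding.

    Each restart seeds the first centre at a random member and the second at
    the member farthest from it, then iterates assignment/update until the
    partition is stable. Returns the boolean assignment of the best restart
    by SSE. Deterministic given the generator state.
    """
    n = len(X)
    best_assign = None
    best_obj = np.inf
    for _ in range(n_restarts):
        i0 = int(rng.integers(n))
        d0 = ((X - X[i0]) ** 2).sum(axis=1)
        i1 = int(np.argmax(d0))
        centers = np.stack([X[i0], X[i1]])
        assign = None
        sq = (X**2).sum(axis=1)
        for _ in range(max_iter):
            d = sq[:, None] - 2 * X @ centers.T + (centers**2).sum(axis=1)[None, :]
            new_assign = d[:, 1] < d[:, 0]
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for c in (0, 1):
                members = X[assign == bool(c)]
                if len(members) == 0:
                    far = int(np.argmax(d.min(axis=1)))
                    centers[c] = X[far]
                    assign[far] = bool(c)
                else:
                    centers[c] = members.mean(axis=0)
        obj = _sse(X[~assign]) + _sse(X[assign])
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_assign = assign.copy()
    return best_assign


def bisecting_kmeans(
    X: FeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> SegmentationMap:
    """Divisive Euclidean clustering into ``k`` clusters.

    The leaf cluster with the largest SSE is split by 2-means (greedy, best
    of ``n_restarts``) until ``k`` leaves exist; leaves whose members are all
    identical are never split. Deterministic given (X, k, seed, n_restarts).
    """
    if isinstance(X, FeatureMatrix):
        data, coords = X.X, X.coords
    else:
        data = np.asarray(X, dtype=np.float64)
        coords = np.zeros((len(data), 2), dtype=np.int64)
    n_distinct = len(np.unique(data, axis=0))
    if k < 1 or k > n_distinct:
        raise ValueError(f"k must be in [1, {n_distinct}] (number of distinct rows)")
    rng = np.random.default_rng(seed)

    labels = np.zeros(len(data), dtype=np.int64)
    root = SplitNode(node_id=0, parent=None, sse=_sse(data), n_members=len(data), depth=0)
    hierarchy = [root]
    leaf_nodes = {0: 0}  # label -> node id
    while len(leaf_nodes) < k:
        # split the leaf with the highest SSE that is still splittable
        order = sorted(
            leaf_nodes.items(), key=lambda kv: (-hierarchy[kv[1]].sse, kv[0])
        )
        split_label = None
        for label, node_id in order:
            rows = np.nonzero(labels == label)[0]
            if len(np.unique(data[rows], axis=0)) > 1:
                split_label = label
                break
        if split_label is None:
            raise ValueError("no splittable cluster left before reaching k")
        rows = np.nonzero(labels == split_label)[0]
        assign = _two_means(data[rows], rng, n_restarts)
        new_label = max(leaf_nodes) + 1
        labels[rows[assign]] = new_label
        parent_id = leaf_nodes[split_label]
        parent = hierarchy[parent_id]
        left = SplitNode(
            node_id=len(hierarchy), parent=parent_id,
            sse=_sse(data[rows[~assign]]), n_members=int((~assign).sum()),
            depth=parent.depth + 1,
        )
        hierarchy.append(left)
        right = SplitNode(
            node_id=len(hierarchy), parent=parent_id,
            sse=_sse(data[rows[assign]]), n_members=int(assign.sum()),
            depth=parent.depth + 1,
        )
        hierarchy.append(right)
        parent.children = (left.node_id, right.node_id)
        leaf_nodes[split_label] = left.node_id
        leaf_nodes[new_label] = right.node_id

    # relabel to compact contiguous ids ordered by label value
    remap = {old: i for i, old in enumerate(sorted(leaf_nodes))}
    labels = np.array([remap[l] for l in labels])
    leaf_nodes = {remap[l]: nid for l, nid in leaf_nodes.items()}
    return SegmentationMap(labels=labels, coords=coords, k=len(leaf_nodes),
                           hierarchy=hierarchy, leaf_nodes=leaf_nodes)


def cut_hierarchy(seg: SegmentationMap, depth: int) -> np.ndarray:
    """Labels of the hierarchy cut at a given split depth.

    ``depth=0`` returns a single cluster; the maximal depth reproduces the
    full map. The half-depth cut corresponds to a coarse ("50 %")
    segmentation map.
    """
    ancestors = {}

    def climb(node_id: int) -> int:
        node = seg.hierarchy[node_id]
        while node.depth > depth:
            node = seg.hierarchy[node.parent]
        return node.node_id

    out = np.empty_like(seg.labels)
    cut_ids: dict[int, int] = {}
    for label, node_id in seg.leaf_nodes.items():
        cid = climb(node_id)
        if cid not in cut_ids:
            cut_ids[cid] = len(cut_ids)
        ancestors[label] = cut_ids[cid]
    for label, cut_label in ancestors.items():
        out[seg.labels == label] = cut_label
    return out


def label_plaque_clusters(
    seg: SegmentationMap,
    X: FeatureMatrix,
    reference_variants: list[str] | None = None,
    enrichment: float = 3.0,
    min_detected_fraction: float = 0.25,
) -> set[int]:
    """Clusters enriched in reference A-beta species (plaque class).

    A cluster is flagged when its mean abundance over the reference variants
    exceeds ``enrichment`` times the grand mean and at least
    ``min_detected_fraction`` of its pixels carry any reference signal; the
    latter guards against flagging noise-only clusters in A-beta-negative
    control tissue. If any cluster satisfies the support condition, the one
    with the highest enrichment statistic is always flagged.
    """
    if reference_variants is None:
        reference_variants = [n for n in X.feature_names if n in ("Abeta1-42", "Abeta1-40")]
    ref_idx = [X.feature_names.index(n) for n in reference_variants]
    if not ref_idx:
        raise ValueError("no reference variants present in the feature matrix")
    ref = X.X[:, ref_idx].mean(axis=1)
    grand = ref.mean()
    if grand <= 0:
        warnings.warn("reference signal is zero everywhere; no plaque clusters")
        return set()
    flagged: set[int] = set()
    stats = {}
    for label in range(seg.k):
        rows = seg.labels == label
        support = float((X.X[rows][:, ref_idx].max(axis=1) > 0).mean())
        if support < min_detected_fraction:
            continue
        stats[label] = ref[rows].mean() / grand
        if stats[label] > enrichment:
            flagged.add(label)
    if not flagged and stats:
        flagged.add(max(stats, key=stats.get))
    if not stats:
        warnings.warn("no cluster has supported reference signal; no plaque clusters")
    return flagged


def extract_plaque_objects(
    seg: SegmentationMap,
    plaque_classes: set[int],
    pixel_size_um: float,
    min_pixels: int = 2,
    X: FeatureMatrix | None = None,
) -> PlaqueObjectSet:
    """4-connected components of plaque-class pixels as individual objects.

    Components smaller than ``min_pixels`` are dropped (single-pixel objects
    are unstable at 20 um resolution). Areas are pixel count times pixel
    area; centroids are micron coordinates of pixel centers.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    ny = int(seg.coords[:, 1].max())
    nx = int(seg.coords[:, 0].max())
    mask = np.zeros((ny, nx), dtype=bool)
    row_of = -np.ones((ny, nx), dtype=np.int64)
    for label in plaque_classes:
        rows = np.nonzero(seg.labels == label)[0]
        mask[seg.coords[rows, 1] - 1, seg.coords[rows, 0] - 1] = True
    row_of[seg.coords[:, 1] - 1, seg.coords[:, 0] - 1] = np.arange(len(seg.coords))
    labeled, n_obj = ndimage.label(mask, structure=FOUR_CONNECTED)
    objects: list[PlaqueObject] = []
    feature_names = X.feature_names if X is not None else []
    next_id = 1
    for obj in range(1, n_obj + 1):
        ys, xs = np.nonzero(labeled == obj)
        if len(ys) < min_pixels:
            continue
        rows = row_of[ys, xs]
        centroid = (
            float((xs + 0.5).mean() * pixel_size_um),
            float((ys + 0.5).mean() * pixel_size_um),
        )
        mean_features = (
            X.X[rows].mean(axis=0) if X is not None else np.empty(0)
        )
        objects.append(
            PlaqueObject(
                object_id=next_id,
                pixel_rows=rows,
                coords=np.column_stack([xs + 1, ys + 1]),
                centroid_um=centroid,
                area_um2=len(ys) * pixel_size_um**2,
                mean_features=mean_features,
            )
        )
        next_id += 1
    return PlaqueObjectSet(objects=objects, feature_names=feature_names,
                           pixel_size_um=pixel_size_um)
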
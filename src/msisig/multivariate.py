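"""Multivariate exploration: supervised PCA and bisecting k-means segmentation.

PCA is computed on group-labeled ROI pixels (tumor-cell-rich regions) after
level scaling, i.e. each feature is mean-centered and divided by its mean,
``(x - m) / m``.  Level scaling expresses every feature as a relative change
from its average, which suits intensity data whose uncertainty grows with the
mean.  "Supervised" here means the decomposition is computed on the labeled
pixel subset and the scores carry the group labels for separation diagnostics;
the decomposition itself is ordinary PCA.

Spatial segmentation is top-down bisecting k-means: starting from one cluster,
the leaf with the largest within-cluster sum of squares is repeatedly split by
2-means until ``k`` leaves exist.  Splits are seeded deterministically by
farthest-point initialization, so segmentations are reproducible.  With
``spatial_smoothing="medium"`` each feature image is Gaussian-smoothed
(sigma = 1 pixel) before clustering, suppressing single-pixel speckle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .peakalign import Datacube

__all__ = [
    "PCAResult",
    "SegmentationResult",
    "level_scale",
    "run_pca",
    "bisect_kmeans",
]


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_labeled_pixels, n_components)
    loadings: np.ndarray  # (n_features, n_components)
    explained_fraction: np.ndarray  # per component, in [0, 1]
    group_labels: np.ndarray | None = None  # aligned with score rows
    mean: np.ndarray | None = None  # feature means of the decomposed data


@dataclass
class SegmentationResult:
    """Pixel labels plus the bisecting history (one entry per split)."""

    labels: np.ndarray  # (n_pixels,) integer cluster ids
    tree: list[dict] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(np.unique(self.labels))


def level_scale(cube: Datacube) -> Datacube:
    """Transform each feature to (x - mean) / mean; requires positive feature means."""
    means = cube.matrix.mean(axis=0)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"feature m/z {cube.feature_mzs[bad[0]]:.4f} has non-positive mean; "
            "drop empty features before level scaling"
        )
    return cube.replace((cube.matrix - means) / means)


def run_pca(
    cube: Datacube,
    n_components: int = 5,
    group_labels: np.ndarray | list | None = None,
) -> PCAResult:
    """PCA of a (level-scaled) datacube, restricted to group-labeled pixels.

    ``group_labels`` is one entry per cube row; rows whose label is None (or
    NaN) are excluded from the decomposition.  Explained variance fractions
    are relative to the total variance of the decomposed subset, so they sum
    to 1 over all possible components.
    """
    X = cube.matrix
    labels = None
    if group_labels is not None:
        labels = np.asarray(group_labels, dtype=object)
        if len(labels) != X.shape[0]:
            raise ValueError("group_labels length must match pixel count")
        keep = np.array([lab is not None and lab == lab for lab in labels])
        X = X[keep]
        labels = labels[keep]
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} labeled pixels is fewer than {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_fraction=pca.explained_variance_ratio_,
        group_labels=labels,
        mean=pca.mean_,
    )


def _smoothed_matrix(cube: Datacube, sigma: float) -> np.ndarray:
    """Gaussian-smooth each feature as a pixel image, respecting missing pixels."""
    x = cube.pixel_index["x"].to_numpy(dtype=int)
    y = cube.pixel_index["y"].to_numpy(dtype=int)
    xi, yi = x - x.min(), y - y.min()
    h, w = yi.max() + 1, xi.max() + 1
    mask = np.zeros((h, w))
    mask[yi, xi] = 1.0
    sm_mask = gaussian_filter(mask, sigma)
    out = np.empty_like(cube.matrix)
    img = np.zeros((h, w))
    for j in range(cube.n_features):
        img[:] = 0.0
        img[yi, xi] = cube.matrix[:, j]
        sm = gaussian_filter(img, sigma)
        out[:, j] = sm[yi, xi] / sm_mask[yi, xi]
    return out


def _wcss(X: np.ndarray) -> float:
    return float(((X - X.mean(axis=0)) ** 2).sum())


def bisect_kmeans(
    cube: Datacube,
    k: int,
    spatial_smoothing: str = "none",
    seed: int = 0,
) -> SegmentationResult:
    """Top-down bisecting k-means segmentation of the datacube pixels."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = cube.n_pixels
    if k > n:
        raise ValueError(f"k={k} exceeds pixel count {n}")
    if spatial_smoothing not in ("none", "medium"):
        raise ValueError(f"unknown smoothing {spatial_smoothing!r}")
    X = cube.matrix if spatial_smoothing == "none" else _smoothed_matrix(cube, sigma=1.0)

    labels = np.zeros(n, dtype=int)
    tree: list[dict] = []
    next_label = 1
    for _ in range(k - 1):
        leaves = np.unique(labels)
        scores = []
        for leaf in leaves:
            idx = np.flatnonzero(labels == leaf)
            scores.append(_wcss(X[idx]) if idx.size >= 2 else -1.0)
        order = np.argsort([-s for s in scores], kind="stable")
        parent = None
        for pos in order:
            if np.count_nonzero(labels == leaves[pos]) >= 2:
                parent = int(leaves[pos])
                parent_wcss = scores[pos]
                break
        if parent is None:  # every leaf is a singleton; cannot happen for k <= n
            raise ValueError("no splittable cluster left")
        idx = np.flatnonzero(labels == parent)
        sub = X[idx]
        if parent_wcss <= 0.0:
            # degenerate leaf (all points identical): split off the first point
            child_mask = np.zeros(idx.size, dtype=bool)
            child_mask[0] = True
        else:
            center = sub.mean(axis=0)
            c1 = int(np.argmax(((sub - center) ** 2).sum(axis=1)))
            c2 = int(np.argmax(((sub - sub[c1]) ** 2).sum(axis=1)))
            km = KMeans(
                n_clusters=2,
                init=np.vstack([sub[c1], sub[c2]]),
                n_init=1,
                random_state=seed,
            ).fit(sub)
            child_mask = km.labels_ == 1
            if child_mask.all() or not child_mask.any():  # safety: force a real split
                child_mask = np.zeros(idx.size, dtype=bool)
                child_mask[c2] = True
        labels[idx[child_mask]] = next_label
        tree.append(
            {
                "step": len(tree),
                "parent": parent,
                "children": (parent, next_label),
                "parent_wcss": parent_wcss,
            }
        )
        next_label += 1
    return SegmentationResult(labels=labels, tree=tree)
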
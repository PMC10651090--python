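"""Melanistic-pattern segmentation by k-means++-initialized bisecting k-means.

Every foreground pixel is treated as a point in RGB space and clustered with
k-means (k=2 by default, Lloyd iterations, k-means++ seeding).  The cluster
whose center has the lower weighted-RGB luminance is labelled melanistic.
"Hierarchical" clustering is implemented as bisecting k-means — each cluster
is recursively re-split up to ``max_depth``; the default depth of 1 with k=2
is a single binary split, which deliberately avoids overestimating melanin by
fragmenting the light class.

An image whose two cluster centers differ by less than a contrast threshold
has no separable dark pattern: the result is flagged ``low_contrast`` and the
melanistic mask is left empty (proportion 0), which is the correct reading
for near-patternless individuals rather than an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .imaging import ImageRecord, luminance, rgb_to_hls, REC601_WEIGHTS

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "foreground_mask",
    "kmeanspp_init",
    "kmeans",
    "PatternKMeans",
    "segment_pattern",
    "qc_overlay",
    "read_qc_flag",
]


@dataclass
class SegmentationConfig:
    """Knobs for foreground extraction and clustering.

    bg_lightness_threshold separates the pale arena background (HLS lightness
    near 1) from animal pixels; contrast_threshold is the minimum luminance
    separation between cluster centers for a pattern to count as present
    (default 10/255 in [0,1] luminance units).
    """

    k: int = 2
    max_depth: int = 1
    tol: float = 1e-4
    max_iter: int = 100
    seed: int = 0
    n_init: int = 1
    bg_lightness_threshold: float = 0.92
    contrast_threshold: float = 10.0 / 255.0
    lum_weights: tuple[float, float, float] = REC601_WEIGHTS

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0.0 <= self.bg_lightness_threshold <= 1.0):
            raise ValueError("bg_lightness_threshold must lie in [0, 1]")
        if not (0.0 <= self.contrast_threshold <= 1.0):
            raise ValueError("contrast_threshold must lie in [0, 1]")


@dataclass
class SegmentationResult:
    """Binary melanistic mask plus clustering diagnostics for one image."""

    melanistic_mask: np.ndarray
    foreground_mask: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    inertia: float
    low_contrast: bool
    qc_accepted: bool | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.melanistic_mask & ~self.foreground_mask).any():
            raise ValueError("melanistic_mask must be a subset of foreground_mask")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")
        if self.low_contrast and self.melanistic_mask.any():
            raise ValueError("low-contrast result must have an empty melanistic mask")

    @property
    def melanistic_proportion(self) -> float:
        n_fg = int(self.foreground_mask.sum())
        return float(self.melanistic_mask.sum()) / n_fg if n_fg else 0.0


def foreground_mask(img: ImageRecord, cfg: SegmentationConfig) -> np.ndarray:
    """Animal pixels: inside the ROI with HLS lightness below the background threshold.

    For a lightness-standardized record (one carrying a ``lightness_gain`` in
    its metadata) the threshold is also applied to the pre-standardization
    lightness ``L / gain``: a pale background that overexposed at capture
    clips to pure white and a gain below 1 then drags it under the threshold,
    but such pixels are unrecoverable and are still background.
    """
    if not img.roi.any():
        raise ValueError("ROI is empty")
    L = rgb_to_hls(img.pixels)[..., 1]
    bright = L >= cfg.bg_lightness_threshold
    gain = float(img.meta.get("lightness_gain", 1.0))
    if gain < 1.0:
        bright |= (L / gain) >= cfg.bg_lightness_threshold
    mask = img.roi & ~bright
    if not mask.any():
        raise ValueError("no foreground pixels found in ROI (animal not detected)")
    return mask


def kmeanspp_init(pixels: np.ndarray, k: int, rng: np.random.Generator | int) -> np.ndarray:
    """k-means++ seeding: first center uniform, each next drawn with
    probability proportional to squared distance to the nearest chosen center.
    Deterministic given the seed."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("pixels must be an (n, d) array")
    if np.unique(pixels, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct pixels for k={k}")
    rng = np.random.default_rng(rng)
    n = pixels.shape[0]
    centers = np.empty((k, pixels.shape[1]))
    centers[0] = pixels[rng.integers(n)]
    d2 = ((pixels - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # duplicates of chosen centers only; pick any new distinct point
            remaining = np.flatnonzero(d2 > 0)
            idx = rng.choice(remaining) if remaining.size else rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[j] = pixels[idx]
        d2 = np.minimum(d2, ((pixels - centers[j]) ** 2).sum(axis=1))
    return centers


def _assign(pixels: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # squared Euclidean distances to each center, (n, k)
    d2 = ((pixels[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return labels, d2[np.arange(len(labels)), labels]


def kmeans(
    pixels: np.ndarray,
    centers: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Lloyd's algorithm from given initial centers.

    Stops when the maximum center movement drops below ``tol`` or after
    ``max_iter`` sweeps.  Inertia (sum of squared distances to assigned
    centers) is asserted non-increasing every iteration.  An emptied cluster
    is re-seeded at the point farthest from its assigned center.

    Returns ``(centers, labels, inertia, n_iter)``.
    """
    pixels = np.asarray(pixels, dtype=float)
    centers = np.array(centers, dtype=float, copy=True)
    k = centers.shape[0]
    labels, d2 = _assign(pixels, centers)
    inertia = float(d2.sum())
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_centers = centers.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centers[j] = pixels[members].mean(axis=0)
            else:
                new_centers[j] = pixels[d2.argmax()]  # farthest-point re-seed
        labels, d2 = _assign(pixels, new_centers)
        new_inertia = float(d2.sum())
        assert new_inertia <= inertia + 1e-9, "k-means inertia increased"
        movement = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers, inertia = new_centers, new_inertia
        if movement < tol:
            break
    return centers, labels, inertia, n_iter


def _cluster_once(pixels: np.ndarray, cfg: SegmentationConfig, rng: np.random.Generator):
    """Best-of-n_init k-means++ runs on one pixel set."""
    best = None
    for _ in range(max(1, cfg.n_init)):
        init = kmeanspp_init(pixels, cfg.k, rng)
        centers, labels, inertia, _ = kmeans(pixels, init, cfg.tol, cfg.max_iter)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    return best


class PatternKMeans(BaseEstimator, ClusterMixin):
    """Bisecting k-means clusterer over pixel colors.

    At each level every current cluster with at least ``k`` distinct points is
    re-split into ``k`` sub-clusters (k-means++ init, Lloyd refinement);
    recursion proceeds to ``max_depth`` levels.  ``max_depth=1`` is plain
    k-means with ``k`` clusters.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : ndarray (n_clusters, 3)
    labels_ : ndarray (n_pixels,)
    inertia_ : float — sum of squared distances to final centers.
    """

    def __init__(self, k: int = 2, max_depth: int = 1, tol: float = 1e-4,
                 max_iter: int = 100, n_init: int = 1, seed: int = 0):
        self.k = k
        self.max_depth = max_depth
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.seed = seed

    def fit(self, X: np.ndarray, y=None) -> "PatternKMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be an (n_pixels, n_channels) array")
        cfg = SegmentationConfig(
            k=self.k, max_depth=self.max_depth, tol=self.tol,
            max_iter=self.max_iter, n_init=self.n_init, seed=self.seed,
        )
        rng = np.random.default_rng(self.seed)
        # leaves: list of (member_index_array, center)
        leaves = [(np.arange(X.shape[0]), X.mean(axis=0))]
        for _ in range(self.max_depth):
            next_leaves = []
            for idx, center in leaves:
                sub = X[idx]
                if np.unique(sub, axis=0).shape[0] < self.k:
                    next_leaves.append((idx, center))
                    continue
                centers, labels, _ = _cluster_once(sub, cfg, rng)
                for j in range(self.k):
                    members = idx[labels == j]
                    if members.size:
                        next_leaves.append((members, X[members].mean(axis=0)))
            leaves = next_leaves
        self.cluster_centers_ = np.array([c for _, c in leaves])
        labels = np.empty(X.shape[0], dtype=int)
        for j, (idx, _) in enumerate(leaves):
            labels[idx] = j
        self.labels_ = labels
        diffs = X - self.cluster_centers_[labels]
        self.inertia_ = float((diffs ** 2).sum())
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        labels, _ = _assign(X, self.cluster_centers_)
        return labels


def segment_pattern(img: ImageRecord, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Full per-image segmentation: foreground -> clustering -> melanistic labelling.

    The cluster whose center has the lowest weighted-RGB luminance is the
    melanistic class.  If the darkest and lightest center luminances differ by
    less than ``cfg.contrast_threshold`` the image has no separable pattern:
    ``low_contrast`` is set and the melanistic mask is empty.
    """
    cfg = cfg or SegmentationConfig()
    fg = foreground_mask(img, cfg)
    pixels = img.pixels[fg]

    model = PatternKMeans(
        k=cfg.k, max_depth=cfg.max_depth, tol=cfg.tol,
        max_iter=cfg.max_iter, n_init=cfg.n_init, seed=cfg.seed,
    )
    h, w = img.shape
    empty = np.zeros((h, w), dtype=bool)
    try:
        model.fit(pixels)
    except ValueError:
        # fewer distinct colors than k: uniform foreground, no pattern
        center = pixels.mean(axis=0)
        return SegmentationResult(
            melanistic_mask=empty, foreground_mask=fg,
            centers=np.array([center]), labels=np.zeros(len(pixels), dtype=int),
            inertia=float(((pixels - center) ** 2).sum()),
            low_contrast=True, meta={"seed": cfg.seed},
        )

    lum = luminance(np.clip(model.cluster_centers_, 0.0, 1.0), cfg.lum_weights)
    order = np.argsort(lum)
    contrast = float(lum[order[-1]] - lum[order[0]])
    low_contrast = contrast < cfg.contrast_threshold

    mel_mask = empty.copy()
    if not low_contrast:
        dark = order[0]
        fg_idx = np.flatnonzero(fg.ravel())
        mel_flat = np.zeros(h * w, dtype=bool)
        mel_flat[fg_idx[model.labels_ == dark]] = True
        mel_mask = mel_flat.reshape(h, w)

    return SegmentationResult(
        melanistic_mask=mel_mask,
        foreground_mask=fg,
        centers=model.cluster_centers_,
        labels=model.labels_,
        inertia=model.inertia_,
        low_contrast=low_contrast,
        meta={"seed": cfg.seed, "center_contrast": contrast},
    )


def qc_overlay(img: ImageRecord, result: SegmentationResult, out_path: str | Path) -> Path:
    """Write a side-by-side original/segmentation overlay plus an editable QC flag.

    The overlay (PNG) shows the original frame next to a copy with the
    melanistic mask tinted red and the foreground outlined; the JSON flag file
    next to it starts as ``{"accepted": null}`` so a reviewer can set it to
    true/false.  Returns the flag-file path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    overlay = img.pixels.copy()
    overlay[result.melanistic_mask] = [1.0, 0.1, 0.1]
    overlay[result.foreground_mask & ~result.melanistic_mask] *= [0.7, 1.0, 0.7]

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].imshow(img.pixels)
    axes[0].set_title(f"{img.individual_id} #{img.seq_index}")
    axes[1].imshow(np.clip(overlay, 0, 1))
    title = "low contrast (no pattern)" if result.low_contrast else (
        f"proportion {result.melanistic_proportion:.3f}")
    axes[1].set_title(title)
    for ax in axes:
        ax.axis("off")
    fig.savefig(out_path, dpi=100, bbox_inches="tight")
    plt.close(fig)

    flag_path = out_path.with_suffix(".qc.json")
    if not flag_path.exists():
        flag_path.write_text(json.dumps({
            "individual_id": img.individual_id,
            "seq_index": img.seq_index,
            "accepted": None,
        }, indent=2))
    return flag_path


def read_qc_flag(flag_path: str | Path) -> bool | None:
    """Read a reviewer-set QC flag; ``None`` means not yet reviewed."""
    data = json.loads(Path(flag_path).read_text())
    return data.get("accepted")
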
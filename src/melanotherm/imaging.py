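"""Image I/O, HLS color math, luminance, and within-individual lightness
standardization against a grayscale reference patch.

Repeat photographs of the same animal drift in illumination between frames.
Because a neutral (gray) standard is present in every frame, the lightness
channel of each frame can be rescaled so that the standard's mean lightness
matches that of the individual's first frame.  The correction is a
multiplicative gain on the HLS lightness channel: illumination intensity acts
multiplicatively on lightness, so a gain (rather than an offset) cancels a
global intensity change exactly.

Standardization is strictly within-individual: a baseline fitted on one
individual's first image refuses to transform another individual's frames
unless explicitly overridden, because gains anchored to different baseline
exposures are not comparable across animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ImageRecord",
    "RefStats",
    "REC601_WEIGHTS",
    "REC709_WEIGHTS",
    "read_image",
    "rgb_to_hls",
    "hls_to_rgb",
    "luminance",
    "extract_reference_stats",
    "standardize_lightness",
    "LightnessStandardizer",
]

logger = logging.getLogger(__name__)

#: Rec.601 luma weights (R, G, B) — the default photometric brightness proxy.
REC601_WEIGHTS = (0.299, 0.587, 0.114)
#: Rec.709 luma weights, available as a one-line config swap.
REC709_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class RefStats:
    """Summary of the grayscale reference patch: mean HLS lightness and size."""

    mean_lightness: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("reference patch must contain at least one pixel")
        if not 0.0 <= self.mean_lightness <= 1.0:
            raise ValueError("mean_lightness must lie in [0, 1]")


@dataclass
class ImageRecord:
    """One timestamped RGB photograph of one individual.

    Parameters
    ----------
    individual_id : str
        Identifier of the photographed animal.
    seq_index : int
        1-based position of this frame in the individual's time series.
    block : int
        Experimental block label (1-5).
    pixels : ndarray of shape (H, W, 3)
        RGB raster with channel values in [0, 1].
    ref_region : tuple (row0, col0, row1, col1)
        Half-open rectangle (origin top-left, row-major) covering the
        grayscale reference patch.
    roi : ndarray of bool, shape (H, W)
        Mask delimiting the dorsal region of interest (head + trunk + tail).
    """

    individual_id: str
    seq_index: int
    block: int
    pixels: np.ndarray
    ref_region: tuple[int, int, int, int]
    roi: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel channel values must lie in [0, 1]")
        h, w = self.pixels.shape[:2]
        r0, c0, r1, c1 = self.ref_region
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(
                f"ref_region {self.ref_region} outside image bounds {(h, w)}"
            )
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.roi.shape != (h, w):
            raise ValueError("roi mask must match image shape")
        if self.roi[r0:r1, c0:c1].any():
            raise ValueError("ref_region and roi must not overlap")
        if not (1 <= self.block <= 5):
            raise ValueError("block must be in 1..5")
        if self.seq_index < 1:
            raise ValueError("seq_index is 1-based")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def ref_pixels(self) -> np.ndarray:
        r0, c0, r1, c1 = self.ref_region
        return self.pixels[r0:r1, c0:c1].reshape(-1, 3)


def read_image(
    path: str | Path,
    ref_region: tuple[int, int, int, int],
    roi: np.ndarray,
    *,
    individual_id: str = "",
    seq_index: int = 1,
    block: int = 1,
) -> ImageRecord:
    """Read an 8-bit (or 16-bit) RGB image file into an :class:`ImageRecord`.

    Channel values are rescaled to [0, 1] (by 255 for 8-bit input, 65535 for
    16-bit).  Geometry (``ref_region`` inside bounds, ``roi`` aligned and
    disjoint from the reference patch) is validated on construction.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        pixels = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(float) / 65535.0
    else:
        raise ValueError(f"unsupported image dtype {arr.dtype}; expected 8/16-bit")
    return ImageRecord(
        individual_id=individual_id,
        seq_index=seq_index,
        block=block,
        pixels=pixels,
        ref_region=tuple(int(v) for v in ref_region),
        roi=roi,
    )


def _check_unit_range(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
        raise ValueError(f"{name} components must lie in [0, 1]")
    return np.clip(arr, 0.0, 1.0)


def rgb_to_hls(rgb: np.ndarray) -> np.ndarray:
    """Convert RGB in [0,1] to hexcone HLS: H in degrees [0, 360), L, S in [0,1].

    Accepts a single triple or an (..., 3) array.  L = (max+min)/2; S = 0 for
    achromatic pixels, else (max-min)/(1-|2L-1|); H by hexagonal sector with
    H = 0 for achromatic pixels by convention.
    """
    rgb = _check_unit_range(rgb, "rgb")
    r, g, b = np.moveaxis(rgb, -1, 0)
    cmax = np.maximum(np.maximum(r, g), b)
    cmin = np.minimum(np.minimum(r, g), b)
    delta = cmax - cmin
    L = (cmax + cmin) / 2.0

    S = np.zeros_like(L)
    chromatic = delta > 0
    denom = 1.0 - np.abs(2.0 * L - 1.0)
    np.divide(delta, denom, out=S, where=chromatic & (denom > 0))

    H = np.zeros_like(L)
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.mod((g - b) / delta, 6.0)
        hg = (b - r) / delta + 2.0
        hb = (r - g) / delta + 4.0
    H = np.where(cmax == r, hr, np.where(cmax == g, hg, hb))
    H = np.where(chromatic, H * 60.0, 0.0)
    H = np.mod(H, 360.0)
    # guard against float rounding near the gamut boundary
    S = np.clip(S, 0.0, 1.0)
    L = np.clip(L, 0.0, 1.0)
    return np.stack([H, L, S], axis=-1)


def hls_to_rgb(hls: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hls` on its range (H degrees, L, S in [0,1])."""
    hls = np.asarray(hls, dtype=float)
    H, L, S = np.moveaxis(hls, -1, 0)
    if np.any((L < -1e-12) | (L > 1 + 1e-12) | (S < -1e-12) | (S > 1 + 1e-12)):
        raise ValueError("L and S must lie in [0, 1]")
    if np.any((H < 0) | (H >= 360.0)):
        raise ValueError("H must lie in [0, 360)")
    C = (1.0 - np.abs(2.0 * L - 1.0)) * S
    Hp = H / 60.0
    X = C * (1.0 - np.abs(np.mod(Hp, 2.0) - 1.0))
    z = np.zeros_like(C)
    sector = np.floor(Hp).astype(int) % 6
    r1 = np.choose(sector, [C, X, z, z, X, C])
    g1 = np.choose(sector, [X, C, C, X, z, z])
    b1 = np.choose(sector, [z, z, X, C, C, X])
    m = L - C / 2.0
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1)
    return np.clip(rgb, 0.0, 1.0)


def luminance(rgb: np.ndarray, weights: Sequence[float] = REC601_WEIGHTS) -> np.ndarray:
    """Weighted-RGB luminance: wR*R + wG*G + wB*B on [0,1] channels.

    The weighting is the configurable photometric brightness proxy; the
    default is Rec.601 (0.299, 0.587, 0.114).  Monotone non-decreasing in
    every channel for non-negative weights.
    """
    rgb = _check_unit_range(rgb, "rgb")
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < 0).any():
        raise ValueError("weights must be three non-negative numbers")
    return rgb @ w


def extract_reference_stats(img: ImageRecord) -> RefStats:
    """Mean HLS lightness over the grayscale reference patch."""
    ref = img.ref_pixels()
    if ref.size == 0:
        raise ValueError("reference region is empty")
    L = rgb_to_hls(ref)[:, 1]
    return RefStats(mean_lightness=float(L.mean()), n_pixels=ref.shape[0])


_MIN_REF_LIGHTNESS = 1e-6


class LightnessStandardizer(BaseEstimator, TransformerMixin):
    """Standardize HLS lightness of an individual's frames to a baseline.

    ``fit`` takes the individual's first (baseline) :class:`ImageRecord` and
    stores the mean lightness of its grayscale reference patch.  ``transform``
    multiplies every pixel's lightness in a later frame by the gain

        g = baseline_ref_mean_L / current_ref_mean_L

    (clipped to [0, 1]) so the reference patch matches the baseline, then
    converts back to RGB.  Transforming a frame from a different individual
    raises unless ``allow_cross_individual=True``.

    Attributes
    ----------
    baseline_ : RefStats
        Reference-patch statistics of the baseline frame.
    individual_id_ : str
        Individual the baseline belongs to.
    n_clipped_ : int
        Number of lightness values clipped during the most recent transform.
    """

    def __init__(self, allow_cross_individual: bool = False):
        self.allow_cross_individual = allow_cross_individual

    def fit(self, img: ImageRecord, y=None) -> "LightnessStandardizer":
        baseline = extract_reference_stats(img)
        if baseline.mean_lightness <= _MIN_REF_LIGHTNESS:
            raise ValueError("baseline reference patch is black; gain undefined")
        self.baseline_ = baseline
        self.individual_id_ = img.individual_id
        self.n_clipped_ = 0
        return self

    def transform(self, img: ImageRecord) -> ImageRecord:
        if not hasattr(self, "baseline_"):
            raise RuntimeError("LightnessStandardizer is not fitted")
        if (
            img.individual_id != self.individual_id_
            and not self.allow_cross_individual
        ):
            raise ValueError(
                "refusing to standardize a frame of individual "
                f"{img.individual_id!r} against the baseline of "
                f"{self.individual_id_!r}; lightness gains are only comparable "
                "within an individual (set allow_cross_individual=True to override)"
            )
        current = extract_reference_stats(img)
        if current.mean_lightness <= _MIN_REF_LIGHTNESS:
            raise ValueError("current reference patch is black; gain undefined")
        gain = self.baseline_.mean_lightness / current.mean_lightness
        hls = rgb_to_hls(img.pixels)
        scaled = hls[..., 1] * gain
        n_clipped = int(np.count_nonzero((scaled < 0.0) | (scaled > 1.0)))
        self.n_clipped_ = n_clipped
        if n_clipped:
            logger.warning(
                "standardize_lightness: %d pixel(s) clipped (gain=%.4f, %s #%d)",
                n_clipped, gain, img.individual_id, img.seq_index,
            )
        hls[..., 1] = np.clip(scaled, 0.0, 1.0)
        out = hls_to_rgb(hls)
        rec = replace(img, pixels=out)
        rec.meta = dict(img.meta, lightness_gain=gain, n_clipped=n_clipped)
        return rec


def standardize_lightness(img: ImageRecord, baseline: RefStats) -> ImageRecord:
    """Functional wrapper over :class:`LightnessStandardizer` for a known baseline."""
    st = LightnessStandardizer()
    if baseline.mean_lightness <= _MIN_REF_LIGHTNESS:
        raise ValueError("baseline reference patch is black; gain undefined")
    st.baseline_ = baseline
    st.individual_id_ = img.individual_id
    st.n_clipped_ = 0
    return st.transform(img)
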
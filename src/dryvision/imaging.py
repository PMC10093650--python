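"""Binary segmentation and particle analysis for drying-sample frames.

The processing chain mirrors an online machine-vision monitor for samples on a
dark background: RGB frames are reduced to grayscale by the channel mean,
binarized at a histogram-derived threshold (metric thresholding: the gray level
minimizing the count-weighted sum of absolute deviations of each class from its
class mean), and the resulting foreground particles are hole-filled (drying
bubbles read as dark interior holes), size-filtered (dust specks), and summed
into a pixel area.

All operations are pure functions on numpy arrays; :func:`segment_frame` runs
the whole chain on one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DegenerateHistogramError",
    "ThresholdResult",
    "ParticleSet",
    "SegmentedFrame",
    "to_grayscale",
    "histogram",
    "metric_threshold",
    "binarize",
    "to_display",
    "label_particles",
    "fill_holes",
    "filter_particles",
    "total_area",
    "segment_frame",
]

N_LEVELS = 256

# 8-connectivity for foreground particles; background holes are then
# 4-connected (the complementary pairing, so a diagonal foreground chain
# still encloses a hole).
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


class DegenerateHistogramError(ValueError):
    """All pixels occupy a single gray level: no two-class split exists."""


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of metric thresholding.

    Attributes
    ----------
    k : int
        Selected threshold; levels <= k are background, > k foreground.
    cost : float
        Minimized sum of count-weighted absolute deviations.
    mu1, mu2 : float
        Count-weighted mean gray level of the low (<= k) and high (> k) class.
    """

    k: int
    cost: float
    mu1: float
    mu2: float


@dataclass
class ParticleSet:
    """Labeled 8-connected foreground components of a binary mask.

    ``labels`` holds 0 for background and 1..u for particles; ``counts[j-1]``
    is the pixel count of particle j; ``bboxes`` are ``(slice, slice)`` pairs
    as returned by ``scipy.ndimage.find_objects``.
    """

    labels: np.ndarray
    counts: np.ndarray
    bboxes: list = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return len(self.counts)

    @property
    def mask(self) -> np.ndarray:
        return (self.labels > 0).astype(np.uint8)


def _as_array(img, ndim, name):
    a = np.asarray(img)
    if a.ndim != ndim or a.size == 0:
        raise ValueError(f"{name} must be a non-empty {ndim}-D array, got shape {a.shape}")
    return a


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an H×W×3 RGB image to 8-bit grayscale by the channel mean.

    The mean (R+G+B)/3 is rounded half-up so the conversion is
    bit-reproducible across platforms.
    """
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[-1] != 3 or a.shape[0] == 0 or a.shape[1] == 0:
        raise ValueError(f"expected non-empty H×W×3 RGB image, got shape {a.shape}")
    mean = a.astype(np.float64).sum(axis=-1) / 3.0
    gray = np.floor(mean + 0.5)
    return np.clip(gray, 0, 255).astype(np.uint8)


def histogram(img: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram h(i) of an 8-bit grayscale image."""
    a = _as_array(img, 2, "grayscale image")
    return np.bincount(a.ravel().astype(np.int64), minlength=N_LEVELS)[:N_LEVELS]


def metric_threshold(hist: np.ndarray) -> ThresholdResult:
    """Select the binarization threshold by metric minimization.

    Minimizes over k::

        sum_{i<=k} h(i)|i - mu1| + sum_{i>k} h(i)|i - mu2|

    where mu1 and mu2 are the count-weighted mean gray levels of the two
    classes. Only k leaving both classes nonempty are candidates; ties break
    toward the smallest k.

    Raises
    ------
    DegenerateHistogramError
        If every pixel sits at one gray level (no valid split).
    """
    h = np.asarray(hist, dtype=np.float64)
    if h.shape != (N_LEVELS,):
        raise ValueError(f"histogram must have {N_LEVELS} bins, got shape {h.shape}")
    if (h < 0).any():
        raise ValueError("histogram counts must be non-negative")
    n = h.sum()
    if n < 1:
        raise ValueError("empty histogram")

    levels = np.arange(N_LEVELS, dtype=np.float64)
    c = np.cumsum(h)          # pixels at levels <= k
    s = np.cumsum(h * levels)  # intensity mass at levels <= k

    ks = np.arange(N_LEVELS - 1)
    valid = (c[ks] > 0) & (c[ks] < n)
    if not valid.any():
        raise DegenerateHistogramError("all pixels at a single gray level; frame unsegmentable")
    ks = ks[valid]

    mu1 = s[ks] / c[ks]
    mu2 = (s[-1] - s[ks]) / (n - c[ks])

    # (levels, ks) broadcast: class membership of level i under threshold k
    low = levels[:, None] <= ks[None, :]
    dev = np.where(low, np.abs(levels[:, None] - mu1[None, :]),
                   np.abs(levels[:, None] - mu2[None, :]))
    cost = (h[:, None] * dev).sum(axis=0)

    # smallest k among (numerical) minimizers: the cost is exactly flat over
    # empty-bin stretches, where summation order can perturb it by ~1e-12
    cmin = cost.min()
    tol = 1e-9 * max(cmin, 1.0)
    j = int(np.flatnonzero(cost <= cmin + tol)[0])
    return ThresholdResult(k=int(ks[j]), cost=float(cost[j]),
                           mu1=float(mu1[j]), mu2=float(mu2[j]))


def binarize(img: np.ndarray, k: int) -> np.ndarray:
    """Threshold a grayscale image: levels <= k map to 0, others to 1."""
    if not 0 <= k <= 255:
        raise ValueError(f"threshold k must be in [0, 255], got {k}")
    a = _as_array(img, 2, "grayscale image")
    return (a > k).astype(np.uint8)


def to_display(mask: np.ndarray) -> np.ndarray:
    """Scale a {0,1} mask to an 8-bit image (1 -> 255) for display/saving."""
    a = _as_array(mask, 2, "binary mask")
    return (a.astype(np.uint8) * 255)


def label_particles(mask: np.ndarray) -> ParticleSet:
    """Label maximal 8-connected foreground components of a binary mask."""
    a = _as_array(mask, 2, "binary mask")
    labels, u = ndimage.label(a > 0, structure=_STRUCTURE_8)
    if u == 0:
        return ParticleSet(labels=labels, counts=np.zeros(0, dtype=np.int64), bboxes=[])
    counts = np.bincount(labels.ravel(), minlength=u + 1)[1:]
    bboxes = ndimage.find_objects(labels)
    return ParticleSet(labels=labels, counts=counts.astype(np.int64), bboxes=bboxes)


def fill_holes(particles: ParticleSet | np.ndarray) -> np.ndarray:
    """Fill particle holes: background regions not 4-connected to the border.

    Bubbles that binarize to dark interior regions are completely encircled by
    foreground, so filling restores the true sample area. Foreground pixels
    are never removed, and the operation is idempotent.
    """
    mask = particles.mask if isinstance(particles, ParticleSet) else _as_array(particles, 2, "mask")
    filled = ndimage.binary_fill_holes(mask > 0)
    return filled.astype(np.uint8)


def filter_particles(particles: ParticleSet, min_pixels: int) -> ParticleSet:
    """Retain particles with at least ``min_pixels`` pixels, relabeled 1..u'."""
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    keep = particles.counts >= min_pixels
    if keep.all():
        return particles
    old_labels = np.flatnonzero(keep) + 1
    remap = np.zeros(particles.counts.size + 1, dtype=particles.labels.dtype)
    remap[old_labels] = np.arange(1, old_labels.size + 1)
    labels = remap[particles.labels]
    bboxes = [particles.bboxes[i - 1] for i in old_labels] if particles.bboxes else []
    return ParticleSet(labels=labels, counts=particles.counts[keep], bboxes=bboxes)


def total_area(particles: ParticleSet) -> int:
    """Total sample area A in pixels: the sum of per-particle pixel counts."""
    return int(particles.counts.sum())


@dataclass
class SegmentedFrame:
    """Result of the full per-frame chain, with intermediate diagnostics."""

    area: int
    threshold: ThresholdResult
    particles: ParticleSet
    mask: np.ndarray  # final filled+filtered mask

    @property
    def n_particles(self) -> int:
        return self.particles.n_particles


def segment_frame(rgb: np.ndarray, min_pixels: int = 200) -> SegmentedFrame:
    """Run the full chain on one RGB frame.

    grayscale -> histogram -> metric threshold -> binarize -> label ->
    fill holes -> relabel -> size filter -> area.

    Each frame is thresholded independently (the online acquisition loop).
    Raises :class:`DegenerateHistogramError` for unsegmentable frames; callers
    record the frame's area as missing.
    """
    gray = to_grayscale(rgb)
    thr = metric_threshold(histogram(gray))
    mask = binarize(gray, thr.k)
    filled = fill_holes(label_particles(mask))
    particles = filter_particles(label_particles(filled), min_pixels)
    return SegmentedFrame(area=total_area(particles), threshold=thr,
                          particles=particles, mask=particles.mask)
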
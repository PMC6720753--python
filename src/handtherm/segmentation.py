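"""Hand/background separation, mask cleanup, thinning and finger ROIs.

Thresholding happens in two ways.  The primary route looks for the least
minimum on the grey-level histogram lying between two local maxima and then
applies balanced histogram thresholding (BHT): the heavier tail of the
histogram support is trimmed bin by bin until the mass on either side of a
moving midpoint balances.  When the object has no clear border with the
background (single-mode histogram) the fallback route thresholds the absolute
difference between two frames taken at different thermal states — the hand
changes temperature between frames while the background does not.

The binary mask is cleaned by iterated morphological opening/closing (3×3
square) with a 10-iteration budget; failure to reach a fixed point signals the
caller to restart from thresholding.  The cleaned silhouette is thinned to a
one-pixel skeleton (Zhang–Suen two-subiteration scheme) whose pixel graph is
traversed depth-first from each endpoint to the nearest branch point; the five
longest endpoint branches are the finger midlines, labelled thumb→little by
the angular position of their fingertips around the hand centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage import measure, morphology

from handtherm.preprocessing import GreyImage
from handtherm.synthetic import FINGER_LABELS

__all__ = [
    "BinaryMask",
    "Skeleton",
    "FingerROI",
    "SegmentationResult",
    "NoClearBorderError",
    "SegmentationError",
    "bht_threshold",
    "frame_difference_threshold",
    "morphological_cleanup",
    "skeletonize",
    "identify_fingers",
    "segment_hand",
]


class NoClearBorderError(ValueError):
    """Histogram has no valley between two modes; use the frame-difference path."""


class SegmentationError(RuntimeError):
    """Both thresholding routes failed to produce a usable segmentation."""


@dataclass(frozen=True)
class BinaryMask:
    data: np.ndarray  # bool
    threshold: int
    method: str  # "histogram" | "frame-difference"


@dataclass(frozen=True)
class Skeleton:
    data: np.ndarray  # bool, one-pixel-wide curves, 8-connected


@dataclass(frozen=True)
class FingerROI:
    """Ordered one-pixel midline of a finger, fingertip first."""

    label: str
    path: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return len(self.path)

    def rows_cols(self):
        arr = np.asarray(self.path)
        return arr[:, 0], arr[:, 1]


@dataclass
class SegmentationResult:
    mask: BinaryMask
    skeleton: Skeleton
    rois: list[FingerROI]
    restarts: int = 0
    fallback_used: bool = False
    intermediates: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# thresholding


def _histogram_modes(hist: np.ndarray) -> np.ndarray:
    """Locations of substantive local maxima of a (lightly smoothed) histogram."""
    smooth = np.convolve(hist.astype(float), np.ones(3) / 3.0, mode="same")
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, _ = signal.find_peaks(padded, prominence=0.05 * smooth.max())
    return peaks - 1


def bht_threshold(hist) -> int:
    """Balanced histogram threshold of a 256-bin grey histogram.

    Trims the heavier end of the histogram support one bin at a time,
    shifting the midpoint as the support shrinks; the surviving midpoint is
    the threshold and lies in the valley between the two dominant modes.
    Raises :class:`NoClearBorderError` when fewer than two modes exist.
    """
    hist = np.asarray(hist, dtype=np.int64)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    nonzero = np.flatnonzero(hist)
    if nonzero.size < 2:
        raise NoClearBorderError("histogram support has fewer than 2 levels")
    if _histogram_modes(hist).size < 2:
        raise NoClearBorderError("no valley between two histogram maxima")

    i_s, i_e = int(nonzero[0]), int(nonzero[-1])
    i_m = (i_s + i_e) // 2
    w_l = int(hist[i_s : i_m + 1].sum())
    w_r = int(hist[i_m + 1 : i_e + 1].sum())
    while i_s < i_e and (w_l > 0 or w_r > 0):
        # once both pans are empty the histogram carries no more information
        # and further support-trimming would only drift the midpoint
        if w_l > w_r:  # left side heavier: trim leftmost bin
            w_l -= int(hist[i_s])
            i_s += 1
            if (i_s + i_e) // 2 > i_m:
                w_l += int(hist[i_m + 1])
                w_r -= int(hist[i_m + 1])
                i_m += 1
        else:
            w_r -= int(hist[i_e])
            i_e -= 1
            if (i_s + i_e) // 2 < i_m:
                w_l -= int(hist[i_m])
                w_r += int(hist[i_m])
                i_m -= 1
    return i_m


def _grey_histogram(img: GreyImage) -> np.ndarray:
    return np.bincount(img.data.ravel(), minlength=256)


def threshold_histogram(img: GreyImage) -> BinaryMask:
    """BHT on the grey histogram; foreground = pixels above the threshold
    (the hand is warmer, hence brighter, than the 23 °C background)."""
    level = bht_threshold(_grey_histogram(img))
    return BinaryMask(data=img.data > level, threshold=level, method="histogram")


def frame_difference_threshold(frame_a: GreyImage, frame_b: GreyImage) -> BinaryMask:
    """Threshold |a − b|: the hand warms/cools between thermal states while
    the background stays put, so changed pixels are the hand."""
    if frame_a.data.shape != frame_b.data.shape:
        raise ValueError("frames must have identical dimensions")
    diff = np.abs(frame_a.data.astype(np.int16) - frame_b.data.astype(np.int16))
    diff = np.clip(diff, 0, 255).astype(np.uint8)
    if not diff.any():
        warnings.warn("identical frames: empty frame-difference mask",
                      stacklevel=2)
        return BinaryMask(data=np.zeros_like(diff, dtype=bool), threshold=0,
                          method="frame-difference")
    hist = np.bincount(diff.ravel(), minlength=256)
    try:
        level = bht_threshold(hist)
    except NoClearBorderError:
        # diff histogram degenerate (e.g. two spike levels); split the support
        nz = np.flatnonzero(hist)
        level = int((nz[0] + nz[-1]) // 2)
    return BinaryMask(data=diff > level, threshold=level,
                      method="frame-difference")


# ---------------------------------------------------------------------------
# morphology and thinning

_SE = np.ones((3, 3), dtype=bool)


def morphological_cleanup(mask: BinaryMask, max_iter: int = 10
                          ) -> tuple[BinaryMask, bool]:
    """Iterated opening-then-closing (3×3 square) until a fixed point.

    Returns the cleaned mask and a convergence flag; ``False`` means the mask
    was still changing after ``max_iter`` iterations, which the caller should
    treat as a restart signal for the thresholding step.
    """
    current = mask.data.astype(bool)
    converged = False
    for _ in range(max_iter):
        opened = ndimage.binary_dilation(
            ndimage.binary_erosion(current, structure=_SE), structure=_SE)
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(opened, structure=_SE), structure=_SE)
        if np.array_equal(closed, current):
            converged = True
            break
        current = closed
    return BinaryMask(data=current, threshold=mask.threshold,
                      method=mask.method), converged


def skeletonize(mask: BinaryMask | np.ndarray) -> Skeleton:
    """Thin a silhouette to a one-pixel-wide 8-connected skeleton by
    iterative boundary-layer removal (Zhang–Suen 3×3 tests)."""
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if not data.any():
        return Skeleton(data=np.zeros_like(data, dtype=bool))
    return Skeleton(data=morphology.skeletonize(data).astype(bool))


# ---------------------------------------------------------------------------
# finger identification

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _degree_map(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant") * skel


def _trace_branch(skel, degree, start):
    """Walk from an endpoint until hitting a branch point (degree >= 3),
    another endpoint, or running out of pixels.  Returns (path, hit_junction);
    the branch point itself is not part of the path."""
    path = [start]
    visited = {start}
    current = start
    while True:
        nxt = None
        for dr, dc in _NEIGHBOURS:
            r, c = current[0] + dr, current[1] + dc
            if (0 <= r < skel.shape[0] and 0 <= c < skel.shape[1]
                    and skel[r, c] and (r, c) not in visited):
                if degree[r, c] >= 3:
                    return path, True  # stop just before the junction
                if nxt is None:
                    nxt = (r, c)
        if nxt is None:
            return path, False
        path.append(nxt)
        visited.add(nxt)
        current = nxt


def identify_fingers(skeleton: Skeleton, min_length: int = 10,
                     centroid: tuple[float, float] | None = None,
                     junction_clearance: int = 4) -> list[FingerROI]:
    """Extract the five finger midlines from a hand skeleton.

    Endpoints (degree-1 pixels of the 8-adjacency pixel graph) are traversed
    depth-first toward the nearest branch point; the five longest such
    branches (at least ``min_length`` pixels) are the fingers.  The last
    ``junction_clearance`` pixels before the branch point are dropped: there
    the skeleton bends off the finger midline toward the point where
    neighbouring fingers merge.  Labels are assigned by the angular position
    of the fingertip around the skeleton centroid: the thumb is the most
    lateral, then index→little.
    """
    skel = skeleton.data
    degree = _degree_map(skel)
    endpoints = [tuple(p) for p in np.argwhere(degree == 1)]
    branches = []
    for e in sorted(endpoints):
        b, hit_junction = _trace_branch(skel, degree, e)
        if hit_junction and junction_clearance:
            b = b[: max(min_length, len(b) - junction_clearance)]
        branches.append(b)
    candidates = [b for b in branches if len(b) >= min_length]
    if len(candidates) < 5:
        raise SegmentationError(
            f"found {len(candidates)} finger-like branches of length >= "
            f"{min_length}; expected 5")
    # five longest; deterministic tie-break on fingertip coordinates
    candidates.sort(key=lambda b: (-len(b), b[0]))
    chosen = candidates[:5]
    if centroid is None:
        rc = np.argwhere(skel)
        centroid = (float(rc[:, 0].mean()), float(rc[:, 1].mean()))
    # math angle with y up, branch cut straight down so a lateral thumb that
    # dips below the centroid does not wrap; fingers point upward, thumb
    # (leftmost) has the largest angle; descending → thumb..little
    def tip_angle(branch):
        r, c = branch[0]
        theta = np.arctan2(centroid[0] - r, c - centroid[1])
        return theta + 2 * np.pi if theta < -np.pi / 2 else theta

    chosen.sort(key=tip_angle, reverse=True)
    return [FingerROI(label=lab, path=tuple(b))
            for lab, b in zip(FINGER_LABELS, chosen)]


# ---------------------------------------------------------------------------
# orchestration


def _largest_component(mask: BinaryMask) -> BinaryMask:
    labels, n = measure.label(mask.data, connectivity=2, return_num=True)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return BinaryMask(data=labels == counts.argmax(),
                      threshold=mask.threshold, method=mask.method)


def segment_hand(grey_static: GreyImage, grey_next: GreyImage | None = None,
                 min_length: int = 10, max_restarts: int = 2,
                 max_cleanup_iter: int = 10) -> SegmentationResult:
    """Full segmentation: threshold → cleanup → thinning → finger ROIs.

    The histogram route is tried first; if the histogram has no clear valley,
    or cleanup keeps oscillating through ``max_restarts`` restarts, the
    frame-difference route takes over (requires ``grey_next``).  All
    intermediates are retained for inspection.
    """
    attempts: list[tuple[str, object]] = [("histogram", None)]
    if grey_next is not None:
        attempts.append(("frame-difference", grey_next))

    restarts = 0
    errors: list[str] = []
    for method, aux in attempts:
        for attempt in range(max_restarts):
            try:
                if method == "histogram":
                    mask = threshold_histogram(grey_static)
                else:
                    mask = frame_difference_threshold(grey_static, aux)
                if not mask.data.any():
                    raise NoClearBorderError("empty foreground")
                cleaned, converged = morphological_cleanup(
                    mask, max_iter=max_cleanup_iter)
                if not converged:
                    restarts += 1
                    errors.append(f"{method}: cleanup did not converge "
                                  f"(attempt {attempt + 1})")
                    continue
                cleaned = _largest_component(cleaned)
                skel = skeletonize(cleaned)
                rois = identify_fingers(skel, min_length=min_length)
                return SegmentationResult(
                    mask=cleaned, skeleton=skel, rois=rois,
                    restarts=restarts,
                    fallback_used=(method == "frame-difference"),
                    intermediates={"raw_mask": mask, "method": method},
                )
            except (NoClearBorderError, SegmentationError) as exc:
                errors.append(f"{method}: {exc}")
                break  # this route is structurally unusable; try the next
    raise SegmentationError(
        "segmentation failed on all routes: " + "; ".join(errors))
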
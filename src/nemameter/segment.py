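"""Segmentation: Minimum-method global thresholding and component extraction.

After illumination correction the image is bimodal — a dark flat background
and bright worm-shaped objects.  Prewitt's Minimum method smooths the
intensity histogram with a 3-point moving average until exactly two strict
local maxima remain, then thresholds at the valley between them.  Connected
pixels at or above the threshold become worm candidates, which an area
filter trims of specks and plate-sized artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import IntensityImage

__all__ = [
    "IntensityHistogram",
    "ThresholdResult",
    "WormCandidate",
    "NoThresholdError",
    "intensity_histogram",
    "minimum_threshold",
    "apply_threshold",
    "connected_components",
    "area_filter",
    "trace_boundary",
]

_SMOOTH_CAP = 10_000


class NoThresholdError(RuntimeError):
    """Histogram never becomes bimodal (e.g. uniform or monotone)."""


@dataclass
class IntensityHistogram:
    """Counts y_j of pixels at each of the 256 intensity levels."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (256,):
            raise ValueError("intensity histogram must have 256 bins")


@dataclass
class ThresholdResult:
    t: int
    smoothing_iterations: int
    smoothed: np.ndarray


@dataclass
class WormCandidate:
    """One 8-connected foreground component: putative worm."""

    mask: np.ndarray
    area_px2: int
    contour: np.ndarray  # ordered (row, col) boundary pixels, Moore trace
    bbox: tuple  # (min_row, min_col, max_row, max_col) inclusive
    label: int = 0


def intensity_histogram(image) -> IntensityHistogram:
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    return IntensityHistogram(np.bincount(pixels.ravel(), minlength=256).astype(float))


def _smooth3(y: np.ndarray) -> np.ndarray:
    """One pass of the window-3 moving average, edges repeated."""
    pad = np.pad(y, 1, mode="edge")
    return (pad[:-2] + pad[1:-1] + pad[2:]) / 3.0


def _strict_maxima(y: np.ndarray) -> np.ndarray:
    pad = np.pad(y, 1, mode="edge")
    return np.flatnonzero((y > pad[:-2]) & (y > pad[2:]))


def minimum_threshold(hist: IntensityHistogram) -> ThresholdResult:
    """Threshold at the valley of the iteratively smoothed histogram.

    The histogram is smoothed with [1,1,1]/3 until exactly two strict
    local maxima remain; the returned ``t`` lies strictly between the
    peaks and satisfies ``y[t-1] > y[t] <= y[t+1]`` in the smoothed
    histogram.  Among qualifying valleys the lowest-count one wins, ties
    broken by the smallest ``t``.
    """
    y = np.asarray(hist.y, dtype=float).copy()
    if np.count_nonzero(y) < 2:
        raise NoThresholdError("histogram has fewer than 2 nonzero bins")
    iterations = 0
    while True:
        peaks = _strict_maxima(y)
        if len(peaks) == 2:
            break
        if iterations >= _SMOOTH_CAP:
            raise NoThresholdError(
                f"histogram not bimodal after {_SMOOTH_CAP} smoothing passes")
        y = _smooth3(y)
        iterations += 1
    p1, p2 = int(peaks[0]), int(peaks[1])
    best_t, best_count = None, np.inf
    for t in range(p1 + 1, p2):
        if y[t - 1] > y[t] <= y[t + 1] and y[t] < best_count:
            best_t, best_count = t, y[t]
    if best_t is None:  # cannot happen between two strict maxima
        raise NoThresholdError("no valley between histogram peaks")
    return ThresholdResult(t=best_t, smoothing_iterations=iterations, smoothed=y)


def apply_threshold(image, t: float) -> np.ndarray:
    """Foreground iff intensity >= t (objects are bright after preprocessing)."""
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    return pixels >= t


# 8-connectivity for foreground components
_STRUCT8 = np.ones((3, 3), dtype=bool)

# Moore neighborhood in clockwise screen order starting at W
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered outer boundary of a single component (Moore tracing).

    Starts at the first foreground pixel in raster order and walks the
    Moore neighborhood clockwise (Jacob's stopping criterion).
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty mask has no boundary")
    start = (int(rows[0]), int(cols[0]))
    if len(rows) == 1:
        return np.array([start])

    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    contour = [start]
    # backtrack starts at the pixel west of start (background by raster order)
    cur, prev_dir = start, 0  # prev_dir: Moore index of the backtrack pixel
    seen = {(cur, prev_dir)}
    while True:
        found = False
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if fg(nxt):
                # new backtrack: the neighbor checked just before nxt,
                # re-expressed relative to the new current pixel
                back = (prev_dir + k - 1) % 8
                bp = (cur[0] + _MOORE[back][0], cur[1] + _MOORE[back][1])
                prev_dir = _MOORE.index((bp[0] - nxt[0], bp[1] - nxt[1]))
                cur = nxt
                found = True
                break
        if not found:  # isolated pixel (handled above) — defensive
            break
        state = (cur, prev_dir)
        if state in seen:  # tracing state repeats: the cycle is closed
            break
        seen.add(state)
        contour.append(cur)
    return np.array(contour)


def connected_components(mask: np.ndarray) -> list[WormCandidate]:
    """Label the mask (foreground 8-connected) into worm candidates."""
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    out = []
    for lab, sl in zip(range(1, n + 1), ndimage.find_objects(labels)):
        comp = labels == lab
        area = int(comp.sum())
        contour = trace_boundary(comp)
        bbox = (sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1)
        out.append(WormCandidate(mask=comp, area_px2=area, contour=contour,
                                 bbox=bbox, label=lab))
    return out


def area_filter(candidates, min_px2: float, max_px2: float):
    """Keep candidates whose pixel area lies in [min_px2, max_px2]."""
    if not min_px2 < max_px2:
        raise ValueError("area filter requires min < max")
    return [c for c in candidates if min_px2 <= c.area_px2 <= max_px2]
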
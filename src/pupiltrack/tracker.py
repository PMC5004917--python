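"""Pupil segmentation and centroid tracking.

The segmentation chain is deliberately simple so it runs comfortably at
camera rate: intensity threshold (fixed once per session, exploiting the
bimodal dark-pupil/bright-iris histogram) → morphological closing with a
7×7 square kernel to remove extraneous dark regions (eyelashes, shadows)
→ connected-component analysis → unweighted center of mass of the largest
blob → deviation from a designated reference position in camera pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import ImageFrame, NoValleyError

# re-exported container (declared here for the tracker's public surface)
__all__ = [
    "ImageFrame", "PupilDetection", "select_threshold", "binarize_and_close",
    "largest_component_centroid", "track_frame", "track_stack",
]

_CLOSE_SIZE = 7
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class PupilDetection:
    """Result of segmenting one frame.

    ``centroid`` is (x, y) in pixels with sub-pixel precision; ``area`` the
    blob size in pixels.  ``valid`` is False when no foreground survived
    segmentation (blink, lost pupil), in which case the other fields are
    meaningless.
    """

    centroid: tuple[float, float]
    area: int
    threshold_used: float
    valid: bool


def select_threshold(frame: ImageFrame | np.ndarray, method: str = "valley",
                     smoothing_sigma: float = 2.0) -> float:
    """Pick the session threshold from a bimodal intensity histogram.

    ``valley`` (default) lightly smooths the 256-bin histogram, finds the
    two most populated modes, and returns the gray level of the deepest
    valley between them.  ``otsu`` delegates to Otsu's criterion.  Frames
    without two separated modes raise :class:`NoValleyError` — the caller
    must then supply a threshold manually.
    """
    pixels = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    if method == "otsu":
        from skimage.filters import threshold_otsu

        if pixels.min() == pixels.max():
            raise NoValleyError("uniform frame has no threshold")
        return float(threshold_otsu(pixels))
    if method != "valley":
        raise ValueError(f"unknown threshold method {method!r}")

    hist = np.bincount(pixels.astype(np.int64).ravel(), minlength=256).astype(float)
    smooth = ndimage.gaussian_filter1d(hist, smoothing_sigma)
    # local maxima of the smoothed histogram
    interior = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] > smooth[2:])
    peaks = np.flatnonzero(interior) + 1
    if smooth[0] > smooth[1]:
        peaks = np.r_[0, peaks]
    if smooth[-1] > smooth[-2]:
        peaks = np.r_[peaks, len(smooth) - 1]
    if len(peaks) < 2:
        raise NoValleyError("histogram is unimodal; supply threshold manually")
    # the two most populated modes
    order = peaks[np.argsort(smooth[peaks])[::-1]]
    lo, hi = sorted(order[:2])
    if hi - lo < 2:
        raise NoValleyError("modes not separated by a valley")
    valley = lo + 1 + int(np.argmin(smooth[lo + 1:hi]))
    return float(valley)


def binarize_and_close(frame: ImageFrame | np.ndarray,
                       threshold: float) -> np.ndarray:
    """Threshold (pupil = dark = foreground) and close with a 7×7 kernel.

    Equivalent to ``scipy.ndimage.binary_closing`` with a 7×7 square
    structuring element, implemented as separable max/min filters for
    speed (the square element factorizes exactly).
    """
    pixels = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    mask = pixels <= threshold
    dilated = ndimage.maximum_filter(mask, size=_CLOSE_SIZE,
                                     mode="constant", cval=0)
    return ndimage.minimum_filter(dilated, size=_CLOSE_SIZE,
                                  mode="constant", cval=0)


def largest_component_centroid(binary: np.ndarray,
                               threshold_used: float = np.nan,
                               reference: tuple[float, float] | None = None,
                               ) -> PupilDetection:
    """Centroid of the largest 8-connected foreground component.

    Equal-area ties are broken toward the component whose centroid lies
    nearest ``reference`` (the pupil is expected near the designated
    center); without a reference the lowest label wins.  An empty
    foreground yields ``valid=False`` rather than an exception.
    """
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    if n == 0:
        return PupilDetection(centroid=(np.nan, np.nan), area=0,
                              threshold_used=threshold_used, valid=False)
    areas = np.bincount(labels.ravel())[1:]  # skip background
    best = np.flatnonzero(areas == areas.max()) + 1
    if len(best) > 1 and reference is not None:
        coms = ndimage.center_of_mass(binary, labels, best)
        dists = [np.hypot(c[1] - reference[0], c[0] - reference[1]) for c in coms]
        label = best[int(np.argmin(dists))]
    else:
        label = best[0]
    cy, cx = ndimage.center_of_mass(binary, labels, label)
    return PupilDetection(centroid=(float(cx), float(cy)),
                          area=int(areas[label - 1]),
                          threshold_used=threshold_used, valid=True)


def track_frame(frame: ImageFrame, threshold: float,
                reference: tuple[float, float],
                ) -> tuple[np.ndarray | None, PupilDetection]:
    """Deviation of the pupil centroid from ``reference`` in pixels.

    Returns ``(deviation, detection)``; deviation is ``centroid −
    reference`` as an (dx, dy) array, or None when the detection is
    invalid (the caller decides how to hold/zero the correction).
    """
    binary = binarize_and_close(frame, threshold)
    det = largest_component_centroid(binary, threshold_used=threshold,
                                     reference=reference)
    if not det.valid:
        return None, det
    deviation = np.array([det.centroid[0] - reference[0],
                          det.centroid[1] - reference[1]])
    return deviation, det


def track_stack(frames, threshold: float,
                reference: tuple[float, float]) -> pd.DataFrame:
    """Track a frame sequence; per-frame detections as a DataFrame.

    Columns: ``frame, t, cx, cy, area, valid`` — the CSV layout used for
    exported detections.
    """
    rows = []
    for i, frame in enumerate(frames):
        _, det = track_frame(frame, threshold, reference)
        rows.append({"frame": i, "t": frame.timestamp,
                     "cx": det.centroid[0], "cy": det.centroid[1],
                     "area": det.area, "valid": det.valid})
    return pd.DataFrame(rows)
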
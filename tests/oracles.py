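"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library-call paths they are checked against:
connected components by flood fill, morphological closing by explicit set
dilation/erosion, and histogram-valley search by exhaustive scan.
"""

from __future__ import annotations

import numpy as np

EIGHT_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                   (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_components(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components via explicit flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in EIGHT_NEIGHBORS:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def largest_component_brute(binary: np.ndarray):
    """(area, centroid (x, y)) of the largest component, or None if empty."""
    comps = flood_fill_components(binary)
    if not comps:
        return None
    comp = max(comps, key=len)
    ys = [p[0] for p in comp]
    xs = [p[1] for p in comp]
    return len(comp), (float(np.mean(xs)), float(np.mean(ys)))


def closing_brute(mask: np.ndarray, k: int = 7) -> np.ndarray:
    """Morphological closing with a k x k square by explicit set logic.

    Dilation marks every pixel whose k x k neighborhood (clipped at the
    border) contains foreground; erosion keeps pixels whose full k x k
    neighborhood lies in the dilated set, treating outside as background.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    half = k // 2
    dil = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            y0, y1 = max(r - half, 0), min(r + half + 1, h)
            x0, x1 = max(c - half, 0), min(c + half + 1, w)
            dil[r, c] = mask[y0:y1, x0:x1].any()
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if r - half < 0 or r + half >= h or c - half < 0 or c + half >= w:
                out[r, c] = False  # neighborhood leaves the image: background
            else:
                out[r, c] = dil[r - half:r + half + 1,
                                c - half:c + half + 1].all()
    return out


def valley_brute(pixels: np.ndarray, lo: int, hi: int, window: int = 9) -> int:
    """Exhaustive histogram-valley search between gray levels lo and hi.

    Smooths the 256-bin histogram with a plain moving average and returns
    the gray level of the minimum count strictly between lo and hi.
    """
    hist = np.bincount(np.asarray(pixels).ravel(), minlength=256).astype(float)
    kernel = np.ones(window) / window
    smooth = np.convolve(hist, kernel, mode="same")
    levels = np.arange(lo + 1, hi)
    return int(levels[np.argmin(smooth[lo + 1:hi])])
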
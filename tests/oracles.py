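"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible (nested loops, exhaustive
search) and must stay independent of the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_box_count(img: np.ndarray, eps: int, offset: tuple[int, int]) -> int:
    """Count occupied eps x eps boxes by scanning every box explicitly.

    The grid origin sits at (-oy, -ox); partial boxes at the edges count.
    """
    H, W = img.shape
    oy, ox = offset
    n = 0
    y = -oy
    while y < H:
        x = -ox
        while x < W:
            block = img[max(y, 0) : min(y + eps, H), max(x, 0) : min(x + eps, W)]
            if block.size and block.any():
                n += 1
            x += eps
        y += eps
    return n


def brute_gliding_box(img: np.ndarray, r: int) -> float | None:
    """Lambda(r) = <M^2>/<M>^2 over all fully contained r x r windows."""
    H, W = img.shape
    masses = []
    for y in range(H - r + 1):
        for x in range(W - r + 1):
            masses.append(int(img[y : y + r, x : x + r].sum()))
    m = np.asarray(masses, dtype=np.float64)
    if m.mean() == 0:
        return None
    return float(np.mean(m * m) / m.mean() ** 2)


def brute_otsu(pixels: np.ndarray) -> int:
    """Exhaustive search over all 255 candidate thresholds.

    For each t, class 0 is {v <= t} and class 1 is {v > t}; the returned t
    maximizes between-class variance, smallest t on ties.
    """
    v = np.asarray(pixels, dtype=np.float64).ravel()
    best_t, best_var = 0, -1.0
    for t in range(255):
        c0 = v[v <= t]
        c1 = v[v > t]
        if c0.size == 0 or c1.size == 0:
            continue
        w0 = c0.size / v.size
        w1 = c1.size / v.size
        var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var + 1e-12:
            best_var = var
            best_t = t
    return best_t


def brute_median_disk(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel median over a disk neighborhood with edge replication."""
    H, W = pixels.shape
    out = np.empty_like(pixels)
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    for y in range(H):
        for x in range(W):
            vals = [
                pixels[min(max(y + dy, 0), H - 1), min(max(x + dx, 0), W - 1)]
                for dy, dx in offsets
            ]
            out[y, x] = np.median(vals)
    return out
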
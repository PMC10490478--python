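"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own algorithms: the DTW oracle
enumerates every monotone warping path recursively (exponential time, tiny
inputs only) and the histogram oracle tallies pixels in a Python loop.
"""

from __future__ import annotations

import math

import numpy as np


def dtw_enumerate(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal cumulative cost over *all* monotone warping paths.

    ``x`` and ``y`` are (n, k) arrays; local cost is |xi - yj| for k = 1 and
    the Euclidean norm otherwise, accumulated front-to-back along each path
    (the same summation order as a forward dynamic program, so agreement can
    be asserted exactly).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    if y.ndim == 1:
        y = y.reshape(-1, 1)
    n, m = x.shape[0], y.shape[0]
    best = [math.inf]

    def cost(i: int, j: int) -> float:
        d = x[i] - y[j]
        if d.size == 1:
            return abs(float(d[0]))
        return math.sqrt(float((d * d).sum()))

    def walk(i: int, j: int, acc: float) -> None:
        acc = acc + cost(i, j)
        if i == n - 1 and j == m - 1:
            if acc < best[0]:
                best[0] = acc
            return
        if i + 1 < n:
            walk(i + 1, j, acc)
            if j + 1 < m:
                walk(i + 1, j + 1, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def histogram_tally(pixels: np.ndarray, channel_index: int) -> np.ndarray:
    """Brute-force per-code pixel tally, normalized; loops over every pixel."""
    counts = [0] * 256
    h, w, _ = pixels.shape
    for r in range(h):
        for c in range(w):
            counts[int(pixels[r, c, channel_index])] += 1
    return np.array(counts, dtype=np.float64) / (h * w)


def welch_closed_form(a, b) -> tuple[float, float]:
    """Textbook Welch statistic and Satterthwaite dof, written independently."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sa, sb = va / na, vb / nb
    t = (ma - mb) / math.sqrt(sa + sb)
    dof = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return t, dof
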
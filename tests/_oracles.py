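"""Independent reference implementations used as test oracles.

Everything here is written as a direct, unoptimized transcription of the
definitions (pure-Python loops, no shared code with the package) so that
agreement with the package is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np


def brute_force_otsu(image: np.ndarray) -> float:
    """Exhaustive search over all candidate thresholds.

    Candidates are the distinct intensities; threshold t puts {x < t} in
    class 0 and {x >= t} in class 1; maximize the weighted between-class
    variance w0*w1*(mu0-mu1)^2, ties toward the lowest t.
    """
    pixels = np.asarray(image, dtype=np.float64).ravel()
    candidates = sorted(set(pixels.tolist()))[1:]
    best_t, best_v = None, -1.0
    for t in candidates:
        lo = pixels[pixels < t]
        hi = pixels[pixels >= t]
        w0 = lo.size / pixels.size
        w1 = hi.size / pixels.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def direct_gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    """2-D Gaussian kernel by direct evaluation, normalized over its support."""
    r = np.arange(-radius, radius + 1)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    k = np.exp(-(rr**2 + cc**2) / (2 * sigma**2))
    return k / k.sum()


def direct_ssim(x: np.ndarray, y: np.ndarray, k1: float, k2: float, L: float) -> float:
    """Term-by-term evaluation of the single-window SSIM formula."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.size
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    return ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


def literal_track(patch: np.ndarray, baseline_row: int, alpha: int, beta: int, gamma: int):
    """Step-by-step transcription of the tracking procedure.

    Seed: first column with ink within the alpha-window around the baseline,
    seed row = median (lower middle) of the in-window ink rows.  Then per
    column rightward: median ink row within the beta-window around the
    previous point; an empty window or a candidate further than gamma from
    the previous offset repeats the last offset.  Columns before the seed
    get the seed offset.  Returns (offsets list, seed_col) or None if no
    seed exists.
    """
    h, w = patch.shape
    half_a = alpha // 2
    half_b = beta // 2

    seed_col = None
    for col in range(w):
        rows = [
            r
            for r in range(max(0, baseline_row - half_a), min(h, baseline_row + half_a + 1))
            if patch[r, col]
        ]
        if rows:
            seed_col = col
            seed_row = rows[(len(rows) - 1) // 2]
            break
    if seed_col is None:
        return None

    signal = [baseline_row - seed_row] * (seed_col + 1)
    prev_row = seed_row
    for col in range(seed_col + 1, w):
        rows = [
            r
            for r in range(max(0, prev_row - half_b), min(h, prev_row + half_b + 1))
            if patch[r, col]
        ]
        if not rows:
            signal.append(signal[-1])  # discontinuity: carry forward
            continue
        cand = rows[(len(rows) - 1) // 2]
        if abs((baseline_row - cand) - signal[-1]) > gamma:
            signal.append(signal[-1])  # validation failure: carry forward
            continue
        prev_row = cand
        signal.append(baseline_row - cand)
    return signal, seed_col
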
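"""Signal re-synthesis and fidelity scoring (SSIM / MSE).

Extracted traces are rendered back onto a blank page as an 8-connected
polyline per lead (optionally dilated to the printed trace thickness), and
the reconstruction is scored against the binarized original with the
structural similarity index and the mean squared error.

SSIM here is the single-global-window form

    SSIM(x, y) = (2 μx μy + C1)(2 σxy + C2) /
                 ((μx² + μy² + C1)(σx² + σy² + C2)),

with population (1/N) moments over the whole image and C1 = (K1 L)²,
C2 = (K2 L)² for dynamic range L.  On {0, 1} masks MSE is exactly the
fraction of mismatched pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from skimage.morphology import dilation, disk

from .errors import ShapeMismatch
from .layout import LayoutModel
from .trace import LeadTrace

__all__ = [
    "SSIMConstants",
    "EvalReport",
    "draw_polyline",
    "render_traces",
    "ssim",
    "mse",
    "evaluate_page",
]


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilizing constants of the SSIM formula.

    K1, K2 are the conventional small dimensionless constants; L is the
    dynamic range (1 for binary masks, 255 for 8-bit images).
    """

    K1: float = 0.01
    K2: float = 0.03
    L: float = 1.0

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0 or self.L <= 0:
            raise ValueError("K1, K2 and L must all be > 0")

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2


@dataclass
class EvalReport:
    """Page-level and per-patch reconstruction fidelity."""

    ssim: float
    mse: float
    per_patch: list[dict]
    n_pixels: int

    def to_dict(self) -> dict:
        return {
            "ssim": self.ssim,
            "mse": self.mse,
            "per_patch": self.per_patch,
            "n_pixels": self.n_pixels,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def draw_polyline(canvas: np.ndarray, rows: np.ndarray, col_start: int = 0) -> None:
    """Mark rows[c] at column col_start + c, vertically filling jumps.

    A jump between consecutive columns is filled symmetrically: the half of
    the vertical run nearer the previous point extends the previous column,
    the half nearer the current point goes to the current column.  This
    mimics a pen stroke centered on the curve (so the per-column median ink
    row tracks the curve even on steep slopes) and keeps the polyline
    8-connected for any jump size.  Rows are clipped to the canvas.
    Modifies ``canvas`` in place.
    """
    h, w = canvas.shape
    rows = np.clip(np.asarray(rows, dtype=np.int64), 0, h - 1)
    n = min(rows.size, w - col_start)
    if n <= 0:
        return
    canvas[rows[0], col_start] = 1
    for c in range(1, n):
        r_prev, r = int(rows[c - 1]), int(rows[c])
        col = col_start + c
        if r == r_prev:
            canvas[r, col] = 1
            continue
        lo, hi = (r_prev, r) if r_prev < r else (r, r_prev)
        m = (lo + hi) // 2
        if r > r_prev:  # downward jump
            canvas[r_prev : m + 1, col - 1] = 1
            canvas[m + 1 : r + 1, col] = 1
        else:  # upward jump
            canvas[m + 1 : r_prev + 1, col - 1] = 1
            canvas[r : m + 1, col] = 1


def render_traces(
    traces: list[LeadTrace],
    layout: LayoutModel,
    shape: tuple[int, int],
    thickness: int = 1,
) -> np.ndarray:
    """Render traces onto a blank page-sized binary mask.

    Each non-missing trace is drawn at row ``baseline_row - offset`` per
    column of its span; ``thickness`` > 1 dilates the union of polylines
    with a disk of radius (thickness - 1) // 2.
    """
    canvas = np.zeros(shape, dtype=np.uint8)
    for t in traces:
        if t.missing:
            continue
        if t.col_end > shape[1] or t.baseline_row >= shape[0]:
            raise ShapeMismatch(
                f"trace span [{t.col_start}, {t.col_end}) / baseline "
                f"{t.baseline_row} exceeds shape {shape}"
            )
        if t.offsets.size != t.col_end - t.col_start:
            raise ShapeMismatch(
                f"trace length {t.offsets.size} != span width {t.col_end - t.col_start}"
            )
        draw_polyline(canvas, t.baseline_row - t.offsets, t.col_start)
    radius = (int(thickness) - 1) // 2
    if radius > 0:
        canvas = dilation(canvas, disk(radius))
    return canvas


def estimate_stroke_thickness(mask: np.ndarray, col_step: int = 17) -> int:
    """Median vertical ink-run length over sampled columns of a binary page.

    Binarization after blur widens a printed stroke, so matching the render
    thickness to the measured stroke width gives a like-for-like fidelity
    comparison.  Returns at least 1.
    """
    mask = np.asarray(mask).astype(np.uint8)
    runs: list[int] = []
    for col in range(0, mask.shape[1], col_step):
        d = np.diff(np.concatenate(([0], mask[:, col], [0])))
        runs.extend(np.flatnonzero(d == -1) - np.flatnonzero(d == 1))
    if not runs:
        return 1
    return max(1, int(np.median(np.asarray(runs))))


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ShapeMismatch(f"shape {x.shape} vs {y.shape}")
    return x, y


def ssim(x: np.ndarray, y: np.ndarray, consts: SSIMConstants | None = None) -> float:
    """Global-window structural similarity of two same-shape images."""
    if consts is None:
        consts = SSIMConstants()
    x, y = _check_shapes(x, y)
    if x.size < 2:
        raise ShapeMismatch("need at least 2 pixels")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/N)
    cov = ((x - mx) * (y - my)).mean()
    c1, c2 = consts.C1, consts.C2
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared pixel difference; mismatch fraction on {0,1} masks."""
    x, y = _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def evaluate_page(
    original: np.ndarray,
    traces: list[LeadTrace],
    layout: LayoutModel,
    consts: SSIMConstants | None = None,
    thickness: int = 1,
) -> EvalReport:
    """Render ``traces`` and score them against the binarized original."""
    if consts is None:
        consts = SSIMConstants()
    original = np.asarray(original)
    recon = render_traces(traces, layout, original.shape, thickness=thickness)
    per_patch = []
    for i, (a, b) in enumerate(layout.patch_spans, start=1):
        per_patch.append(
            {
                "patch": i,
                "ssim": ssim(original[:, a:b], recon[:, a:b], consts),
                "mse": mse(original[:, a:b], recon[:, a:b]),
            }
        )
    return EvalReport(
        ssim=ssim(original, recon, consts),
        mse=mse(original, recon),
        per_patch=per_patch,
        n_pixels=int(original.size),
    )
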
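"""Per-lead signal extraction by seeded, windowed rightward tracking.

Each lead's trace is recovered as a vector of signed vertical offsets from
its isoelectric baseline, one per patch column (positive = above baseline,
the usual ECG display convention).  Tracking starts at a *seed point* — the
first column holding ink within an α-pixel vertical window around the
baseline — and walks rightward, looking for ink within a β-pixel window
centered on the previous point.  Within a window the *median* ink row is
taken (robust to trace thickness); an empty window (a gap in the print) or a
candidate jumping more than γ pixels from the previous offset carries the
previous offset forward, so the output always spans the full patch width.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import NoSignalFound
from .layout import LayoutModel

__all__ = [
    "TrackingParams",
    "LeadTrace",
    "find_seed",
    "next_point",
    "track_trace",
    "extract_page",
]


@dataclass(frozen=True)
class TrackingParams:
    """Window sizes of the tracker, in pixels (full window heights).

    alpha: seed search window around the baseline (default 150).
    beta:  tracking window around the previous point (default 75).
    gamma: maximum accepted offset jump between adjacent columns (default 15).
    """

    alpha: int = 150
    beta: int = 75
    gamma: int = 15

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class LeadTrace:
    """One lead's extracted signal: per-column offsets from its baseline.

    ``offsets`` has length exactly ``col_end - col_start`` (the patch width);
    it is None for a MISSING trace (seeding failed, e.g. a blank lead).
    ``lead`` is the 1-12 lead number for the three lead rows, None for the
    bottom rhythm-strip segment.
    """

    offsets: Optional[np.ndarray]
    baseline_row: int
    patch_index: int  # 1-4, left to right
    row_index: int  # 1-4, top to bottom; 4 = rhythm strip
    seed_col: int  # column (patch-local) where tracking began; -1 if missing
    col_start: int  # page-coordinate span of the patch
    col_end: int
    lead: Optional[int] = None

    @property
    def missing(self) -> bool:
        return self.offsets is None

    @property
    def is_rhythm(self) -> bool:
        return self.row_index == 4


def _window(center: int, size: int, n_rows: int) -> tuple[int, int]:
    """Row slice bounds of a size-pixel window centered on ``center``."""
    half = size // 2
    return max(0, center - half), min(n_rows, center + half + 1)


def _median_row(rows: np.ndarray) -> int:
    """Median of sorted integer rows; even count -> lower middle value."""
    return int(rows[(rows.size - 1) // 2])


def find_seed(patch: np.ndarray, baseline_row: int, alpha: int) -> tuple[int, int]:
    """First column with ink within an alpha-window around the baseline.

    Returns (col, row): the leftmost qualifying column and the median
    foreground row inside the window there.  Raises NoSignalFound if no
    column qualifies.
    """
    patch = np.asarray(patch)
    h, w = patch.shape
    if not (0 <= baseline_row < h):
        raise ValueError(f"baseline row {baseline_row} outside patch height {h}")
    lo, hi = _window(baseline_row, alpha, h)
    band = patch[lo:hi, :]
    hit = band.any(axis=0)
    if not hit.any():
        raise NoSignalFound(
            f"no ink within {alpha}-px window of baseline row {baseline_row}"
        )
    col = int(np.argmax(hit))
    rows = np.flatnonzero(band[:, col]) + lo
    return col, _median_row(rows)


def next_point(patch: np.ndarray, col: int, prev_row: int, beta: int) -> Optional[int]:
    """Median ink row in column ``col`` within a beta-window of ``prev_row``.

    Returns None when the window holds no ink (a discontinuity), which the
    caller treats as carry-forward, not as an error.
    """
    patch = np.asarray(patch)
    lo, hi = _window(prev_row, beta, patch.shape[0])
    rows = np.flatnonzero(patch[lo:hi, col])
    if rows.size == 0:
        return None
    return int(rows[(rows.size - 1) // 2]) + lo


def track_trace(
    patch: np.ndarray, baseline_row: int, params: TrackingParams
) -> tuple[np.ndarray, int]:
    """Track one lead across the patch; returns (offsets, seed_col).

    Offsets are baseline_row - ink_row.  Columns left of the seed are filled
    with the seed offset so the result length always equals the patch width.
    A column whose window is empty, or whose candidate offset differs from
    the previous one by more than gamma, repeats the previous offset.
    """
    patch = np.asarray(patch)
    w = patch.shape[1]
    seed_col, seed_row = find_seed(patch, baseline_row, params.alpha)
    offsets = np.empty(w, dtype=np.int64)
    offsets[: seed_col + 1] = baseline_row - seed_row
    prev_row = seed_row
    for col in range(seed_col + 1, w):
        cand = next_point(patch, col, prev_row, params.beta)
        if cand is not None and abs((baseline_row - cand) - (baseline_row - prev_row)) <= params.gamma:
            prev_row = cand
        offsets[col] = baseline_row - prev_row
    return offsets, seed_col


def extract_page(
    mask: np.ndarray, layout: LayoutModel, params: TrackingParams | None = None
) -> list[LeadTrace]:
    """Extract every (patch, baseline) trace of a page — up to 16 traces.

    Lead rows 1-3 map to the 12 leads column-major (lead = (row-1)*4 +
    patch, so patch 1 carries leads 1, 5, 9); row 4 is the rhythm strip,
    one segment per patch.  A lead whose seeding fails becomes a MISSING
    trace rather than aborting the page.
    """
    if params is None:
        params = TrackingParams()
    mask = np.asarray(mask)
    layout.validate_against(mask)
    traces: list[LeadTrace] = []
    for p, ((a, b), baselines) in enumerate(
        zip(layout.patch_spans, layout.baselines), start=1
    ):
        patch = mask[:, a:b]
        for r, baseline_row in enumerate(np.sort(np.asarray(baselines)), start=1):
            lead = (r - 1) * 4 + p if r <= 3 else None
            try:
                offsets, seed_col = track_trace(patch, int(baseline_row), params)
            except NoSignalFound:
                offsets, seed_col = None, -1
            traces.append(
                LeadTrace(
                    offsets=offsets,
                    baseline_row=int(baseline_row),
                    patch_index=p,
                    row_index=r,
                    seed_col=seed_col,
                    col_start=a,
                    col_end=b,
                    lead=lead,
                )
            )
    return traces
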
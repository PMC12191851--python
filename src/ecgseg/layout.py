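"""Lead layout detection from projection histograms.

A standard one-page 12-lead printout arranges the leads in 4 columns of 3,
with a rhythm strip across the bottom.  Three full-height vertical separator
lines dominate the per-column (vertical) foreground histogram, and the four
isoelectric baselines dominate the per-row (horizontal) histogram; peaks of
those histograms give the column separators and the lead baselines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyPatch, InsufficientPeaks, LayoutMismatch

__all__ = [
    "ProjectionHistogram",
    "LayoutModel",
    "DEFAULT_MARGIN",
    "projection_histogram",
    "top_k_peaks",
    "split_patches",
    "estimate_baselines",
    "detect_layout",
]

#: Pixels trimmed on each side of a separator line when slicing patches;
#: also the left margin of patch 1.
DEFAULT_MARGIN = 5


@dataclass(frozen=True)
class ProjectionHistogram:
    """Foreground-pixel counts per row (``horizontal``) or column (``vertical``)."""

    counts: np.ndarray
    axis: str  # "horizontal" | "vertical"


def projection_histogram(mask: np.ndarray, axis: str) -> ProjectionHistogram:
    """Count foreground pixels per row (horizontal) or per column (vertical)."""
    mask = np.asarray(mask)
    if axis == "horizontal":
        counts = mask.sum(axis=1)
    elif axis == "vertical":
        counts = mask.sum(axis=0)
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return ProjectionHistogram(counts=counts.astype(np.int64), axis=axis)


def top_k_peaks(hist: ProjectionHistogram | np.ndarray, k: int, min_sep: int) -> np.ndarray:
    """Greedy top-k peak picking with non-maximum suppression.

    Repeatedly selects the highest remaining count (ties -> lower index) and
    suppresses every position strictly within ``min_sep`` pixels of it, until
    ``k`` peaks are found.  Selected positions are returned sorted ascending.
    Positions with zero count are never selected.
    """
    counts = hist.counts if isinstance(hist, ProjectionHistogram) else np.asarray(hist)
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_sep < 0:
        raise ValueError("min_sep must be >= 0")
    work = counts.astype(np.float64).copy()
    work[work <= 0] = -np.inf
    picked: list[int] = []
    for _ in range(k):
        idx = int(np.argmax(work))
        if not np.isfinite(work[idx]):
            raise InsufficientPeaks(
                f"only {len(picked)} peaks found, {k} requested (min_sep={min_sep})"
            )
        picked.append(idx)
        lo = max(0, idx - min_sep + 1)
        work[lo : idx + min_sep] = -np.inf
        work[idx] = -np.inf  # min_sep == 0 still consumes the position itself
    return np.sort(np.asarray(picked))


@dataclass
class LayoutModel:
    """Detected page layout: separators, patch column spans and baselines.

    ``patch_spans`` are half-open [start, end) column intervals in page
    coordinates, ordered left to right; ``baselines[p]`` are the ascending
    baseline rows of patch ``p`` (index 0..3).
    """

    separators: np.ndarray  # 3 ascending column indices
    patch_spans: list[tuple[int, int]]  # 4 half-open column intervals
    baselines: list[np.ndarray]  # per patch, ascending row indices
    margin: int = DEFAULT_MARGIN

    def validate_against(self, mask: np.ndarray) -> None:
        h, w = np.asarray(mask).shape
        for a, b in self.patch_spans:
            if not (0 <= a < b <= w):
                raise LayoutMismatch(f"span [{a}, {b}) outside width {w}")
        for rows in self.baselines:
            if len(rows) and (min(rows) < 0 or max(rows) >= h):
                raise LayoutMismatch(f"baseline rows {rows} outside height {h}")

    def to_dict(self) -> dict:
        return {
            "separators": [int(s) for s in self.separators],
            "patch_spans": [[int(a), int(b)] for a, b in self.patch_spans],
            "baselines": [[int(r) for r in rows] for rows in self.baselines],
            "margin": int(self.margin),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "LayoutModel":
        return cls(
            separators=np.asarray(d["separators"], dtype=int),
            patch_spans=[(int(a), int(b)) for a, b in d["patch_spans"]],
            baselines=[np.asarray(rows, dtype=int) for rows in d["baselines"]],
            margin=int(d.get("margin", DEFAULT_MARGIN)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LayoutModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def patch_spans_from_separators(
    separators: np.ndarray, width: int, margin: int = DEFAULT_MARGIN
) -> list[tuple[int, int]]:
    """Column spans [margin, s1-m), [s1+m, s2-m), [s2+m, s3-m), [s3+m, width)."""
    s1, s2, s3 = (int(s) for s in separators)
    spans = [
        (margin, s1 - margin),
        (s1 + margin, s2 - margin),
        (s2 + margin, s3 - margin),
        (s3 + margin, width),
    ]
    for a, b in spans:
        if a >= b:
            raise EmptyPatch(f"span [{a}, {b}) is empty (separators {separators})")
    return spans


def split_patches(
    mask: np.ndarray, separators: np.ndarray, margin: int = DEFAULT_MARGIN
) -> tuple[list[tuple[int, int]], list[np.ndarray]]:
    """Split the page into 4 patches between the separator lines.

    Full row extent is kept; ``margin`` pixels are trimmed on each side of a
    separator (and from the page's left edge) to drop the separator ink and
    the lead-name text printed at column starts.
    """
    mask = np.asarray(mask)
    separators = np.sort(np.asarray(separators, dtype=int))
    if separators.size != 3:
        raise ValueError(f"expected exactly 3 separators, got {separators.size}")
    spans = patch_spans_from_separators(separators, mask.shape[1], margin)
    patches = [mask[:, a:b] for a, b in spans]
    return spans, patches


def estimate_baselines(
    patch_mask: np.ndarray, k: int = 4, min_sep: int | None = None
) -> np.ndarray:
    """Baseline rows of one patch: top-k peaks of its horizontal histogram.

    The flat isoelectric stretches of each lead dominate the per-row counts.
    ``min_sep`` defaults to patch_height // 8, wide enough to keep one thick
    trace from claiming two peaks in the 4-row layout.
    """
    patch_mask = np.asarray(patch_mask)
    if min_sep is None:
        min_sep = patch_mask.shape[0] // 8
    hist = projection_histogram(patch_mask, "horizontal")
    return top_k_peaks(hist, k=k, min_sep=min_sep)


def detect_layout(
    mask: np.ndarray,
    margin: int = DEFAULT_MARGIN,
    sep_min_sep: int | None = None,
    baseline_min_sep: int | None = None,
    n_baselines: int = 4,
) -> LayoutModel:
    """Detect separators then per-patch baselines from a binarized page."""
    mask = np.asarray(mask)
    if sep_min_sep is None:
        sep_min_sep = mask.shape[1] // 8
    vhist = projection_histogram(mask, "vertical")
    separators = top_k_peaks(vhist, k=3, min_sep=sep_min_sep)
    spans, patches = split_patches(mask, separators, margin)
    baselines = [
        estimate_baselines(p, k=n_baselines, min_sep=baseline_min_sep) for p in patches
    ]
    return LayoutModel(
        separators=separators, patch_spans=spans, baselines=baselines, margin=margin
    )
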
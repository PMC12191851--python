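"""Seeded synthetic ECG page renderer with exact ground truth.

Emulates a scanned single-page 12-lead printout as the pipeline expects it:
dark thin traces on light paper, 4 lead rows (3 lead rows + a bottom rhythm
strip) by 4 columns, three full-height vertical separator lines, an optional
faint background grid, short trace gaps, small label clutter at column
starts, and salt-and-pepper noise.  Every page comes with its exact layout
and per-lead offset vectors, so layout detection, tracking and scoring are
all verifiable without any external scan.

The beat model is a sum of Gaussian bumps (P wave, Q/R/S complex, T wave)
repeated at a fixed period with seeded per-beat phase jitter — not a
physiological simulator, but enough shape variety (flat stretches, steep QRS
slopes, rounded waves) to exercise seeding, median picking, gap
carry-forward and jump validation.

Trace gaps are placed on isoelectric (flat, zero-offset) stretches: printed
discontinuities occur on the isoelectric line, and the carry-forward rule
can only ever reproduce a hidden segment whose true offset matches the last
seen one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, disk

from .errors import InvalidBeatParams, SpecInvalid
from .layout import DEFAULT_MARGIN, LayoutModel, patch_spans_from_separators
from .reconstruct_eval import draw_polyline
from .trace import LeadTrace

__all__ = ["BeatParams", "PageSpec", "GroundTruth", "synth_waveform", "render_synthetic_page"]


@dataclass(frozen=True)
class BeatParams:
    """Gaussian-bump beat shape, all lengths in pixels.

    Amplitudes are vertical offsets (positive = above baseline); widths are
    the Gaussian standard deviations; ``period`` is the beat-to-beat spacing
    in columns and ``jitter`` the per-beat phase jitter amplitude.
    """

    p_amp: float = 10.0
    q_amp: float = -15.0
    r_amp: float = 60.0
    s_amp: float = -15.0
    t_amp: float = 20.0
    p_width: float = 8.0
    qrs_width: float = 3.0
    t_width: float = 12.0
    period: int = 180
    jitter: float = 3.0

    def __post_init__(self) -> None:
        if self.period < 1:
            raise InvalidBeatParams(f"period must be >= 1, got {self.period}")
        if self.p_width <= 0 or self.qrs_width <= 0 or self.t_width <= 0:
            raise InvalidBeatParams("bump widths must be > 0")
        if self.jitter < 0:
            raise InvalidBeatParams("jitter must be >= 0")

    @property
    def max_amplitude(self) -> float:
        return max(abs(a) for a in (self.p_amp, self.q_amp, self.r_amp, self.s_amp, self.t_amp))

    def bumps(self) -> list[tuple[float, float, float]]:
        """(center offset within beat, amplitude, width) per wave."""
        p = self.period
        return [
            (0.22 * p, self.p_amp, self.p_width),
            (0.39 * p, self.q_amp, self.qrs_width),
            (0.43 * p, self.r_amp, self.qrs_width),
            (0.47 * p, self.s_amp, self.qrs_width),
            (0.70 * p, self.t_amp, self.t_width),
        ]


def synth_waveform(beat: BeatParams, length: int, rng: np.random.Generator) -> np.ndarray:
    """Integer offset vector of a repeated jittered beat, ``length`` columns."""
    if length < 1:
        raise InvalidBeatParams(f"length must be >= 1, got {length}")
    x = np.arange(length, dtype=np.float64)
    out = np.zeros(length, dtype=np.float64)
    phase = float(rng.uniform(0, beat.period))
    n_beats = int(np.ceil(length / beat.period)) + 2
    for k in range(-1, n_beats):
        start = k * beat.period + phase + float(rng.uniform(-beat.jitter, beat.jitter))
        for center, amp, width in beat.bumps():
            c = start + center
            if -6 * width < c < length + 6 * width:
                out += amp * np.exp(-((x - c) ** 2) / (2 * width**2))
    return np.rint(out).astype(np.int64)


@dataclass(frozen=True)
class PageSpec:
    """Full description of one synthetic page; equal specs render equal pages.

    Default geometry mirrors the cropped plotting region of the scans this
    layout targets: a 1240 x 2000 page, separators every 500 columns and
    baselines every 310 rows.
    """

    shape: tuple[int, int] = (1240, 2000)
    baseline_rows: tuple[int, ...] = (155, 465, 775, 1085)
    separator_cols: tuple[int, ...] = (500, 1000, 1500)
    margin: int = DEFAULT_MARGIN
    thickness: int = 1
    gap_spans: tuple[tuple[int, int, int, int], ...] = ()  # (patch, row, col_a, col_b) patch-local
    n_random_gaps: int = 0
    max_gap: int = 10
    label_clutter: bool = False
    grid: bool = True
    grid_level: int = 235
    grid_step: int = 25
    noise_density: float = 0.0
    beat: BeatParams = field(default_factory=BeatParams)
    ink_level: int = 20
    bg_level: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        rows = np.asarray(self.baseline_rows)
        cols = np.asarray(self.separator_cols)
        if rows.size != 4 or np.any(np.diff(rows) <= 0) or rows[0] < 0 or rows[-1] >= h:
            raise SpecInvalid(f"need 4 ascending baseline rows inside height {h}")
        if cols.size != 3 or np.any(np.diff(cols) <= 0) or cols[0] < 0 or cols[-1] >= w:
            raise SpecInvalid(f"need 3 ascending separator cols inside width {w}")
        if self.thickness < 1:
            raise SpecInvalid("thickness must be >= 1")
        if not (0 <= self.noise_density < 1):
            raise SpecInvalid("noise_density must be in [0, 1)")
        if not (0 <= self.ink_level < self.bg_level <= 255):
            raise SpecInvalid("need 0 <= ink_level < bg_level <= 255")
        spacing = int(np.diff(rows).min())
        if self.beat.max_amplitude >= spacing / 2:
            raise SpecInvalid(
                f"beat amplitude {self.beat.max_amplitude} >= half baseline spacing {spacing / 2}"
            )


@dataclass
class GroundTruth:
    """Rendered page plus the exact layout and traces that produced it."""

    page: np.ndarray  # grayscale uint8
    signal_mask: np.ndarray  # {0,1}; trace ink only (gaps applied), no separators
    layout: LayoutModel
    traces: list[LeadTrace]
    spec: PageSpec


def _truth_layout(spec: PageSpec) -> LayoutModel:
    separators = np.asarray(spec.separator_cols, dtype=int)
    spans = patch_spans_from_separators(separators, spec.shape[1], spec.margin)
    baselines = [np.asarray(spec.baseline_rows, dtype=int) for _ in range(4)]
    return LayoutModel(separators=separators, patch_spans=spans, baselines=baselines, margin=spec.margin)


def _flat_run_starts(offsets: np.ndarray, gap_len: int) -> np.ndarray:
    """Start columns c >= 2 such that offsets[c-1 : c+gap_len+1] is all zero."""
    zero = offsets == 0
    win = gap_len + 2
    if zero.size < win:
        return np.array([], dtype=int)
    ok = np.convolve(zero.astype(int), np.ones(win, dtype=int), mode="valid") == win
    starts = np.flatnonzero(ok) + 1  # run covers [c-1, c+gap_len]
    return starts[starts >= 2]


def render_synthetic_page(spec: PageSpec) -> GroundTruth:
    """Render one page from its spec; fully deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    layout = _truth_layout(spec)

    traces: list[LeadTrace] = []
    canvas = np.zeros((h, w), dtype=np.uint8)
    # Lead rows 1-3: one independent waveform per grid cell.
    for p, (a, b) in enumerate(layout.patch_spans, start=1):
        for r in range(1, 4):
            offsets = synth_waveform(spec.beat, b - a, rng)
            traces.append(
                LeadTrace(
                    offsets=offsets,
                    baseline_row=spec.baseline_rows[r - 1],
                    patch_index=p,
                    row_index=r,
                    seed_col=0,
                    col_start=a,
                    col_end=b,
                    lead=(r - 1) * 4 + p,
                )
            )
    # Rhythm strip: one continuous waveform across the page, sliced per patch.
    rhythm = synth_waveform(spec.beat, w, rng)
    for p, (a, b) in enumerate(layout.patch_spans, start=1):
        traces.append(
            LeadTrace(
                offsets=rhythm[a:b].copy(),
                baseline_row=spec.baseline_rows[3],
                patch_index=p,
                row_index=4,
                seed_col=0,
                col_start=a,
                col_end=b,
                lead=None,
            )
        )
    # Reorder into extract_page's (patch, row) order for easy pairing.
    traces.sort(key=lambda t: (t.patch_index, t.row_index))

    for t in traces:
        draw_polyline(canvas, t.baseline_row - t.offsets, t.col_start)
    radius = (spec.thickness - 1) // 2
    if radius > 0:
        canvas = dilation(canvas, disk(radius))

    # Gap erasures: explicit spans first, then seeded random ones on
    # isoelectric stretches.  Erasure is confined to a vertical band around
    # the trace's own baseline so neighbouring rows are untouched.
    band = int(np.diff(np.asarray(spec.baseline_rows)).min()) // 2
    gaps = list(spec.gap_spans)
    if spec.n_random_gaps > 0:
        by_key = {(t.patch_index, t.row_index): t for t in traces}
        for _ in range(spec.n_random_gaps):
            p = int(rng.integers(1, 5))
            r = int(rng.integers(1, 5))
            gap_len = int(rng.integers(3, max(4, spec.max_gap + 1)))
            t = by_key[(p, r)]
            starts = _flat_run_starts(t.offsets, gap_len)
            starts = starts[starts + gap_len <= t.offsets.size - 2]
            if starts.size == 0:
                continue
            c = int(rng.choice(starts))
            gaps.append((p, r, c, c + gap_len))
    by_key = {(t.patch_index, t.row_index): t for t in traces}
    for p, r, ca, cb in gaps:
        t = by_key[(p, r)]
        base = t.baseline_row
        canvas[max(0, base - band) : min(h, base + band), t.col_start + ca : t.col_start + cb] = 0

    # Assemble the grayscale page: paper, faint grid, then ink.
    page = np.full((h, w), spec.bg_level, dtype=np.uint8)
    if spec.grid:
        page[:: spec.grid_step, :] = spec.grid_level
        page[:, :: spec.grid_step] = spec.grid_level
    ink = canvas.astype(bool).copy()
    ink[:, np.asarray(spec.separator_cols, dtype=int)] = True
    if spec.label_clutter:
        for a, _ in layout.patch_spans:
            for base in spec.baseline_rows:
                r0 = base - 70 + int(rng.integers(0, 10))
                c0 = a + int(rng.integers(0, 30))
                ink[max(0, r0) : max(0, r0) + 4, c0 : min(w, c0 + 8)] = True
    page[ink] = spec.ink_level
    if spec.noise_density > 0:
        n_noise = int(round(spec.noise_density * page.size))
        idx = rng.choice(page.size, size=n_noise, replace=False)
        vals = rng.choice(np.array([0, 255], dtype=np.uint8), size=n_noise)
        page.ravel()[idx] = vals

    return GroundTruth(page=page, signal_mask=canvas, layout=layout, traces=traces, spec=spec)
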
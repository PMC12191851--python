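# Methods

## Problem and model

A standard one-page 12-lead ECG printout arranges short lead traces in a
4 × 3 grid plus a full-width rhythm strip, with drawn vertical lines
separating the four columns.  `ecgseg` treats digitization as four
deterministic stages — binarization, layout detection, per-lead centerline
tracking, and reconstruction scoring — with no learned components.  The
core assumptions are:

- ink is dark on light paper, so a global Otsu threshold separates it;
- the three separator lines and four isoelectric baselines dominate the
  vertical and horizontal projection histograms respectively;
- each lead's trace is a function of the column (single-valued after taking
  the median ink row per search window), starts near its baseline, and
  moves at most γ pixels per column once outliers are suppressed.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| crop box | plotting region, rows × cols | `[280,1520) × [150,2150)` | dataset-class specific; disable for pre-trimmed images |
| σ | Gaussian blur std, px | 0.7 | kernel truncated at radius ⌈3σ⌉, reflect padding |
| α | seed search window height, px | 150 | full height, centered on the baseline |
| β | tracking window height, px | 75 | full height, centered on the previous point |
| γ | max accepted offset jump, px | 15 | larger jumps carry the previous offset forward |
| margin | px trimmed beside separators | 5 | also the left edge of patch 1 |
| min_sep | peak suppression radius | width/8, height/8 | separators / baselines |
| K₁, K₂, L | SSIM constants | 0.01, 0.03, 1 | L = 255 for 8-bit comparisons |

Window semantics: a size-*w* window around center *c* covers integer rows
`[c − w//2, c + w//2]`.  Medians of even-sized row sets take the lower
middle value, keeping all rows integral.

## Design choices at genuinely open points

- **Otsu definition.** Thresholds are searched over the exact distinct
  intensities present (not fixed-width bins); threshold *t* assigns
  `x < t` to the foreground class; ties go to the lowest *t*.  This makes
  the implementation bit-identical to an exhaustive between-class-variance
  search, which the test suite verifies against an independent brute-force
  transcription and cross-checks against scikit-image's bin-based variant
  on well-separated images.
- **Peak picking.** Naively taking the top-k histogram bins would return
  adjacent rows of one thick line; greedy selection with a strict
  non-maximum-suppression radius is used instead (highest count first,
  ties to the lower index, suppress positions strictly within `min_sep`).
- **Validation failure = discontinuity.** When a candidate point jumps
  more than γ, the tracker carries the previous offset forward and
  advances one column, exactly as for an empty window.  Rejecting without
  advancing would never terminate; rejecting and dropping the column would
  break the full-patch-width contract.
- **Pre-seed columns** are filled with the seed offset so trace length
  always equals patch width; a lead whose seed search finds no ink at all
  becomes a MISSING trace rather than failing the page.
- **Offset sign** is positive above the baseline (row index decreasing),
  the usual ECG display convention.
- **Stroke rendering.** Re-drawn polylines fill vertical jumps
  symmetrically: the half of the run nearer the previous point extends the
  previous column, the rest goes to the current column.  This mimics a pen
  stroke centered on the curve — the per-column median ink row then tracks
  the curve even on steep QRS slopes — and keeps the stroke 8-connected.
  Dilation with a disk of radius (thickness−1)/2 reproduces thicker print.
- **SSIM window.** SSIM is computed in a single global window with
  population (1/N) moments; no sliding window is used.  Fidelity scores
  are therefore comparable across pages
  of one geometry but are not interchangeable with windowed mean-SSIM
  values.
- **Thickness matching.** Blur + thresholding widens a printed 1 px stroke
  to ≈3 px, so the benchmark matches the reconstruction's dilation to the
  measured median vertical ink-run length before scoring; a thickness
  mismatch otherwise dominates the SSIM/MSE difference.  Per-patch scores
  exclude the separator columns, which the signal reconstruction
  deliberately does not redraw.

## Synthetic pages

The generator emulates the features the pipeline actually keys on: a
1240 × 2000 plotting region, baselines every 310 rows, separators every
500 columns, dark traces (intensity 20) on light paper (250), an optional
faint grid (level 235, every 25 px) that a global threshold removes,
label-like clutter at column starts, short trace gaps, variable stroke
thickness (1/3/5 px), and salt-and-pepper noise.  Beats are sums of
Gaussian bumps (P, Q, R, S, T; R amplitude 60 px, QRS σ 3 px, period
180 px ≈ 0.9 s at 200 px/s) with seeded per-beat phase jitter — shapes
chosen to exercise flat stretches, steep slopes near the γ limit, and
rounded waves, not to model pathology.

Gap erasures are placed on isoelectric (zero-offset) stretches: printed
discontinuities occur on the isoelectric line, and a hidden segment is
only recoverable by carry-forward when its true offset equals the last
visible one, so gaps elsewhere would measure the generator, not the
tracker.  Gaps never change the length of the ground-truth offset vectors.

What the generator does **not** emulate: page rotation/skew, non-uniform
illumination, colored grids that survive binarization, overlapping or
crossing traces, and pathological morphologies.  Passing the synthetic
benchmarks therefore demonstrates correctness of the algorithmic chain
under the stated layout assumptions, not robustness to every archival
scan.

## Benchmark sizes and determinism

The shipped benchmarks use 50 pages for layout and trace recovery and 20
pages for pipeline fidelity — enough to cover the thickness × gap grid
with stable means while keeping a full run under a minute.  All
randomness flows from explicit seeds (`numpy.random.default_rng`); page
seeds are derived from one master seed via `SeedSequence`, so every
reported number is bit-reproducible.

## Known limitations

- Layouts other than 4 columns × (3 rows + rhythm strip) are out of scope;
  the detector always looks for 3 separators and 4 baselines.
- No millivolt/time calibration: offsets are pixels, columns are samples.
- The tracker follows one centerline per window; leads that genuinely
  overlap vertically within β cannot be disentangled.
- A baseline estimate off by a row (possible with thick strokes, where
  adjacent rows tie in the histogram) shifts that lead's offsets by a
  constant; absolute-row comparisons in the benchmarks are unaffected.
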
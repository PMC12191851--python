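"""Seeded synthetic benchmarks: layout recovery, trace recovery, round trip.

These drive the same library pipeline a user runs on real scans, but on
generated pages whose layout and per-lead offsets are known exactly, so the
errors reported here are true recovery errors, not proxies.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .config import RunConfig
from .pipeline import segment_image
from .reconstruct_eval import estimate_stroke_thickness, evaluate_page
from .synth import GroundTruth, PageSpec, render_synthetic_page

__all__ = [
    "page_seeds",
    "layout_recovery",
    "trace_recovery",
    "round_trip",
    "pipeline_scores",
]


def page_seeds(n: int, seed: int) -> np.ndarray:
    """n per-page seeds derived reproducibly from one master seed."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint64) % (2**31)).astype(np.int64)


def _no_crop_config(**overrides) -> RunConfig:
    # Synthetic pages are already the plotting region.
    return RunConfig(apply_crop=False).override(**overrides)


def _paired_row_errors(truth: GroundTruth, result) -> list[np.ndarray]:
    """Per-trace absolute ink-row errors on overlapping page columns."""
    truth_by_key = {(t.patch_index, t.row_index): t for t in truth.traces}
    errors = []
    for det in result.traces:
        tr = truth_by_key[(det.patch_index, det.row_index)]
        if det.missing:
            errors.append(np.array([np.inf]))
            continue
        a = max(det.col_start, tr.col_start)
        b = min(det.col_end, tr.col_end)
        det_rows = det.baseline_row - det.offsets[a - det.col_start : b - det.col_start]
        tru_rows = tr.baseline_row - tr.offsets[a - tr.col_start : b - tr.col_start]
        errors.append((det_rows - tru_rows).astype(np.float64))
    return errors


def layout_recovery(n_pages: int = 50, seed: int = 0, tol: int = 2) -> dict:
    """Separator/baseline recovery on clean (noise-free, thickness-1) pages."""
    seps, bases, ok = [], [], 0
    for s in page_seeds(n_pages, seed):
        truth = render_synthetic_page(PageSpec(seed=int(s)))
        result = segment_image(truth.page, _no_crop_config())
        sep_err = np.max(np.abs(result.layout.separators - truth.layout.separators))
        base_err = max(
            np.max(np.abs(np.sort(det) - np.sort(tru)))
            for det, tru in zip(result.layout.baselines, truth.layout.baselines)
        )
        seps.append(sep_err)
        bases.append(base_err)
        ok += sep_err <= tol and base_err <= tol
    return {
        "n_pages": n_pages,
        "separator_max_error_px": float(np.max(seps)),
        "baseline_max_error_px": float(np.max(bases)),
        "pages_within_tol": int(ok),
        "recovery_rate_pct": 100.0 * ok / n_pages,
    }


def trace_recovery(
    n_pages: int = 50,
    seed: int = 0,
    thicknesses: Sequence[int] = (1, 3, 5),
    n_random_gaps: int = 3,
    max_gap: int = 10,
) -> dict:
    """Per-lead offset RMSE and contract checks on degraded pages.

    Pages cycle through the given trace thicknesses and carry short seeded
    gaps on isoelectric stretches.  The RMSE bound checked downstream is
    thickness/2 + 1 px per lead.
    """
    cfg = _no_crop_config()
    rmses, bounds, length_ok, jump_ok = [], [], True, True
    for i, s in enumerate(page_seeds(n_pages, seed)):
        thickness = int(thicknesses[i % len(thicknesses)])
        spec = PageSpec(
            seed=int(s), thickness=thickness, n_random_gaps=n_random_gaps, max_gap=max_gap
        )
        truth = render_synthetic_page(spec)
        result = segment_image(truth.page, cfg)
        for det, err in zip(result.traces, _paired_row_errors(truth, result)):
            rmses.append(float(np.sqrt(np.mean(err**2))))
            bounds.append(thickness / 2 + 1)
            if not det.missing:
                if det.offsets.size != det.col_end - det.col_start:
                    length_ok = False
                jumps = np.abs(np.diff(det.offsets[det.seed_col :]))
                if jumps.size and jumps.max() > cfg.gamma:
                    jump_ok = False
    rmses = np.asarray(rmses)
    bounds = np.asarray(bounds)
    return {
        "n_pages": n_pages,
        "n_traces": int(rmses.size),
        "rmse_mean_px": float(np.mean(rmses)),
        "rmse_max_px": float(np.max(rmses)),
        "traces_within_bound": int(np.sum(rmses <= bounds)),
        "within_bound_rate_pct": 100.0 * float(np.mean(rmses <= bounds)),
        "lengths_ok": length_ok,
        "jumps_within_gamma": jump_ok,
    }


def round_trip(seed: int = 0) -> dict:
    """Render a clean page's ground-truth traces and score them against it."""
    truth = render_synthetic_page(PageSpec(seed=seed))
    report = evaluate_page(truth.signal_mask, truth.traces, truth.layout)
    return {"ssim": report.ssim, "mse": report.mse}


def pipeline_scores(
    n_pages: int = 20,
    seed: int = 0,
    thickness: int = 1,
    n_random_gaps: int = 0,
    render_thickness: int | None = None,
) -> dict:
    """Mean reconstruction fidelity of the full pipeline on synthetic pages.

    ``render_thickness=None`` matches the reconstruction to the measured
    binarized stroke width of each page (blur widens a printed stroke), so
    the score reflects trace alignment rather than a thickness mismatch.
    Per-patch means score the lead columns alone, excluding the separator
    lines, which the signal reconstruction intentionally does not redraw.
    """
    ssims, mses, patch_ssims, patch_mses = [], [], [], []
    for s in page_seeds(n_pages, seed):
        truth = render_synthetic_page(
            PageSpec(seed=int(s), thickness=thickness, n_random_gaps=n_random_gaps)
        )
        result = segment_image(truth.page, _no_crop_config())
        t = render_thickness or estimate_stroke_thickness(result.mask)
        report = evaluate_page(result.mask, result.traces, result.layout, thickness=t)
        ssims.append(report.ssim)
        mses.append(report.mse)
        patch_ssims.extend(p["ssim"] for p in report.per_patch)
        patch_mses.extend(p["mse"] for p in report.per_patch)
    return {
        "n_pages": n_pages,
        "ssim_mean": float(np.mean(ssims)),
        "mse_mean": float(np.mean(mses)),
        "patch_ssim_mean": float(np.mean(patch_ssims)),
        "patch_mse_mean": float(np.mean(patch_mses)),
    }
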
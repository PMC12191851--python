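"""End-to-end page segmentation: preprocess -> layout -> trace -> score."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .layout import LayoutModel, detect_layout
from .preprocess import as_grayscale, crop_roi, gaussian_blur, otsu_binarize
from .reconstruct_eval import EvalReport, evaluate_page, render_traces
from .trace import LeadTrace, extract_page

__all__ = ["PageResult", "segment_image"]

log = logging.getLogger(__name__)


@dataclass
class PageResult:
    """Everything one page run produces."""

    threshold: float
    mask: np.ndarray
    layout: LayoutModel
    traces: list[LeadTrace]
    reconstruction: np.ndarray
    report: EvalReport


def segment_image(image: np.ndarray, config: RunConfig | None = None) -> PageResult:
    """Run the full segmentation pipeline on a page image."""
    if config is None:
        config = RunConfig()
    gray = as_grayscale(image)
    if config.apply_crop:
        gray = crop_roi(gray, config.preprocess_params().crop)
    blurred = gaussian_blur(gray, config.sigma)
    threshold, mask = otsu_binarize(blurred)
    log.info("binarized: threshold=%.2f, foreground=%d px", threshold, int(mask.sum()))
    layout = detect_layout(
        mask,
        margin=config.margin,
        sep_min_sep=config.sep_min_sep,
        baseline_min_sep=config.baseline_min_sep,
    )
    log.info("layout: separators=%s", [int(s) for s in layout.separators])
    traces = extract_page(mask, layout, config.tracking_params())
    n_missing = sum(t.missing for t in traces)
    log.info("extracted %d traces (%d missing)", len(traces), n_missing)
    recon = render_traces(traces, layout, mask.shape, thickness=config.thickness)
    report = evaluate_page(
        mask, traces, layout, config.ssim_constants(), thickness=config.thickness
    )
    log.info("fidelity: ssim=%.4f mse=%.5f", report.ssim, report.mse)
    return PageResult(
        threshold=threshold,
        mask=mask,
        layout=layout,
        traces=traces,
        reconstruction=recon,
        report=report,
    )
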
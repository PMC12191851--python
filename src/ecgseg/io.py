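"""Reading and writing of images, traces and reports."""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd
from PIL import Image

from .trace import LeadTrace

__all__ = [
    "load_image",
    "save_image",
    "save_mask_png",
    "load_mask_png",
    "traces_to_dataframe",
    "traces_to_csv",
    "traces_to_json",
    "traces_from_json",
    "make_overlay",
]


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as 8-bit grayscale (Rec. 601 luminance for color)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image).astype(np.uint8)).save(path)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit 0/255 PNG."""
    save_image(np.asarray(mask).astype(np.uint8) * 255, path)


def load_mask_png(path: str | Path) -> np.ndarray:
    return (load_image(path) > 127).astype(np.uint8)


def traces_to_dataframe(traces: list[LeadTrace]) -> pd.DataFrame:
    """Long-format per-column table: lead, patch, row, col, offset_px."""
    records = []
    for t in traces:
        if t.missing:
            continue
        for c, off in enumerate(t.offsets):
            records.append(
                {
                    "lead": t.lead if t.lead is not None else 0,
                    "patch": t.patch_index,
                    "row": t.row_index,
                    "col": t.col_start + c,
                    "offset_px": int(off),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["lead", "patch", "row", "col", "offset_px"]
    )


def traces_to_csv(traces: list[LeadTrace], path: str | Path) -> None:
    traces_to_dataframe(traces).to_csv(path, index=False)


def _trace_dict(t: LeadTrace) -> dict:
    return {
        "lead": t.lead,
        "patch": t.patch_index,
        "row": t.row_index,
        "baseline_row": t.baseline_row,
        "seed_col": t.seed_col,
        "col_start": t.col_start,
        "col_end": t.col_end,
        "missing": t.missing,
        "offsets": None if t.missing else [int(v) for v in t.offsets],
    }


def traces_to_json(traces: list[LeadTrace], path: str | Path) -> None:
    Path(path).write_text(json.dumps({"traces": [_trace_dict(t) for t in traces]}, indent=1))


def traces_from_json(path: str | Path) -> list[LeadTrace]:
    data = json.loads(Path(path).read_text())
    out = []
    for d in data["traces"]:
        out.append(
            LeadTrace(
                offsets=None if d["offsets"] is None else np.asarray(d["offsets"], dtype=np.int64),
                baseline_row=d["baseline_row"],
                patch_index=d["patch"],
                row_index=d["row"],
                seed_col=d["seed_col"],
                col_start=d["col_start"],
                col_end=d["col_end"],
                lead=d["lead"],
            )
        )
    return out


def make_overlay(original: np.ndarray, reconstruction: np.ndarray) -> np.ndarray:
    """RGB overlay: original mask in red, reconstruction in cyan, overlap dark."""
    orig = np.asarray(original).astype(bool)
    recon = np.asarray(reconstruction).astype(bool)
    rgb = np.full(orig.shape + (3,), 255, dtype=np.uint8)
    rgb[orig, 1] = 0
    rgb[orig, 2] = 0
    rgb[recon, 0] = 0
    return rgb
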
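"""Gel-style rendering of aligned traces.

Peaks in a profile appear as dark bands in a gray-scale lane image, the
way the field inspects electrophoresis results.  Annotated residues are
overlaid as colored circles with the conventional base palette: G green,
C cyan, U blue, A red.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .annotate import BandAnnotation
from .preprocess import TraceSet

BASE_COLORS = {"G": (0, 200, 0), "C": (0, 200, 200),
               "U": (0, 0, 230), "A": (230, 0, 0), "T": (0, 0, 230)}


def gel_matrix(traces: TraceSet, clip_percentile: float = 98.0,
               height: int = 800) -> np.ndarray:
    """Down-sampled intensity matrix (rows x lanes) over the ROI, clipped
    at a high percentile so one saturated band cannot wash out the rest."""
    roi = traces.roi.slice() if traces.roi is not None else slice(None)
    sig = traces.signal[roi]
    n = sig.shape[0]
    rows = np.linspace(0, n - 1, height)
    idx = np.clip(np.round(rows).astype(int), 0, n - 1)
    mat = sig[idx]
    top = np.percentile(mat, clip_percentile)
    if top <= 0:
        return np.zeros_like(mat)
    return np.clip(mat, 0, top) / top


def render_gel(traces: TraceSet, annotation: BandAnnotation | None,
               out_path, lane_width: int = 24, height: int = 800,
               clip_percentile: float = 98.0) -> None:
    """Write a PNG gel image: dark bands on a light background, one
    vertical stripe per capillary, optional per-base colored markers at
    the annotated positions.  Deterministic for identical inputs."""
    mat = gel_matrix(traces, clip_percentile, height)
    gray = (255 - np.round(mat * 255)).astype(np.uint8)
    img_arr = np.repeat(gray, lane_width, axis=1)
    img = Image.fromarray(img_arr, mode="L").convert("RGB")
    if annotation is not None:
        draw = ImageDraw.Draw(img)
        roi_start = traces.roi.start if traces.roi is not None else 0
        roi_len = (len(traces.roi) if traces.roi is not None
                   else traces.n_samples)
        seq = annotation.sequence.upper().replace("T", "U")
        for j in range(traces.n_lanes):
            cx = j * lane_width + lane_width // 2
            for res_idx, pos in zip(annotation.annotated_residues,
                                    annotation.positions):
                row = (pos - roi_start) / max(1, roi_len - 1) * (height - 1)
                if not (0 <= row < height):
                    continue
                color = BASE_COLORS.get(seq[res_idx], (120, 120, 120))
                r = max(2, lane_width // 6)
                draw.ellipse([cx - r, row - r, cx + r, row + r],
                             outline=color, width=1)
    img.save(Path(out_path), format="PNG")
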
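"""Preprocessing: channel selection, region-of-interest detection and
constant-baseline removal.

Each capillary carries several spectral channels; the caller names which
channel holds the chemical-probing signal and which holds the co-loaded
reference ladder.  The informative part of an electrophoresis run is a
sub-range of the trace, found here by a 1-D edge detector on the
lane-summed intensity envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .abif_io import BatchSet


class ConfigError(ValueError):
    pass


class DetectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open sample range [start, end) of informative signal."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid ROI [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass(frozen=True)
class LaneInfo:
    capillary_id: str
    batch_id: str
    batch_ordinal: int


@dataclass
class TraceSet:
    """Signal and reference-ladder lane matrices with lane bookkeeping.

    Both matrices are ``n_samples x n_lanes`` float arrays in the same
    lane order (batches concatenated, lexicographic within a batch).
    """

    signal: np.ndarray
    reference: np.ndarray
    lanes: list[LaneInfo]
    roi: RegionOfInterest | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.signal.shape != self.reference.shape:
            raise ValueError("signal and reference matrices must share a shape")
        if self.signal.shape[1] != len(self.lanes):
            raise ValueError("lane metadata length must match lane count")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_lanes(self) -> int:
        return self.signal.shape[1]

    def batch_slices(self) -> list[tuple[str, slice]]:
        """Contiguous lane-index slice per batch, in batch order."""
        out, start = [], 0
        for i, lane in enumerate(self.lanes):
            if i and lane.batch_id != self.lanes[i - 1].batch_id:
                out.append((self.lanes[start].batch_id, slice(start, i)))
                start = i
        out.append((self.lanes[start].batch_id, slice(start, self.n_lanes)))
        return out

    def copy(self) -> "TraceSet":
        return TraceSet(self.signal.copy(), self.reference.copy(),
                        list(self.lanes), self.roi)


def select_channels(batchset: BatchSet, signal_channel: int,
                    reference_channel: int) -> TraceSet:
    """Pick the signal and reference channels of every capillary.

    Lanes are concatenated batch by batch; shorter lanes are zero-padded
    to the global maximum length.
    """
    if signal_channel == reference_channel:
        raise ConfigError("signal and reference channels must differ")
    lanes_meta: list[LaneInfo] = []
    sig_cols, ref_cols = [], []
    for batch_id, lanes in batchset.batches:
        for ordinal, cap in enumerate(lanes):
            for idx, label in ((signal_channel, "signal"),
                               (reference_channel, "reference")):
                if not (0 <= idx < cap.n_channels):
                    raise ConfigError(
                        f"{label} channel {idx} out of range for lane "
                        f"{cap.capillary_id!r} ({cap.n_channels} channels)")
            sig_cols.append(np.asarray(cap.channels[:, signal_channel], float))
            ref_cols.append(np.asarray(cap.channels[:, reference_channel], float))
            lanes_meta.append(LaneInfo(cap.capillary_id, batch_id, ordinal))
    n = max(len(c) for c in sig_cols)

    def pad(cols):
        m = np.zeros((n, len(cols)))
        for j, c in enumerate(cols):
            m[:len(c), j] = c
        return m

    return TraceSet(pad(sig_cols), pad(ref_cols), lanes_meta)


def detect_roi(traces: TraceSet, smooth_window: int = 50,
               threshold_frac: float = 0.05) -> RegionOfInterest:
    """Locate the informative range by edge detection.

    The lane-summed intensity envelope (signal plus reference) is smoothed
    with a moving average, and the absolute first difference of that
    envelope is thresholded at ``threshold_frac`` of its maximum; the ROI
    is the smallest range containing every super-threshold edge, padded
    outward by ``smooth_window`` and clipped to the trace.  The threshold
    is relative, so the result is invariant to rescaling all lanes.
    """
    envelope = traces.signal.sum(axis=1) + traces.reference.sum(axis=1)
    if np.ptp(envelope) == 0:
        raise DetectionError(
            "traces are constant; set the region of interest manually")
    smooth = uniform_filter1d(envelope, size=smooth_window, mode="nearest")
    edges = np.abs(np.diff(smooth))
    hits = np.flatnonzero(edges >= threshold_frac * edges.max())
    start = max(0, int(hits[0]) - smooth_window)
    end = min(traces.n_samples, int(hits[-1]) + 1 + smooth_window)
    return RegionOfInterest(start, end)


def subtract_constant_baseline(traces: TraceSet,
                               percentile: float = 0.02) -> TraceSet:
    """Remove each lane's constant offset, estimated as a low order
    statistic (default the 2nd percentile) of the lane within the ROI.

    Values may go slightly negative; nothing is clipped — the least-squares
    peak fit downstream handles residual offsets better than truncation.
    """
    if traces.roi is None:
        raise ConfigError("set the region of interest before baseline removal")
    sl = traces.roi.slice()
    out = traces.copy()
    for mat in (out.signal, out.reference):
        base = np.quantile(mat[sl], percentile, axis=0, method="lower")
        mat -= base
    return out


def replace_roi(traces: TraceSet, roi: RegionOfInterest) -> TraceSet:
    if roi.end > traces.n_samples:
        raise ConfigError("ROI extends past the end of the traces")
    new = traces.copy()
    new.roi = roi
    return new
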
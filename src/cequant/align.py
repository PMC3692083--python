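"""Lane alignment: linear (shift + scale) registration within and between
batches, smooth-baseline removal, and piecewise-linear refinement by
dynamic programming.

Products in different capillaries run under slightly different
electrophoretic conditions, so their traces are shifted and rescaled
relative to each other, with residual local wobble on top.  Alignment is
scored on the co-loaded reference ladder — which is present in every
capillary and independent of the chemical modifier — and the estimated
warp is applied to both the ladder and the signal channel.

Conventions
-----------
A :class:`LinearTransform` describes the *displacement* of a profile
relative to its reference: the profile looks like the reference warped by
(shift, scale), i.e. ``profile[x] ~= reference[(x - shift) / scale]``.
``warp_profile`` applies a transform in that forward sense; aligning a
profile back onto the reference therefore applies the inverse transform.
Piecewise anchors are (source, target) pairs on the reference grid:
``aligned[y] = profile[interp(y, targets, sources)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import percentile_filter, uniform_filter1d

from .preprocess import ConfigError, TraceSet


class AlignmentError(RuntimeError):
    pass


@dataclass(frozen=True)
class LinearTransform:
    """Global shift (samples) and scale of one lane relative to a reference."""

    shift: float = 0.0
    scale: float = 1.0
    score: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def invert(self) -> "LinearTransform":
        return LinearTransform(-self.shift / self.scale, 1.0 / self.scale,
                               self.score)

    def compose(self, outer: "LinearTransform") -> "LinearTransform":
        """Transform equivalent to warping by self, then by ``outer``."""
        return LinearTransform(outer.shift + self.shift * outer.scale,
                               self.scale * outer.scale,
                               min(self.score, outer.score))

    @property
    def is_identity(self) -> bool:
        return self.shift == 0.0 and self.scale == 1.0


@dataclass(frozen=True)
class WarpTransform:
    """A linear displacement plus piecewise-linear anchor refinement."""

    linear: LinearTransform = field(default_factory=LinearTransform)
    anchors: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.anchors:
            src = np.array([a[0] for a in self.anchors])
            tgt = np.array([a[1] for a in self.anchors])
            if np.any(np.diff(src) <= 0) or np.any(np.diff(tgt) <= 0):
                raise ValueError(
                    "warp anchors must be strictly increasing in both "
                    "coordinates")


def _resample(profile: np.ndarray, source_pos: np.ndarray) -> np.ndarray:
    """Read ``profile`` at fractional positions; out of range reads 0."""
    profile = np.asarray(profile, dtype=float)
    out = np.interp(source_pos, np.arange(profile.size), profile,
                    left=0.0, right=0.0)
    out[(source_pos < 0) | (source_pos > profile.size - 1)] = 0.0
    return out


def _source_positions(t: WarpTransform | LinearTransform, n: int,
                      aligning: bool) -> np.ndarray:
    grid = np.arange(n, dtype=float)
    if isinstance(t, LinearTransform):
        lin, anchors = t, ()
    else:
        lin, anchors = t.linear, t.anchors
    if aligning:
        lin = lin.invert()
        if len(anchors) == 1:  # degenerate: constant offset
            grid = grid + (anchors[0][0] - anchors[0][1])
        elif anchors:
            src = np.array([a[0] for a in anchors])
            tgt = np.array([a[1] for a in anchors])
            # extend with constant end offsets so out-of-span samples keep
            # a sensible local mapping instead of a clamped constant source
            if tgt[0] > 0:
                src = np.concatenate([[src[0] - tgt[0]], src])
                tgt = np.concatenate([[0.0], tgt])
            if tgt[-1] < n - 1:
                src = np.concatenate([src, [src[-1] + (n - 1 - tgt[-1])]])
                tgt = np.concatenate([tgt, [float(n - 1)]])
            grid = np.interp(grid, tgt, src)  # refine first, in reference frame
    elif len(anchors) == 1:
        grid = grid - (anchors[0][0] - anchors[0][1])
    elif anchors:
        src = np.array([a[0] for a in anchors])
        tgt = np.array([a[1] for a in anchors])
        grid = np.interp(grid, src, tgt)
    if lin.is_identity:
        return grid
    return (grid - lin.shift) / lin.scale


def warp_profile(profile: np.ndarray, t: WarpTransform | LinearTransform
                 ) -> np.ndarray:
    """Apply a transform in the forward (displacing) sense.

    For a pure linear transform, output position ``x`` reads source
    position ``(x - shift) / scale``; anchor pairs define a piecewise
    linear source map in between.  Out-of-range samples read zero.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2:
        raise ValueError("profile must have at least 2 samples")
    return _resample(profile, _source_positions(t, profile.size, False))


def apply_alignment(profile: np.ndarray, t: WarpTransform | LinearTransform
                    ) -> np.ndarray:
    """Undo a fitted displacement: map the profile onto the reference grid."""
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2:
        raise ValueError("profile must have at least 2 samples")
    return _resample(profile, _source_positions(t, profile.size, True))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(a, b) and np.ptp(a) > 0:
        return 1.0  # exact self-correlation, immune to rounding
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    # snap accumulated float error so exact identity candidates stay exact
    return np.round(lo + step * np.arange(n + 1), 12)


def fit_linear(profile: np.ndarray, reference: np.ndarray,
               shift_range: tuple[float, float] = (-300.0, 300.0),
               shift_step: float = 10.0,
               scale_range: tuple[float, float] = (0.95, 1.05),
               scale_step: float = 0.005,
               roi: slice | None = None,
               refine_levels: int = 2,
               refine_candidates: int = 16,
               return_candidates: bool = False):
    """Estimate the shift and scale of ``profile`` relative to ``reference``
    by exhaustive grid search maximizing Pearson correlation.

    A coarse grid is followed by successive 10x-finer grids
    (``refine_levels`` of them) around each of the ``refine_candidates``
    best coarse optima; ladder traces are quasi-periodic, so chasing only
    the single best coarse point can lock onto an off-by-one-band
    registration whose coarse score happens to edge out the true basin.

    With ``return_candidates=True`` the refined optimum of every seed
    basin is returned (best first) so a caller can disambiguate
    near-tied registrations with extra evidence; an every-residue ladder
    is nearly periodic in band position, so shift-by-one-band
    registrations can be close competitors.

    Ties break toward the identity — (shift, scale) closest to (0, 1),
    then smallest shift, then smallest scale — so self-alignment returns
    shift 0, scale 1, score 1 exactly.
    """
    profile = np.asarray(profile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if profile.shape != reference.shape:
        raise ValueError("profile and reference must have the same length")
    sl = roi if roi is not None else slice(None)
    ref_win = reference[sl]
    if np.ptp(ref_win) == 0:
        raise AlignmentError("reference has zero variance over the ROI")
    if np.ptp(profile[sl]) == 0:
        raise AlignmentError("profile has zero variance over the ROI")
    def tie_key(score: float, s: float, k: float):
        return (-score, s * s + (k - 1.0) ** 2, abs(s), abs(k - 1.0), s, k)

    n = profile.size
    roi_grid = np.arange(n, dtype=float)[sl]
    xp = np.arange(n, dtype=float)

    def evaluate(shifts: np.ndarray, scales: np.ndarray):
        # aligning read position for displacement (s, k) is y*k + s;
        # resampling only the ROI keeps the search cheap
        results = []
        for k in scales:
            base = roi_grid * k
            for s in shifts:
                pos = base + s
                seg = np.interp(pos, xp, profile, left=0.0, right=0.0)
                seg[(pos < 0) | (pos > n - 1)] = 0.0
                score = _pearson(seg, ref_win)
                results.append((tie_key(score, float(s), float(k)),
                                LinearTransform(float(s), float(k)), score))
        results.sort(key=lambda r: r[0])
        return results

    coarse = evaluate(_grid(shift_range[0], shift_range[1], shift_step),
                      _grid(scale_range[0], scale_range[1], scale_step))
    # diverse refinement seeds: suppress coarse candidates that sit in the
    # same basin as an already selected one
    seeds: list[LinearTransform] = []
    for _, t, _ in coarse:
        if all(abs(t.shift - s.shift) > 2 * shift_step
               or abs(t.scale - s.scale) > 1.5 * scale_step for s in seeds):
            seeds.append(t)
        if len(seeds) >= refine_candidates:
            break
    refined = [coarse[0]]
    for seed_t in seeds:
        t_best = seed_t
        s_step, k_step = shift_step, scale_step
        cand = None
        for _ in range(refine_levels):
            s0, k0 = t_best.shift, t_best.scale
            shifts = _grid(s0 - s_step, s0 + s_step, s_step / 10.0)
            scales = _grid(max(1e-6, k0 - k_step), k0 + k_step, k_step / 10.0)
            s_step /= 10.0
            k_step /= 10.0
            cand = evaluate(shifts, scales)[0]
            t_best = cand[1]
        if cand is not None:
            refined.append(cand)
    refined.sort(key=lambda r: r[0])
    finals = [LinearTransform(t.shift, t.scale, score)
              for _, t, score in refined]
    if return_candidates:
        # drop near-duplicates (same basin reached from several seeds)
        unique: list[LinearTransform] = []
        for t in finals:
            if all(abs(t.shift - u.shift) > 1.0
                   or abs(t.scale - u.scale) > 5e-4 for u in unique):
                unique.append(t)
        return unique
    return finals[0]


def _fit_linear_disambiguated(profile: np.ndarray, reference: np.ndarray,
                              roi: slice | None,
                              margin: float = 0.15, max_candidates: int = 8,
                              piecewise_kwargs: dict | None = None,
                              **fit_kwargs) -> LinearTransform:
    """Linear fit with piecewise-DP disambiguation of near-tied basins.

    An every-residue ladder is nearly periodic, so an off-by-one-band
    registration can out-correlate the true one when local wobble is
    present.  Among refined candidates whose score comes within
    ``margin`` of the best, the one whose subsequent piecewise
    refinement achieves the highest DP objective wins: a misregistered
    lane leaves residual misfit the window offsets cannot absorb.
    """
    cands = fit_linear(profile, reference, roi=roi, return_candidates=True,
                       **fit_kwargs)
    close = [t for t in cands if t.score >= cands[0].score - margin]
    if len(close) <= 1:
        return cands[0]
    # candidates whose predicted misfit stays small across the ROI are the
    # same basin differing only along the shift/scale trade-off ridge; the
    # correlation already ranked those, so keep only basin representatives
    n = np.asarray(profile).size
    lo = (roi.start or 0) if roi is not None else 0
    hi = (roi.stop if roi is not None and roi.stop is not None else n)

    def same_basin(a: LinearTransform, b: LinearTransform) -> bool:
        mis = [abs((a.shift - b.shift) + (a.scale - b.scale) * x)
               for x in (lo, hi)]
        return max(mis) < 30.0

    basins: list[LinearTransform] = []
    for t in close:
        if all(not same_basin(t, u) for u in basins):
            basins.append(t)
    if len(basins) == 1:
        return close[0]
    pw_kwargs = piecewise_kwargs or {}
    best_t, best_obj = None, -np.inf
    for t in basins[:max_candidates]:
        warped = apply_alignment(profile, t)
        pw = fit_piecewise(warped, reference, roi=roi, **pw_kwargs)
        if pw.linear.score > best_obj:
            best_t, best_obj = t, pw.linear.score
    return best_t


def align_within_batch(traces: TraceSet, **fit_kwargs
                       ) -> list[LinearTransform]:
    """Align every lane to the first capillary of its batch.

    Lane 0 of each batch is the within-batch reference and gets the
    identity transform; alignment is scored on the ladder channel and
    near-tied registrations are resolved by their piecewise-DP score.
    """
    roi = traces.roi.slice() if traces.roi is not None else None
    out: list[LinearTransform] = []
    for batch_id, sl in traces.batch_slices():
        ref = traces.reference[:, sl.start]
        for j in range(sl.start, sl.stop):
            if j == sl.start:
                out.append(LinearTransform(0.0, 1.0, 1.0))
                continue
            try:
                out.append(_fit_linear_disambiguated(
                    traces.reference[:, j], ref, roi, **fit_kwargs))
            except AlignmentError as exc:
                raise AlignmentError(
                    f"lane {traces.lanes[j].capillary_id!r} "
                    f"(batch {batch_id!r}): {exc}") from exc
    return out


def align_between_batches(traces: TraceSet, within: list[LinearTransform],
                          **fit_kwargs) -> list[LinearTransform]:
    """Register each batch's reference lane onto batch 0's reference lane.

    Returns per-lane composed transforms (within-batch then batch-level).
    """
    roi = traces.roi.slice() if traces.roi is not None else None
    slices = traces.batch_slices()
    global_ref = traces.reference[:, slices[0][1].start]
    out: list[LinearTransform] = list(within)
    for b, (batch_id, sl) in enumerate(slices):
        if b == 0:
            continue
        batch_ref = apply_alignment(traces.reference[:, sl.start],
                                    within[sl.start])
        try:
            t_batch = _fit_linear_disambiguated(batch_ref, global_ref, roi,
                                                **fit_kwargs)
        except AlignmentError as exc:
            raise AlignmentError(f"batch {batch_id!r}: {exc}") from exc
        for j in range(sl.start, sl.stop):
            out[j] = within[j].compose(t_batch)
    return out


def subtract_smooth_baseline(profile: np.ndarray, window: int = 501
                             ) -> np.ndarray:
    """Remove a slowly varying baseline.

    The baseline is a moving 10th-percentile filter of width ``window``,
    smoothed by a moving average of the same width; band peaks sit far
    above the local 10th percentile as long as bands are sparse on the
    scale of the window, so they survive subtraction.  The window must
    span several band spacings, or the percentile starts tracking the
    band structure itself and biases the quantification.
    """
    profile = np.asarray(profile, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ConfigError("baseline window must be odd and >= 3")
    if window > profile.size:
        raise ConfigError("baseline window larger than the profile")
    base = percentile_filter(profile, 10, size=window, mode="nearest")
    base = uniform_filter1d(base, size=window, mode="nearest")
    return profile - base


def piecewise_windows(start: int, stop: int, window: int
                      ) -> list[tuple[int, int]]:
    """Contiguous window bounds over [start, stop); the last absorbs the
    remainder."""
    n_windows = max(1, (stop - start) // window)
    return [(start + w * window,
             stop if w == n_windows - 1 else start + (w + 1) * window)
            for w in range(n_windows)]


def piecewise_scores(profile: np.ndarray, reference: np.ndarray,
                     bounds: list[tuple[int, int]], offsets: np.ndarray
                     ) -> np.ndarray:
    """Per-window, per-offset Pearson correlation data terms.

    The window score at offset ``d`` correlates ``profile[lo+d:hi+d]``
    against ``reference[lo:hi]``; windows with zero variance score 0 and
    out-of-range samples read zero.
    """
    profile = np.asarray(profile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    scores = np.zeros((len(bounds), len(offsets)))
    for w, (lo, hi) in enumerate(bounds):
        ref_win = reference[lo:hi]
        if np.ptp(ref_win) == 0:
            continue
        rc = ref_win - ref_win.mean()
        rnorm = np.sqrt(np.dot(rc, rc))
        for i, d in enumerate(offsets):
            a, b = lo + int(d), hi + int(d)
            if a < 0 or b > profile.size:
                seg = np.zeros(hi - lo)
                src = np.arange(a, b)
                ok = (src >= 0) & (src < profile.size)
                seg[ok] = profile[src[ok]]
            else:
                seg = profile[a:b]
            if np.ptp(seg) == 0:
                continue
            pc = seg - seg.mean()
            den = np.sqrt(np.dot(pc, pc)) * rnorm
            if den > 0 and np.isfinite(den):  # tiny windows underflow
                scores[w, i] = float(np.dot(pc, rc) / den)
    return scores


def fit_piecewise(profile: np.ndarray, reference: np.ndarray,
                  window: int = 100, max_offset: int = 50, step: int = 1,
                  penalty: float = 0.01,
                  roi: slice | None = None,
                  return_details: bool = False):
    """Piecewise-linear refinement by dynamic programming.

    The ROI is split into contiguous windows of ``window`` samples (the
    last window absorbs the remainder).  Each window may read the profile
    at an integer offset in [-max_offset, +max_offset]; the window score
    is the Pearson correlation between the offset profile window and the
    reference window (zero-variance windows score 0), and adjacent
    windows pay ``penalty * |d - d'|`` for disagreeing offsets.  The DP
    maximizes total score minus total transition cost; ties break toward
    smaller absolute offsets.  The optimal offsets become warp anchors at
    window centers.
    """
    profile = np.asarray(profile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if window < 2 * max_offset:
        raise ConfigError("window must be at least twice max_offset")
    if roi is None:
        roi = slice(0, profile.size)
    start, stop = roi.start or 0, roi.stop if roi.stop is not None else profile.size
    bounds = piecewise_windows(start, stop, window)
    offsets = np.arange(-max_offset, max_offset + 1, step)
    n_windows, n_states = len(bounds), offsets.size
    scores = piecewise_scores(profile, reference, bounds, offsets)

    # DP over offset paths; tie-break toward smaller |offset|
    tie = np.abs(offsets) * 1e-12
    best = scores[0] - tie
    back = np.zeros((n_windows, n_states), dtype=int)
    trans = penalty * np.abs(offsets[:, None] - offsets[None, :])
    for w in range(1, n_windows):
        cand = best[None, :] - trans  # cand[i, j]: come to state i from j
        back[w] = np.argmax(cand, axis=1)
        best = scores[w] - tie + cand[np.arange(n_states), back[w]]
    path = np.zeros(n_windows, dtype=int)
    path[-1] = int(np.argmax(best))
    for w in range(n_windows - 1, 0, -1):
        path[w - 1] = back[w, path[w]]
    path_offsets = offsets[path].astype(float)

    # refine each window's offset with a doubled correlation window
    # centered at the same place, constrained near the DP path, plus a
    # parabolic sub-sample vertex: a single window at realistic noise
    # resolves the offset to +-2-3 samples only, and pooling the
    # neighboring bands tightens that without disturbing the path choice
    fine = path_offsets.astype(float).copy()
    centers_arr = np.array([(lo + hi - 1) / 2.0 for lo, hi in bounds])
    half_wide = max(2 * window, 2 * max_offset)
    for w in range(n_windows):
        c = int(round(centers_arr[w]))
        wlo, whi = max(0, c - half_wide), min(profile.size, c + half_wide)
        local = np.arange(path_offsets[w] - 4 * step,
                          path_offsets[w] + 4 * step + 1, step)
        sc = piecewise_scores(profile, reference, [(wlo, whi)], local)[0]
        i = int(np.argmax(sc))
        est = float(local[i])
        if 0 < i < local.size - 1:
            y0, y1, y2 = sc[i - 1], sc[i], sc[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                if abs(delta) <= 1.0:
                    est += delta * step
        fine[w] = est

    centers = np.array([(lo + hi - 1) / 2.0 for lo, hi in bounds])
    anchors = [(float(c + d), float(c))
               for c, d in zip(centers, fine)]
    # extend the end offsets to the ROI boundaries so anchors span it
    if centers[0] > start:
        anchors.insert(0, (float(start + fine[0]), float(start)))
    if centers[-1] < stop - 1:
        anchors.append((float(stop - 1 + fine[-1]), float(stop - 1)))
    # an extreme offset jump between adjacent windows can make anchor
    # sources non-monotone; drop offending anchors rather than fail
    clean = [anchors[0]]
    for a in anchors[1:]:
        if a[0] > clean[-1][0]:
            clean.append(a)
    warp = WarpTransform(LinearTransform(0.0, 1.0, float(np.max(best))),
                         tuple(clean))
    if return_details:
        window_scores = scores[np.arange(n_windows), path]
        return warp, centers, fine, window_scores, path_offsets
    return warp


def piecewise_objective(path_offsets: np.ndarray, scores: np.ndarray,
                        offsets: np.ndarray, penalty: float) -> float:
    """Objective value of an explicit offset path (for cross-checks)."""
    idx = [int(np.flatnonzero(offsets == d)[0]) for d in path_offsets]
    total = sum(scores[w, i] for w, i in enumerate(idx))
    total -= penalty * float(np.abs(np.diff(path_offsets)).sum())
    return float(total)


def _linear_from_offsets(centers: np.ndarray, offsets: np.ndarray,
                         scores: np.ndarray,
                         min_windows: int = 8,
                         max_slope: float = 0.01,
                         max_intercept: float = 40.0
                         ) -> tuple[float, float] | None:
    """Weighted linear trend (intercept, slope) of piecewise DP offsets.

    Windows with weak correlation carry little information and are
    down-weighted; a trend outside sane bounds (or too few informative
    windows) returns None and no correction is applied.
    """
    good = scores > 0.3
    if good.sum() < min_windows:
        return None
    c, d = centers[good], offsets[good]
    # Theil-Sen first: windows at the edge of the informative region can
    # report wildly wrong offsets with deceptively decent correlation,
    # and a single such outlier wrecks a least-squares trend
    ii, jj = np.triu_indices(c.size, k=1)
    slopes = (d[jj] - d[ii]) / (c[jj] - c[ii])
    slope = float(np.median(slopes))
    intercept = float(np.median(d - slope * c))
    resid = d - (intercept + slope * c)
    inliers = np.abs(resid) < 3.0
    if inliers.sum() >= min_windows:
        ci, di = c[inliers], d[inliers]
        cbar, dbar = ci.mean(), di.mean()
        var = ((ci - cbar) ** 2).sum()
        if var > 0:
            slope = float(((ci - cbar) * (di - dbar)).sum() / var)
            intercept = float(dbar - slope * cbar)
    if abs(slope) > max_slope or abs(intercept) > max_intercept:
        return None
    return intercept, slope


@dataclass
class AlignmentReport:
    """Per-lane alignment bookkeeping, serializable as a TSV table."""

    rows: list[dict]

    def to_tsv(self) -> str:
        header = ["lane", "batch", "shift", "scale", "score", "mean_abs_offset"]
        lines = ["\t".join(header)]
        for r in self.rows:
            lines.append("\t".join([
                str(r["lane"]), str(r["batch"]),
                f"{r['shift']:.4f}", f"{r['scale']:.6f}",
                f"{r['score']:.6f}", f"{r['mean_abs_offset']:.4f}"]))
        return "\n".join(lines) + "\n"


def align_all(traces: TraceSet, *, linear_kwargs: dict | None = None,
              baseline_window: int = 501,
              piecewise_kwargs: dict | None = None,
              do_piecewise: bool = True
              ) -> tuple[TraceSet, list[WarpTransform], AlignmentReport]:
    """Run the full alignment stage in order: within-batch linear,
    between-batch linear, smooth-baseline subtraction, piecewise
    refinement against the global reference lane.

    Returns the aligned trace set (both channels on the global reference
    grid, baselines removed), one :class:`WarpTransform` per lane, and a
    serializable report.
    """
    if traces.roi is None:
        raise ConfigError("set the region of interest before alignment")
    linear_kwargs = linear_kwargs or {}
    piecewise_kwargs = piecewise_kwargs or {}
    roi_sl = traces.roi.slice()

    within = align_within_batch(traces, piecewise_kwargs=piecewise_kwargs,
                                **linear_kwargs)
    composed = align_between_batches(traces, within,
                                     piecewise_kwargs=piecewise_kwargs,
                                     **linear_kwargs)

    n, L = traces.n_samples, traces.n_lanes
    sig = np.zeros((n, L))
    ref = np.zeros((n, L))
    for j in range(L):
        sig[:, j] = apply_alignment(traces.signal[:, j], composed[j])
        ref[:, j] = apply_alignment(traces.reference[:, j], composed[j])
    for j in range(L):
        sig[:, j] = subtract_smooth_baseline(sig[:, j], baseline_window)
        ref[:, j] = subtract_smooth_baseline(ref[:, j], baseline_window)

    global_ref = ref[:, 0]
    warps: list[WarpTransform] = []
    rows = []
    sig_out = np.zeros_like(sig)
    ref_out = np.zeros_like(ref)
    for j in range(L):
        if do_piecewise and j > 0:
            # iterate: DP offsets -> fold their linear trend back into the
            # lane transform -> re-refine.  The DP averages over many
            # windows, which pins shift and scale far more precisely than
            # the correlation ridge of the global grid search.
            pw = None
            for _ in range(3):
                pw, centers, offsets, scores, _ = fit_piecewise(
                    ref[:, j], global_ref, roi=roi_sl, return_details=True,
                    **piecewise_kwargs)
                correction = _linear_from_offsets(centers, offsets, scores)
                if correction is None:
                    break
                a, b = correction
                if abs(a) < 0.2 and abs(b) < 2e-5:
                    break
                composed[j] = LinearTransform(
                    composed[j].shift + a * composed[j].scale,
                    composed[j].scale * (1.0 + b),
                    composed[j].score)
                sig[:, j] = subtract_smooth_baseline(
                    apply_alignment(traces.signal[:, j], composed[j]),
                    baseline_window)
                ref[:, j] = subtract_smooth_baseline(
                    apply_alignment(traces.reference[:, j], composed[j]),
                    baseline_window)
                pw = None  # transform changed; refit below if loop ends
            if pw is None:
                pw = fit_piecewise(ref[:, j], global_ref, roi=roi_sl,
                                   **piecewise_kwargs)
            anchors = pw.anchors
            sig_out[:, j] = _resample(
                sig[:, j], _source_positions(pw, n, aligning=True))
            ref_out[:, j] = _resample(
                ref[:, j], _source_positions(pw, n, aligning=True))
        else:
            anchors = ()
            sig_out[:, j] = sig[:, j]
            ref_out[:, j] = ref[:, j]
        warps.append(WarpTransform(composed[j], anchors))
        mean_off = (float(np.mean([abs(s - t) for s, t in anchors]))
                    if anchors else 0.0)
        rows.append({
            "lane": traces.lanes[j].capillary_id,
            "batch": traces.lanes[j].batch_id,
            "shift": composed[j].shift, "scale": composed[j].scale,
            "score": composed[j].score, "mean_abs_offset": mean_off,
        })
    aligned = TraceSet(sig_out, ref_out, list(traces.lanes), traces.roi)
    return aligned, warps, AlignmentReport(rows)
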
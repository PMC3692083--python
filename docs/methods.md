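# Methods

This note records the model assumptions, parameter choices and
numerical decisions behind `cequant`, and what the synthetic benchmark
does and does not establish about real data.

## Signal model

A capillary trace is modelled as

    y(t) = Σ_i a_i · exp(−(t − p_i)² / 2σ_i²) + b(t) + ε(t)

where `i` ranges over residues of the probed sequence, `p_i` are
band centers strictly increasing in `t`, `σ_i` the band widths, `b(t)`
a smooth baseline and `ε` white noise. Residues map to centers through
a smooth mobility function; lanes differ by an affine time transform
(shift, scale) plus slowly varying local offsets. The co-loaded
reference ladder obeys the same warp as the signal channel, which is
the entire basis for modifier-independent alignment.

Quantities reported downstream are band areas `a_i σ_i √(2π)`. No
signal-decay correction, background (no-modification lane) subtraction
or normalization is applied; those conventions belong to the user.

## Preprocessing

* ROI detection: the lane-summed envelope (signal + ladder channels)
  is smoothed with a moving average (`smooth_window`, default 50
  samples), the absolute first difference is thresholded at
  `threshold_frac` (default 0.05) of its maximum, and the ROI is the
  smallest range covering all super-threshold edges, padded outward by
  one smoothing window. The threshold is relative, making detection
  invariant to overall gain. Manual `roi_start`/`roi_end` override it.
* Constant baseline: the 2nd percentile (not the minimum — robust to
  single-sample undershoot) of each lane within the ROI is subtracted
  per channel. Negative samples are never clipped anywhere in the
  pipeline; clipping would bias the least-squares areas.

## Alignment

* **Linear stage.** Exhaustive correlation search on the ladder
  channel: shift ±300 samples step 10, scale 0.95–1.05 step 0.005,
  followed by two successive 10×-finer refinement passes around the
  best coarse candidates. An every-residue ladder is nearly periodic,
  so off-by-one-band registrations are close competitors; refinement
  therefore seeds from up to 16 basin-distinct coarse candidates, and
  candidates whose score ties within 0.15 are arbitrated by which one
  the subsequent piecewise DP can actually flatten. Ties break toward
  the identity, so self-alignment returns shift 0, scale 1, score 1
  bit-exactly.
* **Smooth baseline.** A moving 10th-percentile filter smoothed by a
  moving average of the same width. The default width is 501 samples:
  the window must span several band spacings (~65 samples in the
  benchmark geometry), otherwise the percentile tracks the band
  structure itself and measurably biases the fitted areas.
* **Piecewise stage.** Windows of 100 samples, integer offsets within
  ±50, window score = local Pearson correlation (zero-variance windows
  score 0, underflowing windows are guarded to 0), transition cost
  0.01·|Δd|, solved exactly by dynamic programming; ties prefer
  smaller |offset|. Each window's offset is then re-measured with a
  doubled window centered at the same place (constrained to ±4 of the
  DP path) plus a parabolic sub-sample vertex — a single 100-sample
  window at realistic noise resolves its offset only to ±2–3 samples,
  and pooling neighboring bands tightens this without disturbing the
  path.
* **Trend feedback.** The fitted window offsets are regressed on the
  window centers (Theil–Sen first, then least squares on inliers;
  windows scoring below 0.3 are ignored) and the linear component is
  folded back into the lane's shift/scale, iterating up to three
  times. The correlation objective alone leaves a flat ridge where a
  shift error trades against a scale error; averaging the DP offsets
  over ~60 informative windows resolves that ridge to roughly ±0.7
  samples in shift and ±1.5e−4 in scale on the synthetic benchmark.
* Alignment is estimated on the ladder and applied to both channels.
  Cross-lane *signal* correlation is deliberately not used as an
  alignment objective: band heights are independent between lanes with
  different chemistries, so it carries no registration information.

## Band annotation

One consensus position per residue, shared by all lanes. Reagent
priors (weights in [0, 1]): DMS → 1 at A/C, CMCT → 1 at G/U, SHAPE →
1 everywhere, ddXTP → 1 at the complementary template residue and 0
elsewhere, no-modification/other → 0.5 everywhere. Unreactive residues
under DMS/CMCT keep weight 0.1 because real traces show residual stops
at every position.

Candidates are local maxima of the composite evidence (per-lane
max-normalized intensities, weighted by each lane's mean prior so an
all-zero-mask lane is inert) plus a uniform fallback grid. The DP
maximizes Σ_i Σ_lanes mask·intensity(p_i) − μ·Σ((Δp − d̂)/d̂)² with
μ = 1, expected spacing d̂ initialized to ROI length / L and refined
once from the first pass's median spacing, and transitions restricted
to spacings in [0.4, 2.5]·d̂. Final positions are polished to the
sub-sample vertex of the evidence parabola when a local maximum sits
within a quarter spacing. The stop-site numbering convention
(modified residue i versus i±1) is exposed as an integer
`annotation_offset`; lanes increase residue index with elution time by
default.

## Peak fitting

Centers fixed at annotated positions; widths fixed at
`width_factor × local median spacing` (window of 5 spacings). The
factor defaults to 0.25 but is calibrated per run against the global
reference ladder by a bounded scalar search minimizing the fit
residual — band width varies between runs, and a mismatched width is
the single largest error source in quantification. Amplitudes solve a
non-negative least-squares problem per lane (design columns truncated
at ±5σ; truncation error < 1e−6 of column mass). The lane-level fit
additionally includes sign-unconstrained hat-function columns every
400 samples which absorb residual smooth baseline jointly; hats form a
partition of unity, so constants and linear trends cannot leak into
band amplitudes. Isolated-single-band fits keep the purely Gaussian
design, because a lone narrow peak can be partially represented by a
broad baseline column.

## Synthetic benchmark

The generator emulates: Gamma(1.5, 1)-distributed reactivities times
the modifier mask plus 0.05 background; a quadratic mobility map
(start 1600, mean spacing 65, curvature 0.04 over 10⁴ samples for 92
residues); Gaussian bands of σ = 12 samples (~0.18× spacing — a sharp,
well-run capillary); a uniform every-residue ladder in a second
channel; per-lane planted shift (±150), scale (1 ± 0.02) and a smooth
local-offset curve (bounded random walk through 5 nodes, smoothed so
the local slope stays well below one sample per alignment window —
electrophoretic wobble drifts, it does not kink); constant (200
counts) plus slow sinusoidal (60 counts) baselines; white noise of
0.1 (so a unit-reactivity band has peak signal-to-noise 10); 1000
counts per reactivity unit, rounded to integers for the ABIF files.
Signal decay is off by default, matching the decision to leave decay
correction to the user.

What passing the benchmark shows: the pipeline undoes the distortions
it models — affine warps, smooth local wobble, smooth baselines,
additive noise — well enough that fitted areas track planted
reactivities at per-lane r² ≥ 0.99. What it does not show: robustness
to dye spectral cross-talk, saturation artifacts, mobility anomalies
(compressions), signal decay, or mis-specified sequences; real ladders
are also sparser and less periodic than the uniform synthetic one,
which if anything makes the registration problem easier.

## Numerical and reproducibility notes

* All randomness flows from one integer seed through
  `numpy.random.default_rng`; generation is byte-deterministic.
* Grid values in the linear search are rounded to 12 decimals so the
  exact identity candidate stays exactly (0, 1).
* TSV and RDAT exports format numbers with 6 significant digits, use
  UTF-8 and Unix line endings, and are byte-identical across runs;
  the RDAT rows are pre-rounded to the same precision so the two
  formats carry identical numbers.
* Degenerate inputs: constant profiles raise alignment errors rather
  than returning meaningless correlations; zero-variance or
  underflowing DP windows score 0; a single annotated band requires an
  explicit width.
* Benchmark problem sizes (6 lanes × 92 nt × 10⁴ samples, 20 seeds for
  the recovery and fidelity properties) keep a full test run in the
  ten-minute range on one core while matching the scale the method is
  meant for.
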
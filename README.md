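# cequant

Alignment, band annotation and quantification of high-throughput
capillary electrophoresis (CE) traces from nucleic-acid chemical
probing experiments.

## The problem

Chemical probing reads out RNA (or DNA) structure one residue at a
time: a reagent — dimethyl sulfate (DMS), CMCT, or a SHAPE acylation
reagent — modifies flexible residues, reverse transcription stops at
each adduct, and the resulting cDNA fragments are separated by
capillary electrophoresis. Each fragment length appears as a Gaussian
band in a fluorescence-versus-time trace, so a trace holds hundreds of
bands whose areas encode per-residue reactivity. A modern experiment
spans many capillaries run in several machine batches, each trace
shifted, stretched and locally wobbled relative to the others, riding
on a drifting baseline.

`cequant` turns a folder (or zip) of raw `.ab1`/`.fsa` ABIF sequencer
files into an aligned, residue-annotated matrix of band areas — one
row per residue, one column per capillary — exported as tab-delimited
text and as an RDAT chemical-mapping file. Signal-decay correction,
background subtraction and normalization are deliberately left to the
user, as those post-processing conventions differ between labs.

## Method

1. **Preprocess** — pick the signal and reference-ladder spectral
   channels, find the informative region of interest (ROI) with a 1-D
   edge detector on the lane-summed envelope, and subtract each lane's
   constant baseline (a low order statistic within the ROI).
2. **Align** — every capillary co-loads a reference ladder in a second
   color. Each lane's ladder is registered to the first capillary of
   its batch by a grid search over shift `s` and scale `k` maximizing
   the Pearson correlation of the warped profile (position `x` reads
   source `(x − s)/k`); batches are then registered to the first batch
   the same way. After a moving-percentile smooth-baseline removal, a
   dynamic program refines the residual warp: the ROI is cut into
   windows, each window may shift by an integer offset `d ∈ [−50, 50]`,
   window score is the local Pearson correlation and adjacent windows
   pay `λ·|d − d′|`; the optimal offset path becomes a piecewise-linear
   warp. The linear trend of the fitted offsets is folded back into the
   lane's shift/scale estimate and the refinement repeated, which pins
   the planted shift to ±1 sample and scale to ±0.001 on synthetic
   benchmarks.
3. **Annotate** — each residue gets one consensus trace position shared
   by all aligned lanes. Reagent priors say where bands should appear
   (DMS marks A/C, CMCT marks G/U, SHAPE marks everything, a ddXTP
   ladder marks the template residues pairing with X); a dynamic
   program places strictly increasing positions `p_1 < … < p_L`
   maximizing the mask-weighted lane intensities minus a quadratic
   penalty for uneven spacing. Positions can be edited one residue at a
   time (`cequant adjust`) and the pipeline re-run from the fit stage.
4. **Fit** — each lane is modelled as a sum of Gaussians centered at
   the annotated positions with widths proportional to the local band
   spacing (the factor is calibrated on the reference ladder);
   amplitudes are obtained by non-negative least squares and the band
   area is the analytic integral `a·σ·√(2π)`.

## Worked example

Generate a synthetic six-condition experiment over a random 92-nt
sequence — complete with planted shifts, scales, baselines, noise and
a ground-truth table — then run the full pipeline:

```
$ cequant synth --seed 7 --out fx --length 92
wrote 6 lanes in 1 batches to fx

$ cequant run --input fx --sequence "$(cat fx/sequence.txt)" \
      --modifiers SHAPE,DMS,CMCT,ddTTP,nomod,other --out results
annotated and quantified 552 bands (92 residues x 6 capillaries)
  tsv: results/quantification.tsv
  rdat: results/result.rdat
  alignment_report: results/alignment_report.tsv
  annotation: results/annotation.tsv
  gel_image: results/gel.png
```

552 bands = 92 residues × 6 capillaries: every residue of the probed
sequence was assigned a band in every lane. The quantification table
has one row per residue and one column per capillary; values are
fitted band areas (fluorescence × samples):

```
residue  000_b0_lane0  001_b0_lane1  002_b0_lane2  ...
U1       4900.71       3783.68       37853.7       ...
G2       38591.7       9987.55       20567.7       ...
```

The alignment report lists each lane's fitted displacement relative to
the global reference and the ladder correlation achieved:

```
lane          batch   shift      scale     score     mean_abs_offset
000_b0_lane0  batch0  0.0000     1.000000  1.000000  0.0000
001_b0_lane1  batch0  115.5139   0.982055  0.924459  4.1722
```

`results/result.rdat` holds the same matrix in RDAT form with the
sequence, residue numbering and per-capillary `modifier:` annotations,
ready for downstream chemical-mapping tools. The same works on real
data: point `--input` at a directory with one subfolder of `.ab1`
files per sequencer batch (or a zip of the same layout).

As a library:

```python
import cequant as cq

batches = cq.load_batches("fx")
traces = cq.select_channels(batches, signal_channel=0, reference_channel=1)
traces = cq.preprocess.replace_roi(traces, cq.detect_roi(traces))
traces = cq.subtract_constant_baseline(traces)
aligned, warps, report = cq.align_all(traces)
annotation = cq.auto_annotate(aligned, sequence, modifiers)
quant = cq.quantify(cq.fit_lanes(aligned, annotation), aligned)
```

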
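"""End-to-end pipeline orchestration with resumable stage checkpoints.

Stages run in the order load → preprocess → align → annotate → fit →
export, mirroring how an analyst works through a CE dataset with
checkpoints between stages: after automated annotation the user may edit
band positions and re-run only the downstream stages.  Each stage writes
its state under ``<out>/checkpoints`` so later stages can resume without
recomputing alignment.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import abif_io, align, annotate, peakfit, preprocess, rdat, render
from .annotate import BandAnnotation, Modifier
from .preprocess import ConfigError, RegionOfInterest, TraceSet

log = logging.getLogger("cequant")

STAGES = ("preprocess", "align", "annotate", "fit")


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    input_path: str
    sequence: str
    modifiers: list[str]
    output_dir: str
    signal_channel: int = 0
    reference_channel: int = 1
    roi_start: int | None = None        # manual ROI override
    roi_end: int | None = None
    roi_smooth_window: int = 50
    roi_threshold_frac: float = 0.05
    baseline_percentile: float = 0.02
    smooth_baseline_window: int = 501
    shift_range: float = 300.0
    scale_range: float = 0.05
    piecewise_window: int = 100
    piecewise_max_offset: int = 50
    piecewise_penalty: float = 0.01
    annotation_mu: float = 1.0
    annotation_offset: int = 0          # residue numbering offset
    orientation: str = "forward"        # residue index vs elution direction
    width_factor: "float | str" = "auto"  # spacing-to-sigma; auto-calibrated
    structure: str = ""
    name: str = ""
    rdat_version: str = rdat.DEFAULT_VERSION
    render_images: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise ConfigError(f"input path {self.input_path} does not exist")
        if not self.sequence:
            raise ConfigError("a probed sequence is required")
        if not self.modifiers:
            raise ConfigError("per-capillary modifiers are required")
        for m in self.modifiers:
            Modifier.parse(m)


@dataclass
class PipelineResult:
    traces: TraceSet
    warps: list
    report: align.AlignmentReport
    annotation: BandAnnotation
    quant: peakfit.QuantResult
    record: rdat.RdatRecord
    outputs: dict[str, str] = field(default_factory=dict)


def _ckpt_dir(config: RunConfig) -> Path:
    d = Path(config.output_dir) / "checkpoints"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _save_traces(path: Path, traces: TraceSet) -> None:
    np.savez_compressed(
        path,
        signal=traces.signal, reference=traces.reference,
        roi=np.array([traces.roi.start, traces.roi.end])
        if traces.roi else np.array([-1, -1]),
        lane_ids=np.array([l.capillary_id for l in traces.lanes]),
        batch_ids=np.array([l.batch_id for l in traces.lanes]),
        ordinals=np.array([l.batch_ordinal for l in traces.lanes]))


def _load_traces(path: Path) -> TraceSet:
    z = np.load(path, allow_pickle=False)
    lanes = [preprocess.LaneInfo(str(c), str(b), int(o))
             for c, b, o in zip(z["lane_ids"], z["batch_ids"], z["ordinals"])]
    roi = None
    if z["roi"][0] >= 0:
        roi = RegionOfInterest(int(z["roi"][0]), int(z["roi"][1]))
    return TraceSet(z["signal"], z["reference"], lanes, roi)


def stage_preprocess(config: RunConfig) -> TraceSet:
    batchset = abif_io.load_batches(config.input_path)
    traces = preprocess.select_channels(batchset, config.signal_channel,
                                        config.reference_channel)
    if config.roi_start is not None and config.roi_end is not None:
        roi = RegionOfInterest(config.roi_start, config.roi_end)
    else:
        roi = preprocess.detect_roi(traces, config.roi_smooth_window,
                                    config.roi_threshold_frac)
    traces = preprocess.replace_roi(traces, roi)
    return preprocess.subtract_constant_baseline(
        traces, config.baseline_percentile)


def stage_align(config: RunConfig, traces: TraceSet):
    return align.align_all(
        traces,
        linear_kwargs={"shift_range": (-config.shift_range,
                                       config.shift_range),
                       "scale_range": (1 - config.scale_range,
                                       1 + config.scale_range)},
        baseline_window=config.smooth_baseline_window,
        piecewise_kwargs={"window": config.piecewise_window,
                          "max_offset": config.piecewise_max_offset,
                          "penalty": config.piecewise_penalty})


def stage_annotate(config: RunConfig, aligned: TraceSet) -> BandAnnotation:
    if len(config.modifiers) != aligned.n_lanes:
        raise ConfigError(
            f"{len(config.modifiers)} modifiers for {aligned.n_lanes} lanes")
    return annotate.auto_annotate(aligned, config.sequence, config.modifiers,
                                  mu=config.annotation_mu,
                                  offset=config.annotation_offset,
                                  orientation=config.orientation)


def stage_fit(config: RunConfig, aligned: TraceSet,
              annotation: BandAnnotation) -> peakfit.QuantResult:
    model = peakfit.fit_lanes(aligned, annotation, width_factor=config.width_factor)
    mods = [Modifier.parse(m) for m in config.modifiers]
    return peakfit.quantify(model, aligned, modifiers=mods)


def run_pipeline(config: RunConfig, resume_from: str = "preprocess"
                 ) -> PipelineResult:
    """Run the pipeline, optionally resuming from a later stage using the
    checkpoints of a previous run (e.g. after a manual annotation edit).
    Any stage failure raises with the stage name; earlier outputs are
    kept on disk."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ckpt = _ckpt_dir(config)
    if resume_from not in STAGES:
        raise ConfigError(f"unknown stage {resume_from!r}; one of {STAGES}")
    start_idx = STAGES.index(resume_from)
    timings: dict[str, float] = {}

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", name, timings[name])
        return result

    # stage 1-2: preprocess + align (or resume from checkpoints)
    if start_idx <= STAGES.index("align"):
        if start_idx == 0 or not (ckpt / "preprocessed.npz").exists():
            traces = run_stage("preprocess", stage_preprocess, config)
            _save_traces(ckpt / "preprocessed.npz", traces)
        else:
            traces = _load_traces(ckpt / "preprocessed.npz")
        aligned, warps, report = run_stage("align", stage_align, config, traces)
        _save_traces(ckpt / "aligned.npz", aligned)
        (out / "alignment_report.tsv").write_text(report.to_tsv())
    else:
        if not (ckpt / "aligned.npz").exists():
            raise ConfigError(
                f"cannot resume from {resume_from!r}: no alignment checkpoint")
        aligned = _load_traces(ckpt / "aligned.npz")
        warps, report = [], align.AlignmentReport([])

    # stage 3: annotate (a saved manual annotation wins when resuming there)
    ann_path = ckpt / "annotation.tsv"
    if start_idx >= STAGES.index("fit") and ann_path.exists():
        annotation = BandAnnotation.from_tsv(
            ann_path.read_text(), config.sequence, config.annotation_offset)
    else:
        annotation = run_stage("annotate", stage_annotate, config, aligned)
        ann_path.write_text(annotation.to_tsv())
    (out / "annotation.tsv").write_text(annotation.to_tsv())

    # stage 4: fit + export
    quant = run_stage("fit", stage_fit, config, aligned, annotation)
    record = rdat.build_rdat(
        quant, annotation, name=config.name or Path(config.input_path).stem,
        structure=config.structure, version=config.rdat_version)
    outputs = {}
    tsv_path = out / "quantification.tsv"
    tsv_path.write_text(quant.to_tsv(annotation))
    (out / "amplitudes.tsv").write_text(quant.to_tsv(annotation, "amplitude"))
    rdat_path = out / "result.rdat"
    rdat.write_rdat(record, rdat_path)
    outputs["tsv"] = str(tsv_path)
    outputs["rdat"] = str(rdat_path)
    outputs["alignment_report"] = str(out / "alignment_report.tsv")
    outputs["annotation"] = str(out / "annotation.tsv")
    if config.render_images:
        img_path = out / "gel.png"
        render.render_gel(aligned, annotation, img_path)
        outputs["gel_image"] = str(img_path)
    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    return PipelineResult(aligned, warps, report, annotation, quant, record,
                          outputs)
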
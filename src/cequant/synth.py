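"""Synthetic multi-batch capillary electrophoresis experiments with full
ground truth.

The generator emulates what the pipeline must undo: per-residue bands of
reagent-dependent intensity on a smoothly curved mobility axis, a
co-loaded uniform reference ladder in a second spectral channel, per-lane
global shift/scale and smooth local piecewise distortions, constant plus
slowly drifting baselines, and additive Gaussian noise.  Lanes are
written as valid ABIF files so fixtures exercise the real input path.

Default settings mirror a small structure-mapping experiment: a 92-nt
RNA probed in six conditions (SHAPE, DMS, CMCT, a ddTTP ladder, no
modification, other), ~10^4 samples per trace, band peak height ten
times the noise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .abif_io import BatchSet, RawCapillary, abif_write
from .align import LinearTransform, WarpTransform, warp_profile
from .annotate import Modifier, reactivity_mask

DEFAULT_MODIFIERS = ("SHAPE", "DMS", "CMCT", "ddTTP", "nomod", "other")


@dataclass
class SynthConfig:
    """All knobs of the generator; the seed is mandatory."""

    seed: int
    sequence_length: int = 92
    sequence: str = "random"
    n_batches: int = 1
    lanes_per_batch: int = 6
    modifiers: tuple[str, ...] = DEFAULT_MODIFIERS
    n_samples: int = 10000
    mobility_start: float = 1600.0
    mean_spacing: float = 65.0
    spacing_curvature: float = 0.04     # quadratic term of the mobility map
    band_sigma: float = 12.0   # sharp bands, ~0.18 x mean spacing
    decay_rate: float = 1.0             # per-band attenuation; 1.0 = off
    shift_range: float = 150.0          # planted |shift| bound, samples
    scale_range: float = 0.02           # planted |scale - 1| bound
    piecewise_offset_range: float = 0.0  # planted local offset bound, samples
    piecewise_nodes: int = 5
    baseline_const: float = 200.0       # counts
    baseline_drift_amp: float = 60.0    # counts
    noise_sigma: float = 0.1            # relative to a unit-reactivity peak
    amplitude: float = 1000.0           # counts per unit reactivity
    ladder_intensity: float = 1.0       # reference-channel band height
    gamma_shape: float = 1.5
    gamma_scale: float = 1.0
    background_reactivity: float = 0.05

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory; no implicit randomness")
        mods = tuple(Modifier.parse(m) for m in self.modifiers)
        if len(mods) not in (self.lanes_per_batch,
                             self.n_batches * self.lanes_per_batch):
            raise ValueError(
                f"{len(mods)} modifiers for {self.lanes_per_batch} lanes "
                f"per batch")
        self.modifiers = mods

    @property
    def n_lanes(self) -> int:
        return self.n_batches * self.lanes_per_batch

    def lane_modifiers(self) -> list[Modifier]:
        if len(self.modifiers) == self.n_lanes:
            return list(self.modifiers)
        return list(self.modifiers) * self.n_batches


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle comparisons."""

    sequence: str
    true_reactivities: np.ndarray       # residues x lanes
    true_centers: np.ndarray            # residues (reference frame)
    transforms: list[WarpTransform]     # planted per-lane distortions
    modifiers: list[Modifier]
    piecewise_curves: list[np.ndarray]  # planted local offset o(x) per lane

    def expected_offsets(self, lane: int, centers: np.ndarray) -> np.ndarray:
        """Planted piecewise offsets the aligner should report at the
        given window centers (sign matching the recovery convention)."""
        curve = self.piecewise_curves[lane]
        return -np.interp(centers, np.arange(curve.size), curve)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def mobility_centers(config: SynthConfig) -> np.ndarray:
    i = np.arange(config.sequence_length, dtype=float)
    centers = (config.mobility_start + config.mean_spacing * i
               + config.spacing_curvature * i ** 2)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("mobility map is non-monotone; adjust curvature")
    if centers[-1] >= config.n_samples - 6 * config.band_sigma:
        raise ValueError("mobility map runs off the end of the trace")
    return centers


def _gaussian_comb(n: int, centers: np.ndarray, heights: np.ndarray,
                   sigma: float) -> np.ndarray:
    x = np.arange(n, dtype=float)
    out = np.zeros(n)
    for c, h in zip(centers, heights):
        lo = max(0, int(c - 6 * sigma))
        hi = min(n, int(c + 6 * sigma) + 1)
        out[lo:hi] += h * np.exp(-0.5 * ((x[lo:hi] - c) / sigma) ** 2)
    return out


def _smooth_offset_curve(rng: np.random.Generator, n: int, bound: float,
                         nodes: int) -> np.ndarray:
    """A slowly varying offset curve o(x), zero at the trace ends.

    Node values follow a bounded random walk (step <= half the bound)
    and the interpolated curve is smoothed, so the local slope stays
    well below one sample per window of the piecewise aligner —
    electrophoretic wobble drifts gradually, it does not kink.
    """
    if bound == 0:
        return np.zeros(n)
    xs = np.linspace(0, n - 1, nodes + 2)
    ys = np.zeros(nodes + 2)
    for i in range(1, nodes + 1):
        ys[i] = np.clip(ys[i - 1] + rng.uniform(-bound / 2, bound / 2),
                        -bound, bound)
    ys[-1] = 0.0
    curve = np.interp(np.arange(n), xs, ys)
    return uniform_filter1d(curve, size=max(3, n // 16), mode="nearest")


def generate(config: SynthConfig) -> tuple[BatchSet, GroundTruth]:
    """Build a synthetic experiment; byte-deterministic for a fixed seed.

    Per lane, the true reactivity of residue i is
    ``mask_i * Gamma(shape, scale) + background``; the clean signal is a
    Gaussian comb at the mobility centers, the reference channel a
    uniform ladder over every residue.  Both channels then receive the
    planted piecewise distortion, the planted linear shift/scale, a
    constant plus sinusoidal-drift baseline and i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    seq = (random_sequence(rng, config.sequence_length)
           if config.sequence == "random" else config.sequence)
    if len(seq) != config.sequence_length:
        raise ValueError("sequence length does not match config")
    centers = mobility_centers(config)
    mods = config.lane_modifiers()
    n = config.n_samples
    L = config.n_lanes

    reactivities = np.zeros((config.sequence_length, L))
    transforms: list[WarpTransform] = []
    curves: list[np.ndarray] = []
    batches: list[tuple[str, list[RawCapillary]]] = []
    lane = 0
    decay = config.decay_rate ** np.arange(config.sequence_length)
    ladder_heights = np.full(config.sequence_length,
                             config.ladder_intensity) * decay
    x = np.arange(n, dtype=float)
    for b in range(config.n_batches):
        caps: list[RawCapillary] = []
        for k in range(config.lanes_per_batch):
            mask = reactivity_mask(seq, mods[lane])
            r = (mask * rng.gamma(config.gamma_shape, config.gamma_scale,
                                  config.sequence_length)
                 + config.background_reactivity)
            reactivities[:, lane] = r
            signal = _gaussian_comb(n, centers, r * decay, config.band_sigma)
            ladder = _gaussian_comb(n, centers, ladder_heights,
                                    config.band_sigma)

            # the global reference lane (batch 0, lane 0) stays undistorted
            if b == 0 and k == 0:
                shift, scale = 0.0, 1.0
                curve = np.zeros(n)
            else:
                shift = float(rng.uniform(-config.shift_range,
                                          config.shift_range))
                scale = float(rng.uniform(1 - config.scale_range,
                                          1 + config.scale_range))
                curve = _smooth_offset_curve(rng, n,
                                             config.piecewise_offset_range,
                                             config.piecewise_nodes)
            lin = LinearTransform(shift, scale, score=1.0)
            if curve.any():
                signal = np.interp(x + curve, x, signal)
                ladder = np.interp(x + curve, x, ladder)
            if not lin.is_identity:
                signal = warp_profile(signal, lin)
                ladder = warp_profile(ladder, lin)

            drift_phase = rng.uniform(0, 2 * np.pi)
            drift_period = rng.uniform(0.5, 1.5) * n
            drift = (config.baseline_drift_amp / config.amplitude
                     * np.sin(2 * np.pi * x / drift_period + drift_phase))
            base = config.baseline_const / config.amplitude

            chan = np.zeros((n, 4))
            for col, clean in ((0, signal), (1, ladder)):
                noisy = clean + base + drift + rng.normal(
                    0, config.noise_sigma, n)
                chan[:, col] = np.round(noisy * config.amplitude)
            # two dark spectral channels, as on a real 4-dye instrument
            chan[:, 2] = np.round(rng.normal(
                config.baseline_const,
                config.noise_sigma * config.amplitude, n))
            chan[:, 3] = np.round(rng.normal(
                config.baseline_const,
                config.noise_sigma * config.amplitude, n))

            caps.append(RawCapillary(
                capillary_id=f"b{b}_lane{k}",
                batch_id=f"batch{b}",
                channels=chan.astype(np.int64),
                sample_name=f"synthetic_{mods[lane].value}_{lane}",
            ))
            transforms.append(WarpTransform(lin))
            curves.append(curve)
            lane += 1
        batches.append((f"batch{b}", caps))

    truth = GroundTruth(sequence=seq, true_reactivities=reactivities,
                        true_centers=centers, transforms=transforms,
                        modifiers=mods, piecewise_curves=curves)
    return BatchSet(batches), truth


def write_fixture(batchset: BatchSet, truth: GroundTruth, out_dir) -> None:
    """Write the experiment as one ABIF file per lane in per-batch
    subfolders, plus tab-delimited truth tables, so ``load_batches`` can
    consume the layout unchanged."""
    out = Path(out_dir)
    for batch_id, lanes in batchset.batches:
        bdir = out / batch_id
        bdir.mkdir(parents=True, exist_ok=True)
        for i, cap in enumerate(lanes):
            abif_write(cap, bdir / f"{i:03d}_{cap.capillary_id}.fsa")

    lanes_flat = batchset.all_lanes()
    lines = ["residue\tbase\tlane\tmodifier\ttrue_reactivity\ttrue_center"]
    for i in range(truth.true_reactivities.shape[0]):
        for j in range(truth.true_reactivities.shape[1]):
            lines.append("\t".join([
                str(i + 1), truth.sequence[i], lanes_flat[j].capillary_id,
                truth.modifiers[j].value,
                f"{truth.true_reactivities[i, j]:.6g}",
                f"{truth.true_centers[i]:.3f}"]))
    (out / "ground_truth.tsv").write_text("\n".join(lines) + "\n")

    tlines = ["lane\tshift\tscale"]
    for j, t in enumerate(truth.transforms):
        tlines.append(f"{lanes_flat[j].capillary_id}\t"
                      f"{t.linear.shift:.4f}\t{t.linear.scale:.6f}")
    (out / "planted_transforms.tsv").write_text("\n".join(tlines) + "\n")
    (out / "sequence.txt").write_text(truth.sequence + "\n")
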
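"""Band annotation: mapping electrophoretic bands to residues.

Each residue of the probed sequence leaves a band whose expected
intensity depends on the chemistry applied to the lane — DMS marks A/C,
CMCT marks G/U, SHAPE marks every residue, and a ddNTP sequencing lane
marks the template residues complementary to its dideoxynucleotide.
Those priors, together with the aligned intensities of all lanes, drive a
dynamic program that places one strictly increasing trace position per
residue.  Positions are shared across lanes: after alignment, a residue's
band sits at one consensus location in every capillary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import argrelmax

from .preprocess import TraceSet


class AnnotationError(RuntimeError):
    pass


class SequenceError(ValueError):
    pass


class Modifier(str, Enum):
    """The nine per-capillary modifier options."""

    DMS = "DMS"
    CMCT = "CMCT"
    SHAPE = "SHAPE"
    ddGTP = "ddGTP"
    ddATP = "ddATP"
    ddTTP = "ddTTP"
    ddCTP = "ddCTP"
    nomod = "nomod"
    other = "other"

    @classmethod
    def parse(cls, s: "str | Modifier") -> "Modifier":
        if isinstance(s, Modifier):
            return s
        for m in cls:
            if m.value.lower() == str(s).lower():
                return m
        raise ValueError(f"unknown modifier {s!r}; choose one of "
                         f"{[m.value for m in cls]}")

    @property
    def is_ladder(self) -> bool:
        return self in (Modifier.ddGTP, Modifier.ddATP,
                        Modifier.ddTTP, Modifier.ddCTP)


# ddXTP terminates opposite its complementary template base
_DDNTP_TARGET = {Modifier.ddTTP: "A", Modifier.ddATP: "U",
                 Modifier.ddCTP: "G", Modifier.ddGTP: "C"}

_BACKGROUND_WEIGHT = 0.1  # residual stops appear at unreactive residues too


def _clean_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    for i, c in enumerate(seq):
        if c not in "ACGU":
            raise SequenceError(
                f"invalid character {sequence[i]!r} at position {i}")
    return seq


def reactivity_mask(sequence: str, modifier: "Modifier | str") -> np.ndarray:
    """Per-residue prior band weight in [0, 1] for one lane's chemistry."""
    if not sequence:
        raise SequenceError("sequence is empty")
    seq = _clean_sequence(sequence)
    modifier = Modifier.parse(modifier)
    bases = np.array(list(seq))
    if modifier is Modifier.SHAPE:
        return np.ones(len(seq))
    if modifier is Modifier.DMS:
        return np.where(np.isin(bases, ["A", "C"]), 1.0, _BACKGROUND_WEIGHT)
    if modifier is Modifier.CMCT:
        return np.where(np.isin(bases, ["G", "U"]), 1.0, _BACKGROUND_WEIGHT)
    if modifier.is_ladder:
        return np.where(bases == _DDNTP_TARGET[modifier], 1.0, 0.0)
    return np.full(len(seq), 0.5)  # nomod / other: uninformative


@dataclass(frozen=True)
class BandAnnotation:
    """Consensus residue → trace-position map shared by all aligned lanes."""

    sequence: str
    positions: np.ndarray          # strictly increasing, one per residue
    annotated_residues: tuple[int, ...]  # 0-based indices into sequence
    offset: int = 0                # added to 1-based numbering for display

    def __post_init__(self):
        object.__setattr__(self, "positions",
                           np.asarray(self.positions, dtype=float))
        if len(self.positions) != len(self.annotated_residues):
            raise ValueError("positions and residue indices differ in length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("annotation positions must strictly increase")

    def residue_labels(self) -> list[str]:
        seq = _clean_sequence(self.sequence)
        return [f"{seq[i]}{i + 1 + self.offset}" for i in self.annotated_residues]

    def to_tsv(self) -> str:
        seq = _clean_sequence(self.sequence)
        lines = ["residue_index\tbase\tposition"]
        for i, p in zip(self.annotated_residues, self.positions):
            lines.append(f"{i + 1 + self.offset}\t{seq[i]}\t{p:.3f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, sequence: str, offset: int = 0
                 ) -> "BandAnnotation":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        residues = tuple(int(r[0]) - 1 - offset for r in rows)
        positions = np.array([float(r[2]) for r in rows])
        return cls(sequence, positions, residues, offset)


def _candidate_positions(evidence: np.ndarray, roi: slice,
                         n_residues: int) -> np.ndarray:
    """Local maxima of the evidence profile plus a uniform fallback grid."""
    lo = roi.start or 0
    hi = roi.stop if roi.stop is not None else evidence.size
    window = evidence[lo:hi]
    peaks = argrelmax(window, order=2)[0] + lo
    grid_step = max(2.0, (hi - lo) / (4.0 * n_residues))
    fallback = np.arange(lo, hi, grid_step)
    cand = np.unique(np.round(np.concatenate([peaks, fallback])))
    return cand[(cand >= lo) & (cand < hi)].astype(float)


def auto_annotate(aligned: TraceSet, sequence: str,
                  modifiers: "list[Modifier | str]",
                  mu: float = 1.0, offset: int = 0,
                  spacing_band: tuple[float, float] = (0.4, 2.5),
                  refine_passes: int = 1,
                  orientation: str = "forward") -> BandAnnotation:
    """Assign every residue of ``sequence`` a band position.

    ``orientation="forward"`` (default) means higher residue index
    elutes later; ``"reverse"`` flips the residue-to-band direction for
    primer placements that run the other way.

    A composite evidence profile (the sum of max-normalized lane
    intensities) proposes candidate band locations; a dynamic program
    then chooses strictly increasing positions p_1 < ... < p_L maximizing
    the per-lane mask-weighted intensities at the chosen positions minus
    a quadratic penalty ``mu * ((spacing - d_hat)/d_hat)**2`` for uneven
    spacing, where ``d_hat`` is the expected local spacing (initialized
    to ROI length / L and refined from the first pass's median spacing).

    Intensities are max-normalized per lane, so the result is invariant
    under rescaling lane intensities by positive constants.
    """
    seq = _clean_sequence(sequence)
    if orientation not in ("forward", "reverse"):
        raise AnnotationError("orientation must be 'forward' or 'reverse'")
    dp_seq = seq if orientation == "forward" else seq[::-1]
    L = len(seq)
    if len(modifiers) != aligned.n_lanes:
        raise AnnotationError(
            f"{len(modifiers)} modifiers given for {aligned.n_lanes} lanes")
    modifiers = [Modifier.parse(m) for m in modifiers]
    roi = aligned.roi.slice() if aligned.roi is not None else slice(
        0, aligned.n_samples)
    lo = roi.start or 0
    hi = roi.stop if roi.stop is not None else aligned.n_samples

    masks = np.stack([reactivity_mask(dp_seq, m) for m in modifiers], axis=1)
    lane_profiles = []
    for j in range(aligned.n_lanes):
        prof = aligned.signal[:, j].astype(float)
        peak = np.max(np.abs(prof[roi]))
        lane_profiles.append(prof / peak if peak > 0 else prof)
    lanes_mat = np.stack(lane_profiles, axis=1)  # n_samples x n_lanes
    lanes_mat = uniform_filter1d(lanes_mat, size=5, axis=0, mode="nearest")

    # lanes weigh into the composite by their mean prior, so a lane whose
    # mask is identically zero cannot influence the annotation
    lane_weight = masks.mean(axis=0)
    evidence = lanes_mat @ lane_weight
    cand = _candidate_positions(evidence, roi, L)
    if cand.size < L:
        raise AnnotationError(
            f"only {cand.size} candidate band locations inside the ROI for "
            f"{L} residues; widen the ROI or shorten the sequence range")
    cand_idx = cand.astype(int)
    # data term per (candidate, residue): sum_lanes mask * intensity
    data = lanes_mat[cand_idx] @ masks.T  # n_cand x L

    d_hat = (hi - lo) / float(L)
    positions = None
    for _ in range(refine_passes + 1):
        positions = _annotation_dp(cand, data, d_hat, mu, spacing_band)
        d_hat = float(np.median(np.diff(positions)))
    positions = _polish_positions(evidence, positions,
                                  max_shift=0.25 * d_hat)
    residues = (tuple(range(L)) if orientation == "forward"
                else tuple(range(L - 1, -1, -1)))
    return BandAnnotation(seq, positions, residues, offset)


def _polish_positions(evidence: np.ndarray, positions: np.ndarray,
                      max_shift: float = 4.0) -> np.ndarray:
    """Sub-sample refinement of DP positions.

    Each position hill-climbs to the nearest local maximum of the
    evidence profile (within ``max_shift``) and lands on the vertex of
    the parabola through that maximum's three samples; residues with no
    nearby maximum stay put, and strict monotonicity is preserved."""
    out = positions.astype(float).copy()
    n = evidence.size
    budget = max(1, int(np.floor(max_shift)))
    for i, p in enumerate(positions):
        c = int(round(p))
        for _ in range(budget):
            if c < 1 or c > n - 2:
                break
            if evidence[c + 1] > evidence[c] and evidence[c + 1] >= evidence[c - 1]:
                c += 1
            elif evidence[c - 1] > evidence[c]:
                c -= 1
            else:
                break
        if c < 1 or c > n - 2 or abs(c - p) > max_shift:
            continue
        y0, y1, y2 = evidence[c - 1], evidence[c], evidence[c + 1]
        denom = y0 - 2 * y1 + y2
        if denom >= 0:
            continue  # not a local maximum
        newp = c + 0.5 * (y0 - y2) / denom
        if abs(newp - p) <= max_shift:
            out[i] = newp
    # revert any polish that broke strict ordering
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = positions[i]
            if out[i] <= out[i - 1]:
                out[i] = out[i - 1] + 1e-6
    return out


def _annotation_dp(cand: np.ndarray, data: np.ndarray, d_hat: float,
                   mu: float, spacing_band: tuple[float, float]
                   ) -> np.ndarray:
    """DP over candidate positions with a quadratic spacing penalty."""
    n_cand, L = data.shape
    lo_sp = spacing_band[0] * d_hat
    hi_sp = spacing_band[1] * d_hat
    NEG = -1e18
    f = np.full((L, n_cand), NEG)
    back = np.zeros((L, n_cand), dtype=int)
    f[0] = data[:, 0]
    for i in range(1, L):
        prev = f[i - 1]
        for c in range(n_cand):
            p = cand[c]
            j_lo = int(np.searchsorted(cand, p - hi_sp, side="left"))
            j_hi = int(np.searchsorted(cand, p - lo_sp, side="right"))
            if j_hi <= j_lo:
                continue
            sp = p - cand[j_lo:j_hi]
            pen = mu * ((sp - d_hat) / d_hat) ** 2
            vals = prev[j_lo:j_hi] - pen
            k = int(np.argmax(vals))
            if vals[k] <= NEG / 2:
                continue
            f[i, c] = vals[k] + data[c, i]
            back[i, c] = j_lo + k
    end = int(np.argmax(f[L - 1]))
    if f[L - 1, end] <= NEG / 2:
        raise AnnotationError(
            "no strictly increasing assignment fits the spacing band; "
            "widen the ROI or relax the spacing constraints")
    path = np.zeros(L, dtype=int)
    path[-1] = end
    for i in range(L - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return cand[path]


def adjust_annotation(annotation: BandAnnotation, residue: int,
                      new_position: float) -> BandAnnotation:
    """Move one residue's band position; neighbors stay put.

    The move is rejected if it would break strict monotonicity against
    either neighbor.
    """
    if residue not in annotation.annotated_residues:
        raise AnnotationError(f"residue {residue} is not annotated")
    idx = annotation.annotated_residues.index(residue)
    pos = annotation.positions.copy()
    if idx > 0 and new_position <= pos[idx - 1]:
        raise AnnotationError(
            f"position {new_position} collides with residue "
            f"{annotation.annotated_residues[idx - 1]} at {pos[idx - 1]}")
    if idx < len(pos) - 1 and new_position >= pos[idx + 1]:
        raise AnnotationError(
            f"position {new_position} collides with residue "
            f"{annotation.annotated_residues[idx + 1]} at {pos[idx + 1]}")
    pos[idx] = new_position
    return replace(annotation, positions=pos)
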
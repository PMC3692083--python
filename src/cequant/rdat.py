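"""The RDAT chemical-mapping text format.

RDAT is a line-oriented, tab-delimited format for per-residue chemical
probing data: a sequence, an optional dot-bracket structure, a residue
numbering offset, and one REACTIVITY row per experimental condition with
key:value annotations.  Output is byte-deterministic (UTF-8, Unix line
endings, 6 significant digits) so repeated exports of the same result
are identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import BandAnnotation
from .peakfit import QuantResult

DEFAULT_VERSION = "0.34"


class RdatFormatError(ValueError):
    pass


@dataclass
class RdatRecord:
    version: str = DEFAULT_VERSION
    name: str = ""
    sequence: str = ""
    structure: str = ""
    offset: int = 0
    seqpos: list[int] = field(default_factory=list)
    global_annotations: list[str] = field(default_factory=list)
    data_annotations: list[list[str]] = field(default_factory=list)
    rows: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))

    def validate(self) -> None:
        if not self.sequence:
            raise RdatFormatError("record has no sequence")
        if self.structure and len(self.structure) != len(self.sequence):
            raise RdatFormatError(
                "structure length does not match sequence length")
        if self.rows.size and self.rows.shape[1] != len(self.seqpos):
            raise RdatFormatError(
                f"row width {self.rows.shape[1]} != len(seqpos) "
                f"{len(self.seqpos)}")
        if len(self.data_annotations) != self.rows.shape[0] and self.rows.size:
            raise RdatFormatError(
                "every data row needs an annotation list (possibly empty)")

    def __eq__(self, other) -> bool:
        if not isinstance(other, RdatRecord):
            return NotImplemented
        return (self.version == other.version and self.name == other.name
                and self.sequence == other.sequence
                and self.structure == other.structure
                and self.offset == other.offset
                and self.seqpos == other.seqpos
                and self.global_annotations == other.global_annotations
                and self.data_annotations == other.data_annotations
                and self.rows.shape == other.rows.shape
                and np.array_equal(self.rows, other.rows))


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_rdat(record: RdatRecord, path) -> None:
    """Serialize a record; validation runs before any bytes hit disk."""
    record.validate()
    lines = [f"RDAT_VERSION\t{record.version}",
             f"NAME\t{record.name}",
             f"SEQUENCE\t{record.sequence}"]
    if record.structure:
        lines.append(f"STRUCTURE\t{record.structure}")
    lines.append(f"OFFSET\t{record.offset}")
    lines.append("SEQPOS\t" + "\t".join(str(s) for s in record.seqpos))
    for ann in record.global_annotations:
        lines.append(f"ANNOTATION\t{ann}")
    for i, anns in enumerate(record.data_annotations, start=1):
        lines.append(f"ANNOTATION_DATA:{i}\t" + "\t".join(anns))
    for i in range(record.rows.shape[0]):
        vals = "\t".join(_fmt(v) for v in record.rows[i])
        lines.append(f"REACTIVITY:{i + 1}\t{vals}")
    Path(path).write_bytes(("\n".join(lines) + "\n").encode("utf-8"))


def read_rdat(path) -> RdatRecord:
    """Parse an RDAT file; unknown record types are preserved verbatim in
    ``global_annotations`` with a ``raw:`` prefix."""
    text = Path(path).read_bytes().decode("utf-8")
    rec = RdatRecord()
    data_anns: dict[int, list[str]] = {}
    rows: dict[int, list[float]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        key, _, rest = line.partition("\t")
        fields = rest.split("\t") if rest else []
        if key == "RDAT_VERSION":
            rec.version = rest
        elif key == "NAME":
            rec.name = rest
        elif key == "SEQUENCE":
            rec.sequence = rest
        elif key == "STRUCTURE":
            rec.structure = rest
        elif key == "OFFSET":
            rec.offset = int(rest)
        elif key == "SEQPOS":
            rec.seqpos = [int(v) for v in fields]
        elif key == "ANNOTATION":
            rec.global_annotations.append(rest)
        elif key.startswith("ANNOTATION_DATA:"):
            data_anns[int(key.split(":", 1)[1])] = (
                fields if rest else [])
        elif key.startswith("REACTIVITY:"):
            try:
                rows[int(key.split(":", 1)[1])] = [float(v) for v in fields]
            except ValueError as exc:
                raise RdatFormatError(
                    f"line {lineno}: bad reactivity value ({exc})") from exc
        else:
            rec.global_annotations.append(f"raw:{line}")
    if not rec.sequence:
        raise RdatFormatError("missing SEQUENCE record")
    if not rows:
        raise RdatFormatError("missing REACTIVITY records")
    n_rows = max(rows)
    width = len(rec.seqpos)
    matrix = np.zeros((n_rows, width))
    for i in range(1, n_rows + 1):
        if i not in rows:
            raise RdatFormatError(f"missing REACTIVITY:{i} row")
        if len(rows[i]) != width:
            raise RdatFormatError(
                f"REACTIVITY:{i} has {len(rows[i])} values, expected {width}")
        matrix[i - 1] = rows[i]
    rec.rows = matrix
    rec.data_annotations = [data_anns.get(i, []) for i in range(1, n_rows + 1)]
    return rec


def build_rdat(quant: QuantResult, annotation: BandAnnotation,
               name: str = "", structure: str = "",
               global_annotations: list[str] | None = None,
               version: str = DEFAULT_VERSION) -> RdatRecord:
    """Assemble an RDAT record: one REACTIVITY row per capillary, one
    column per annotated residue, with each lane's modifier recorded in
    its ANNOTATION_DATA line."""
    if quant.n_lanes == 0 or quant.n_bands == 0:
        raise RdatFormatError("quantification result is empty")
    if quant.n_bands != len(annotation.annotated_residues):
        raise RdatFormatError(
            f"{quant.n_bands} quantified bands vs "
            f"{len(annotation.annotated_residues)} annotated residues")
    seqpos = [i + 1 + annotation.offset for i in annotation.annotated_residues]
    data_annotations = []
    for j in range(quant.n_lanes):
        anns = []
        if quant.modifiers:
            anns.append(f"modifier:{quant.modifiers[j].value}")
        if quant.lane_ids:
            anns.append(f"capillary:{quant.lane_ids[j]}")
        data_annotations.append(anns)
    rec = RdatRecord(
        version=version, name=name, sequence=annotation.sequence,
        structure=structure, offset=annotation.offset, seqpos=seqpos,
        global_annotations=list(global_annotations or []),
        data_annotations=data_annotations,
        rows=np.array([[float(_fmt(v)) for v in quant.areas[:, j]]
                       for j in range(quant.n_lanes)]),
    )
    rec.validate()
    return rec
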
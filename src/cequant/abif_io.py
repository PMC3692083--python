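"""Reading and writing ABIF sequencer trace files (.ab1/.fsa).

The ABIF container is a big-endian binary format: a 4-byte ``ABIF`` magic,
a 2-byte version, a directory entry pointing at the tag directory, and one
28-byte directory entry per tag.  Fluorescence time series live in
``DATA``-numbered tags (DATA1..4 raw, DATA9..12 analyzed on most ABI
instruments).  This module decodes every DATA tag into a column of a
channel matrix and keeps string-valued tags verbatim as metadata; no
rescaling happens at read time.
"""

from __future__ import annotations

import io
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath

import numpy as np

ABIF_MAGIC = b"ABIF"

# element type codes from the public ABIF specification
_TYPE_FORMATS = {
    1: "B",   # unsigned byte
    2: "b",   # char (also used for raw byte strings)
    3: "H",   # unsigned short
    4: "h",   # short
    5: "i",   # long
    7: "f",   # float
    8: "d",   # double
    10: None,  # date
    11: None,  # time
    18: None,  # pString
    19: None,  # cString
}

_TRACE_EXTENSIONS = (".ab1", ".fsa")


class AbifFormatError(ValueError):
    """Raised when a file is not a structurally valid ABIF container."""


@dataclass
class RawCapillary:
    """One capillary's multi-channel fluorescence time series.

    ``channels`` is an ``n_samples x n_channels`` array holding every DATA
    tag of the source file in tag-number order; shorter series are
    right-padded with zeros so the matrix is rectangular.
    """

    capillary_id: str
    batch_id: str
    channels: np.ndarray
    sample_name: str = ""
    source_path: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 2 or self.channels.shape[0] < 1:
            raise ValueError("channels must be a non-empty 2-D matrix")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]


@dataclass
class BatchSet:
    """Ordered batches of capillaries, one list of lanes per batch."""

    batches: list[tuple[str, list[RawCapillary]]]

    def __post_init__(self) -> None:
        ids = [b for b, _ in self.batches]
        if len(set(ids)) != len(ids):
            raise ValueError("batch ids must be unique")
        for bid, lanes in self.batches:
            if not lanes:
                raise ValueError(f"batch {bid!r} is empty")

    @property
    def n_lanes(self) -> int:
        return sum(len(lanes) for _, lanes in self.batches)

    def all_lanes(self) -> list[RawCapillary]:
        return [cap for _, lanes in self.batches for cap in lanes]


def _read_entry(buf: bytes, offset: int, path: str):
    if offset + 28 > len(buf):
        raise AbifFormatError(
            f"{path}: truncated ABIF directory at byte offset {offset}"
        )
    name, number, etype, esize, nelem, dsize, doff, _ = struct.unpack(
        ">4sihhiiii", buf[offset:offset + 28]
    )
    return name.decode("ascii", "replace"), number, etype, esize, nelem, dsize, doff


def _decode_payload(buf: bytes, etype: int, nelem: int, dsize: int, doff: int,
                    entry_offset: int, path: str):
    if dsize <= 4:
        # short payloads are stored inline in the offset field itself
        payload = buf[entry_offset + 20:entry_offset + 24][:dsize]
    else:
        if doff + dsize > len(buf):
            raise AbifFormatError(
                f"{path}: tag data out of bounds at byte offset {doff}"
            )
        payload = buf[doff:doff + dsize]
    if etype == 18:  # pString: leading length byte
        return payload[1:1 + payload[0]].decode("latin-1")
    if etype == 19:  # cString: NUL terminated
        return payload.split(b"\x00", 1)[0].decode("latin-1")
    if etype == 2:
        return payload.decode("latin-1")
    fmt = _TYPE_FORMATS.get(etype)
    if fmt is None:
        return payload  # opaque: keep raw bytes
    values = struct.unpack(f">{nelem}{fmt}", payload[:struct.calcsize(fmt) * nelem])
    return values


def read_abif_bytes(buf: bytes, *, path: str = "<bytes>",
                    capillary_id: str = "", batch_id: str = "") -> RawCapillary:
    """Decode an in-memory ABIF image into a :class:`RawCapillary`."""
    if buf[:4] != ABIF_MAGIC:
        raise AbifFormatError(f"{path}: missing ABIF magic signature")
    if len(buf) < 128:
        raise AbifFormatError(f"{path}: truncated ABIF header")
    _, tdir_num, tdir_type, tdir_size, n_entries, tdir_dsize, tdir_off, _ = (
        struct.unpack(">4sihhiiii", buf[6:34])
    )
    data_series: dict[int, np.ndarray] = {}
    metadata: dict[str, str] = {}
    sample_name = ""
    for i in range(n_entries):
        off = tdir_off + 28 * i
        name, number, etype, esize, nelem, dsize, doff = _read_entry(buf, off, path)
        value = _decode_payload(buf, etype, nelem, dsize, doff, off, path)
        if name == "DATA" and etype in (4, 5):
            data_series[number] = np.asarray(value, dtype=np.int64)
        elif isinstance(value, str):
            metadata[f"{name}{number}"] = value
            if name == "SMPL":
                sample_name = value
    if not data_series:
        raise AbifFormatError(f"{path}: no DATA tags found")
    order = sorted(data_series)
    n = max(len(data_series[k]) for k in order)
    channels = np.zeros((n, len(order)), dtype=np.int64)
    for j, k in enumerate(order):
        col = data_series[k]
        channels[:len(col), j] = col
    return RawCapillary(
        capillary_id=capillary_id or Path(path).stem,
        batch_id=batch_id,
        channels=channels,
        sample_name=sample_name,
        source_path=path,
        metadata=metadata,
    )


def read_abif(path) -> RawCapillary:
    """Read one .ab1/.fsa file into a :class:`RawCapillary`."""
    p = Path(path)
    return read_abif_bytes(p.read_bytes(), path=str(p))


def abif_write(capillary: RawCapillary, path) -> None:
    """Write a minimal valid ABIF file that :func:`read_abif` inverts exactly.

    Channels are emitted as DATA1..DATAn tags, as 16-bit shorts when the
    values fit and 32-bit longs otherwise; the sample name goes into a
    SMPL1 pString tag.
    """
    channels = np.asarray(capillary.channels)
    if channels.size == 0:
        raise ValueError("cannot write a capillary with an empty channel matrix")
    payloads: list[bytes] = []
    entries: list[tuple[bytes, int, int, int, int, bytes]] = []
    for j in range(channels.shape[1]):
        col = np.asarray(channels[:, j], dtype=np.int64)
        if col.min() >= -(2 ** 15) and col.max() < 2 ** 15:
            etype, esize, fmt = 4, 2, "h"
        else:
            etype, esize, fmt = 5, 4, "i"
        data = struct.pack(f">{len(col)}{fmt}", *col.tolist())
        entries.append((b"DATA", j + 1, etype, esize, len(col), data))
    name = capillary.sample_name.encode("latin-1")
    entries.append((b"SMPL", 1, 18, 1, len(name) + 1,
                    bytes([len(name)]) + name))

    header_len = 128
    blobs = []
    offset = header_len
    dir_entries = b""
    for tag, number, etype, esize, nelem, data in entries:
        dsize = len(data)
        if dsize <= 4:
            doff_field = (data + b"\x00" * 4)[:4]
            entry = struct.pack(">4sihhii", tag, number, etype, esize, nelem,
                                dsize) + doff_field + struct.pack(">i", 0)
        else:
            entry = struct.pack(">4sihhiiii", tag, number, etype, esize,
                                nelem, dsize, offset, 0)
            blobs.append(data)
            offset += dsize
        dir_entries += entry
    tdir_offset = offset
    header = ABIF_MAGIC + struct.pack(">h", 101)
    header += struct.pack(">4sihhiiii", b"tdir", 1, 1023, 28, len(entries),
                          28 * len(entries), tdir_offset, 0)
    header += b"\x00" * (header_len - len(header))
    Path(path).write_bytes(header + b"".join(blobs) + dir_entries)


def _group_trace_names(names: list[str]):
    """Group relative paths into (batch_id, [names]) per first-level folder."""
    groups: dict[str, list[str]] = {}
    flat: list[str] = []
    for n in names:
        parts = PurePosixPath(n).parts
        if len(parts) == 1:
            flat.append(n)
        else:
            groups.setdefault(parts[0], []).append(n)
    if groups:
        return [(b, sorted(groups[b])) for b in sorted(groups)]
    return [("batch0", sorted(flat))] if flat else []


def load_batches(root) -> BatchSet:
    """Load a batch-structured CE experiment from a directory or zip archive.

    One subfolder per batch; a flat layout becomes a single batch
    ``batch0``.  Lanes are ordered lexicographically by filename so "the
    first capillary in each batch" is deterministic.  A file that fails to
    parse aborts the load with an error naming it — no silent skipping.
    """
    root = Path(root)
    if root.is_file() and root.suffix.lower() == ".zip":
        with zipfile.ZipFile(root) as zf:
            names = [n for n in zf.namelist()
                     if not n.endswith("/")
                     and PurePosixPath(n).suffix.lower() in _TRACE_EXTENSIONS
                     and not PurePosixPath(n).name.startswith(".")]
            grouped = _group_trace_names(names)
            if not grouped:
                raise FileNotFoundError(
                    f"no .ab1/.fsa members found in zip archive {root}")
            batches = []
            for batch_id, members in grouped:
                lanes = []
                for m in members:
                    try:
                        cap = read_abif_bytes(
                            zf.read(m), path=f"{root}!{m}",
                            capillary_id=PurePosixPath(m).stem,
                            batch_id=batch_id)
                    except AbifFormatError as exc:
                        raise AbifFormatError(
                            f"zip member {m!r}: {exc}") from exc
                    lanes.append(cap)
                batches.append((batch_id, lanes))
            return BatchSet(batches)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is neither a directory nor a zip archive")
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    grouped: list[tuple[str, list[Path]]] = []
    for d in subdirs:
        files = sorted(f for f in d.iterdir()
                       if f.suffix.lower() in _TRACE_EXTENSIONS)
        if files:
            grouped.append((d.name, files))
    if not grouped:
        flat = sorted(f for f in root.iterdir()
                      if f.suffix.lower() in _TRACE_EXTENSIONS)
        if flat:
            grouped = [("batch0", flat)]
    if not grouped:
        raise FileNotFoundError(
            f"no .ab1/.fsa files found under {root} "
            f"(scanned {len(subdirs)} subfolders and the top level)")
    batches = []
    for batch_id, files in grouped:
        lanes = []
        for f in files:
            cap = read_abif(f)
            cap.batch_id = batch_id
            lanes.append(cap)
        batches.append((batch_id, lanes))
    return BatchSet(batches)
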
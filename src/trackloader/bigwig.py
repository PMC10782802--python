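"""Reader and writer for the BigWig binary container.

BigWig stores per-base numeric genome tracks as runs of
``(start, end, value)`` packed into DEFLATE-compressed data sections,
indexed by a chromosome B+ tree (name -> id, size) and an R-tree over
genomic ranges (range -> file offset), so that a range query touches only
the blocks that overlap it.

This module implements the subset needed to serve full-resolution
machine-learning training data:

* :func:`open_track` parses the header, chromosome table and records the
  R-tree root; data sections are read lazily, only when a query needs them.
* :func:`find_blocks` resolves a genomic interval to the leaf blocks that
  overlap it, via R-tree descent.
* :func:`decode_section` turns one decompressed section into explicit
  ``(start, end, value)`` records for all three section encodings
  (bedGraph = 1, variable-step = 2, fixed-step = 3).
* :func:`write_track` emits a spec-compliant zoom-free BigWig file, which
  doubles as the fixture generator for offline testing.

Zoom (downsampled summary) levels are skipped on read and never written:
training-profile regression consumes full-resolution values only.
BigBed files are rejected explicitly.
"""

from __future__ import annotations

import math
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval

BIGWIG_MAGIC = 0x888FFC26
BIGBED_MAGIC = 0x8789F2EB
CHROM_TREE_MAGIC = 0x78CA8C91
RTREE_MAGIC = 0x2468ACE0

#: section_type codes inside data sections
SECTION_BEDGRAPH = 1
SECTION_VARSTEP = 2
SECTION_FIXEDSTEP = 3

SECTION_TYPE_NAMES = {
    "bedgraph": SECTION_BEDGRAPH,
    "varstep": SECTION_VARSTEP,
    "fixedstep": SECTION_FIXEDSTEP,
}

_HEADER_SIZE = 64
_SUMMARY_SIZE = 40
_SECTION_HEADER_SIZE = 24


class BigWigError(Exception):
    """Raised for malformed or unsupported BigWig input."""


@dataclass(frozen=True)
class TotalSummary:
    bases_covered: int
    min_value: float
    max_value: float
    sum_values: float
    sum_squares: float


@dataclass(frozen=True)
class TrackHeader:
    magic: int
    version: int
    zoom_level_count: int
    chrom_tree_offset: int
    full_data_offset: int
    full_index_offset: int
    uncompress_buf_size: int
    total_summary: Optional[TotalSummary]


@dataclass(frozen=True)
class BlockLocation:
    """One R-tree leaf entry: a genomic range mapped to a file region."""

    chrom_id: int
    start: int
    end: int
    file_offset: int
    compressed_size: int


@dataclass(frozen=True)
class SectionRecords:
    """Decoded records of one data section."""

    section_type: int
    chrom_id: int
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    values: np.ndarray  # float32

    @property
    def records(self) -> List[Tuple[int, int, float]]:
        return list(
            zip(self.starts.tolist(), self.ends.tolist(), self.values.tolist())
        )


class ChromTable:
    """Exact-match chromosome name -> (id, size) lookup."""

    def __init__(self, entries: Mapping[str, Tuple[int, int]]):
        self._by_name: Dict[str, Tuple[int, int]] = dict(entries)
        ids = [cid for cid, _ in self._by_name.values()]
        if len(set(ids)) != len(ids):
            raise BigWigError("duplicate chromosome ids in chromosome table")
        for name, (cid, size) in self._by_name.items():
            if size <= 0:
                raise BigWigError(f"chromosome {name!r} has non-positive size {size}")
        self._by_id: Dict[int, str] = {cid: name for name, (cid, _) in self._by_name.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def names(self) -> List[str]:
        return list(self._by_name)

    def chrom_id(self, name: str) -> int:
        return self._by_name[name][0]

    def chrom_size(self, name: str) -> int:
        return self._by_name[name][1]

    def name_of(self, chrom_id: int) -> str:
        return self._by_id[chrom_id]

    def items(self):
        return self._by_name.items()


class _ByteSource:
    """Positioned reads over an open file, with a read log for tests.

    The log lets tests assert that queries touch only the byte ranges the
    R-tree said they need (header/index reads are logged too, tagged by
    whoever asks).
    """

    def __init__(self, fh: BinaryIO, size: int):
        self._fh = fh
        self.size = size
        self.read_log: List[Tuple[int, int]] = []

    def pread(self, offset: int, size: int) -> bytes:
        if offset + size > self.size:
            raise BigWigError(
                f"read of {size} bytes at offset {offset} exceeds file size {self.size}"
            )
        self.read_log.append((offset, size))
        self._fh.seek(offset)
        data = self._fh.read(size)
        if len(data) != size:
            raise BigWigError("short read: corrupt file")
        return data

    def close(self) -> None:
        self._fh.close()


@dataclass
class TrackFileHandle:
    """An opened BigWig file: parsed header and indexes, lazy data access."""

    path: str
    header: TrackHeader
    byteorder: str  # struct prefix "<" or ">"
    chroms: ChromTable
    source: _ByteSource
    _rtree_root_offset: int = 0
    _node_cache: Dict[int, tuple] = field(default_factory=dict)

    def close(self) -> None:
        self.source.close()

    def __enter__(self) -> "TrackFileHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def compressed(self) -> bool:
        return self.header.uncompress_buf_size != 0


def open_track(path) -> TrackFileHandle:
    """Open a BigWig file: parse header, chromosome table, R-tree root.

    Byte order is auto-detected from the magic number; all subsequent
    reads honour the detected order.  Data sections are not touched.
    """
    path = str(path)
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(path)
    fh = open(path, "rb")
    source = _ByteSource(fh, p.stat().st_size)
    try:
        return _parse_track(path, source)
    except Exception:
        source.close()
        raise


def _parse_track(path: str, source: _ByteSource) -> TrackFileHandle:
    if source.size < _HEADER_SIZE:
        raise BigWigError(f"corrupt file (truncated header): {path}")
    raw = source.pread(0, _HEADER_SIZE)
    byteorder = None
    for bo in ("<", ">"):
        magic = struct.unpack_from(bo + "I", raw, 0)[0]
        if magic == BIGWIG_MAGIC:
            byteorder = bo
            break
        if magic == BIGBED_MAGIC:
            raise BigWigError(f"BigBed not supported: {path}")
    if byteorder is None:
        raise BigWigError(f"not a BigWig file: {path}")
    (
        magic,
        version,
        zoom_levels,
        chrom_tree_offset,
        full_data_offset,
        full_index_offset,
        _field_count,
        _defined_field_count,
        _as_offset,
        total_summary_offset,
        uncompress_buf_size,
        _extension_offset,
    ) = struct.unpack_from(byteorder + "IHHQQQHHQQIQ", raw, 0)

    if not (full_data_offset < full_index_offset <= source.size):
        raise BigWigError(f"corrupt file (inconsistent offsets): {path}")

    summary = None
    if total_summary_offset:
        sraw = source.pread(total_summary_offset, _SUMMARY_SIZE)
        bases, mn, mx, s, ss = struct.unpack(byteorder + "Qdddd", sraw)
        summary = TotalSummary(bases, mn, mx, s, ss)

    header = TrackHeader(
        magic=magic,
        version=version,
        zoom_level_count=zoom_levels,
        chrom_tree_offset=chrom_tree_offset,
        full_data_offset=full_data_offset,
        full_index_offset=full_index_offset,
        uncompress_buf_size=uncompress_buf_size,
        total_summary=summary,
    )
    chroms = _read_chrom_tree(source, chrom_tree_offset, byteorder, path)
    handle = TrackFileHandle(
        path=path,
        header=header,
        byteorder=byteorder,
        chroms=chroms,
        source=source,
    )
    handle._rtree_root_offset = _read_rtree_header(source, full_index_offset, byteorder, path)
    return handle


def _read_chrom_tree(source: _ByteSource, offset: int, bo: str, path: str) -> ChromTable:
    raw = source.pread(offset, 32)
    magic, _block_size, key_size, val_size, item_count, _reserved = struct.unpack(
        bo + "IIIIQQ", raw
    )
    if magic != CHROM_TREE_MAGIC:
        raise BigWigError(f"corrupt file (bad chromosome tree magic): {path}")
    if val_size != 8:
        raise BigWigError(f"corrupt file (chromosome tree valSize {val_size} != 8): {path}")
    entries: Dict[str, Tuple[int, int]] = {}

    def walk(node_offset: int) -> None:
        head = source.pread(node_offset, 4)
        is_leaf, _res, count = struct.unpack(bo + "BBH", head)
        if is_leaf:
            body = source.pread(node_offset + 4, count * (key_size + 8))
            for i in range(count):
                base = i * (key_size + 8)
                key = body[base : base + key_size].split(b"\x00", 1)[0].decode("ascii")
                chrom_id, chrom_size = struct.unpack_from(bo + "II", body, base + key_size)
                entries[key] = (chrom_id, chrom_size)
        else:
            body = source.pread(node_offset + 4, count * (key_size + 8))
            for i in range(count):
                (child,) = struct.unpack_from(bo + "Q", body, i * (key_size + 8) + key_size)
                walk(child)

    walk(offset + 32)
    if len(entries) != item_count:
        raise BigWigError(f"corrupt file (chromosome tree count mismatch): {path}")
    return ChromTable(entries)


def _read_rtree_header(source: _ByteSource, offset: int, bo: str, path: str) -> int:
    raw = source.pread(offset, 48)
    magic = struct.unpack_from(bo + "I", raw, 0)[0]
    if magic != RTREE_MAGIC:
        raise BigWigError(f"corrupt file (bad R-tree magic): {path}")
    return offset + 48


def _read_rtree_node(handle: TrackFileHandle, offset: int) -> tuple:
    """Read one R-tree node, cached.  Returns (is_leaf, items)."""
    cached = handle._node_cache.get(offset)
    if cached is not None:
        return cached
    bo = handle.byteorder
    head = handle.source.pread(offset, 4)
    is_leaf, _res, count = struct.unpack(bo + "BBH", head)
    if is_leaf:
        body = handle.source.pread(offset + 4, count * 32)
        items = [struct.unpack_from(bo + "IIIIQQ", body, i * 32) for i in range(count)]
    else:
        body = handle.source.pread(offset + 4, count * 24)
        items = [struct.unpack_from(bo + "IIIIQ", body, i * 24) for i in range(count)]
    node = (bool(is_leaf), items)
    handle._node_cache[offset] = node
    return node


def _range_overlaps(
    s_cix: int, s_base: int, e_cix: int, e_base: int, cix: int, start: int, end: int
) -> bool:
    """Overlap test between an R-tree (chrom, base) range and a query."""
    lo = (s_cix, s_base)
    hi = (e_cix, e_base)
    qlo = (cix, start)
    qhi = (cix, end)
    return lo < qhi and qlo < hi


def find_blocks(handle: TrackFileHandle, interval: GenomicInterval) -> List[BlockLocation]:
    """Return every leaf block overlapping ``interval``, in file-offset order."""
    if interval.chrom not in handle.chroms:
        raise BigWigError(
            f"chromosome not found: {interval.chrom!r} in {handle.path}"
        )
    cix = handle.chroms.chrom_id(interval.chrom)
    size = handle.chroms.chrom_size(interval.chrom)
    if interval.end > size:
        raise BigWigError(
            f"interval {interval} exceeds chromosome size {size} in {handle.path}"
        )
    out: List[BlockLocation] = []

    def descend(offset: int) -> None:
        is_leaf, items = _read_rtree_node(handle, offset)
        if is_leaf:
            for scix, sbase, ecix, ebase, doff, dsize in items:
                if _range_overlaps(scix, sbase, ecix, ebase, cix, interval.start, interval.end):
                    out.append(
                        BlockLocation(
                            chrom_id=scix if scix == ecix else cix,
                            start=sbase,
                            end=ebase,
                            file_offset=doff,
                            compressed_size=dsize,
                        )
                    )
        else:
            for scix, sbase, ecix, ebase, child in items:
                if _range_overlaps(scix, sbase, ecix, ebase, cix, interval.start, interval.end):
                    descend(child)

    descend(handle._rtree_root_offset)
    out.sort(key=lambda b: b.file_offset)
    return out


def iter_leaf_blocks(handle: TrackFileHandle) -> Iterator[BlockLocation]:
    """Linear traversal of every R-tree leaf entry (brute-force oracle path)."""

    def walk(offset: int) -> Iterator[BlockLocation]:
        is_leaf, items = _read_rtree_node(handle, offset)
        if is_leaf:
            for scix, sbase, ecix, ebase, doff, dsize in items:
                yield BlockLocation(scix, sbase, ebase, doff, dsize)
        else:
            for *_range, child in items:
                yield from walk(child)

    yield from walk(handle._rtree_root_offset)


def read_block(handle: TrackFileHandle, block: BlockLocation) -> bytes:
    """Read (and if needed DEFLATE-decompress) one data section's bytes."""
    raw = handle.source.pread(block.file_offset, block.compressed_size)
    if not handle.compressed:
        return raw
    try:
        return zlib.decompress(raw)
    except zlib.error as exc:
        raise BigWigError(
            f"corrupt block at offset {block.file_offset} in file {handle.path}: {exc}"
        ) from exc


def decode_section(raw: bytes, byteorder: str = "<") -> SectionRecords:
    """Decode one decompressed data section into explicit records.

    Fixed-step items expand to ``(start + i*step, start + i*step + span, v_i)``,
    variable-step to ``(s_i, s_i + span, v_i)``, bedGraph items carry explicit
    ``(s_i, e_i, v_i)``.
    """
    if len(raw) < _SECTION_HEADER_SIZE:
        raise BigWigError("corrupt section: shorter than section header")
    chrom_id, chrom_start, _chrom_end, item_step, item_span, stype, _res, item_count = (
        struct.unpack_from(byteorder + "IIIIIBBH", raw, 0)
    )
    body = raw[_SECTION_HEADER_SIZE:]
    dt_u32 = np.dtype(byteorder + "u4")
    dt_f32 = np.dtype(byteorder + "f4")
    if stype == SECTION_BEDGRAPH:
        item_size = 12
        if len(body) != item_count * item_size:
            raise BigWigError("corrupt section: bedgraph byte length mismatch")
        arr = np.frombuffer(body, dtype=np.dtype([("s", dt_u32), ("e", dt_u32), ("v", dt_f32)]))
        starts = arr["s"].astype(np.int64)
        ends = arr["e"].astype(np.int64)
        values = arr["v"].astype(np.float32)
    elif stype == SECTION_VARSTEP:
        item_size = 8
        if len(body) != item_count * item_size:
            raise BigWigError("corrupt section: varstep byte length mismatch")
        arr = np.frombuffer(body, dtype=np.dtype([("s", dt_u32), ("v", dt_f32)]))
        starts = arr["s"].astype(np.int64)
        ends = starts + int(item_span)
        values = arr["v"].astype(np.float32)
    elif stype == SECTION_FIXEDSTEP:
        item_size = 4
        if len(body) != item_count * item_size:
            raise BigWigError("corrupt section: fixedstep byte length mismatch")
        values = np.frombuffer(body, dtype=dt_f32).astype(np.float32)
        starts = chrom_start + np.arange(item_count, dtype=np.int64) * int(item_step)
        ends = starts + int(item_span)
    else:
        raise BigWigError(f"unsupported section type {stype}")
    return SectionRecords(
        section_type=stype,
        chrom_id=chrom_id,
        starts=starts,
        ends=ends,
        values=values,
    )


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def _validate_records(chrom: str, size: int, records: Sequence[Tuple[int, int, float]]) -> None:
    prev_end = 0
    prev_start = -1
    for start, end, _value in records:
        if end <= start:
            raise ValueError(f"record ({start}, {end}) on {chrom} has end <= start")
        if start < prev_start or start < prev_end:
            raise ValueError(
                f"records on {chrom} must be sorted and non-overlapping "
                f"(offender starts at {start}, previous end {prev_end})"
            )
        if start < 0 or end > size:
            raise ValueError(
                f"record ({start}, {end}) outside chromosome {chrom} bounds [0, {size})"
            )
        prev_start, prev_end = start, end


def _chunk_sections(
    records: Sequence[Tuple[int, int, float]], section_type: int, items_per_section: int
):
    """Split a chromosome's records into encoding-legal sections.

    A variable-step section needs a single span; a fixed-step section needs a
    single span and arithmetically spaced starts.  Sections are flushed when
    the next record would violate the encoding or the item budget.
    """
    chunk: List[Tuple[int, int, float]] = []
    for rec in records:
        if chunk:
            flush = len(chunk) >= items_per_section
            if not flush and section_type != SECTION_BEDGRAPH:
                span0 = chunk[0][1] - chunk[0][0]
                if rec[1] - rec[0] != span0:
                    flush = True
                elif section_type == SECTION_FIXEDSTEP:
                    step = chunk[1][0] - chunk[0][0] if len(chunk) > 1 else None
                    gap = rec[0] - chunk[-1][0]
                    if step is None:
                        if gap < span0:
                            flush = True  # fixed-step items may not overlap
                    elif gap != step:
                        flush = True
            if flush:
                yield chunk
                chunk = []
        chunk.append(rec)
    if chunk:
        yield chunk


def _encode_section(
    chrom_id: int, chunk: Sequence[Tuple[int, int, float]], section_type: int, bo: str
) -> bytes:
    starts = [r[0] for r in chunk]
    ends = [r[1] for r in chunk]
    values = [r[2] for r in chunk]
    span = ends[0] - starts[0]
    if section_type == SECTION_FIXEDSTEP:
        step = starts[1] - starts[0] if len(chunk) > 1 else span
    else:
        step = 0
    if section_type == SECTION_BEDGRAPH:
        span = 0
    header = struct.pack(
        bo + "IIIIIBBH",
        chrom_id,
        starts[0],
        ends[-1],
        step,
        span,
        section_type,
        0,
        len(chunk),
    )
    if section_type == SECTION_BEDGRAPH:
        body = b"".join(
            struct.pack(bo + "IIf", s, e, v) for s, e, v in zip(starts, ends, values)
        )
    elif section_type == SECTION_VARSTEP:
        body = b"".join(struct.pack(bo + "If", s, v) for s, v in zip(starts, values))
    else:
        body = b"".join(struct.pack(bo + "f", v) for v in values)
    return header + body


def _build_rtree(
    entries: List[Tuple[int, int, int, int, int]], block_size: int, tree_offset: int, bo: str
) -> bytes:
    """Bottom-up packed R-tree over sections sorted by (chrom_id, start).

    ``entries``: (chrom_id, start, end, data_offset, data_size) per section.
    Returns the serialized index (header + nodes) to be placed at
    ``tree_offset`` in the file.
    """
    item_count = len(entries)
    if item_count:
        start_cix, start_base = entries[0][0], entries[0][1]
        end_cix = max(e[0] for e in entries)
        end_base = max(e[2] for e in entries if e[0] == end_cix)
        end_file_offset = max(e[3] + e[4] for e in entries)
    else:
        start_cix = start_base = end_cix = end_base = 0
        end_file_offset = tree_offset

    header = struct.pack(
        bo + "IIQIIIIQII",
        RTREE_MAGIC,
        block_size,
        item_count,
        start_cix,
        start_base,
        end_cix,
        end_base,
        end_file_offset,
        block_size,  # itemsPerSlot (informational)
        0,
    )

    # Build levels bottom-up: leaves hold section entries, parents hold children.
    leaves = [entries[i : i + block_size] for i in range(0, len(entries), block_size)] or [[]]
    levels = [leaves]  # levels[0] = leaf nodes
    while len(levels[-1]) > 1:
        prev = levels[-1]
        levels.append([prev[i : i + block_size] for i in range(0, len(prev), block_size)])

    # Serialize root-first, then each deeper level, computing child offsets.
    ordered = levels[::-1]  # root level first
    node_sizes: List[List[int]] = []
    for depth, level in enumerate(ordered):
        is_leaf = depth == len(ordered) - 1
        per_item = 32 if is_leaf else 24
        node_sizes.append([4 + per_item * len(node) for node in level])

    offsets: List[List[int]] = []
    cursor = tree_offset + 48
    for sizes in node_sizes:
        offsets.append([])
        for s in sizes:
            offsets[-1].append(cursor)
            cursor += s

    # Precompute each node's covering range per level (leaf level first).
    ranges_by_level: List[List[Tuple[int, int, int, int]]] = [[] for _ in ordered]
    leaf_depth = len(ordered) - 1
    for node in ordered[leaf_depth]:
        if node:
            scix = min(e[0] for e in node)
            ecix = max(e[0] for e in node)
            sbase = min(e[1] for e in node if e[0] == scix)
            ebase = max(e[2] for e in node if e[0] == ecix)
        else:
            scix = ecix = sbase = ebase = 0
        ranges_by_level[leaf_depth].append((scix, sbase, ecix, ebase))
    for depth in range(leaf_depth - 1, -1, -1):
        child_ranges = ranges_by_level[depth + 1]
        idx = 0
        for node in ordered[depth]:
            rs = child_ranges[idx : idx + len(node)]
            idx += len(node)
            scix = min(r[0] for r in rs)
            ecix = max(r[2] for r in rs)
            sbase = min(r[1] for r in rs if r[0] == scix)
            ebase = max(r[3] for r in rs if r[2] == ecix)
            ranges_by_level[depth].append((scix, sbase, ecix, ebase))

    out = [header]
    for depth, level in enumerate(ordered):
        is_leaf = depth == leaf_depth
        child_idx = 0
        for node in level:
            out.append(struct.pack(bo + "BBH", 1 if is_leaf else 0, 0, len(node)))
            if is_leaf:
                for cix, s, e, doff, dsize in node:
                    out.append(struct.pack(bo + "IIIIQQ", cix, s, cix, e, doff, dsize))
            else:
                for _child in node:
                    r = ranges_by_level[depth + 1][child_idx]
                    child_offset = offsets[depth + 1][child_idx]
                    child_idx += 1
                    out.append(struct.pack(bo + "IIIIQ", r[0], r[1], r[2], r[3], child_offset))
    return b"".join(out)


def _build_chrom_tree(chrom_sizes: Mapping[str, int], bo: str) -> Tuple[bytes, Dict[str, int]]:
    names = list(chrom_sizes)
    key_size = max(len(n) for n in names)
    ids = {name: i for i, name in enumerate(sorted(names))}
    block_size = max(len(names), 1)
    header = struct.pack(
        bo + "IIIIQQ", CHROM_TREE_MAGIC, block_size, key_size, 8, len(names), 0
    )
    node = [struct.pack(bo + "BBH", 1, 0, len(names))]
    for name in sorted(names):  # B+ tree keys must be sorted
        key = name.encode("ascii").ljust(key_size, b"\x00")
        node.append(key + struct.pack(bo + "II", ids[name], chrom_sizes[name]))
    return header + b"".join(node), ids


def write_track(
    chrom_sizes: Mapping[str, int],
    records_per_chrom: Mapping[str, Sequence[Tuple[int, int, float]]],
    path,
    section_type: str = "bedgraph",
    items_per_section: int = 64,
    compress: bool = True,
    byteorder: str = "<",
) -> str:
    """Write a zoom-free BigWig file containing the given value runs.

    ``records_per_chrom`` maps chromosome name to sorted, non-overlapping
    ``(start, end, value)`` runs within the chromosome bounds.  Sections
    hold at most ``items_per_section`` records each and are split further
    wherever the chosen encoding cannot represent the run structure, so any
    legal record set can be written with any of the three encodings.
    """
    if section_type not in SECTION_TYPE_NAMES:
        raise ValueError(f"unknown section_type {section_type!r}")
    if items_per_section < 1:
        raise ValueError("items_per_section must be positive")
    if byteorder not in ("<", ">"):
        raise ValueError("byteorder must be '<' or '>'")
    stype = SECTION_TYPE_NAMES[section_type]
    bo = byteorder
    path = str(path)

    for chrom in records_per_chrom:
        if chrom not in chrom_sizes:
            raise ValueError(f"records given for unknown chromosome {chrom!r}")
        _validate_records(chrom, chrom_sizes[chrom], records_per_chrom[chrom])

    chrom_tree, ids = _build_chrom_tree(chrom_sizes, bo)

    # Encode sections per chromosome in (chrom_id, start) order.
    sections: List[Tuple[int, int, int, bytes]] = []  # (cid, start, end, payload)
    max_uncompressed = 0
    covered = 0
    vmin, vmax, vsum, vsumsq = math.inf, -math.inf, 0.0, 0.0
    for chrom in sorted(records_per_chrom, key=lambda c: ids[c]):
        records = records_per_chrom[chrom]
        if not records:
            continue
        cid = ids[chrom]
        for s, e, v in records:
            n = e - s
            covered += n
            vmin = min(vmin, v)
            vmax = max(vmax, v)
            vsum += v * n
            vsumsq += v * v * n
        for chunk in _chunk_sections(records, stype, items_per_section):
            payload = _encode_section(cid, chunk, stype, bo)
            max_uncompressed = max(max_uncompressed, len(payload))
            sections.append((cid, chunk[0][0], chunk[-1][1], payload))

    if covered == 0:
        vmin = vmax = 0.0
    summary = TotalSummary(covered, vmin, vmax, vsum, vsumsq)

    summary_offset = _HEADER_SIZE
    chrom_tree_offset = summary_offset + _SUMMARY_SIZE
    full_data_offset = chrom_tree_offset + len(chrom_tree)

    blobs: List[bytes] = []
    entries: List[Tuple[int, int, int, int, int]] = []
    cursor = full_data_offset + 8  # uint64 section count precedes sections
    for cid, start, end, payload in sections:
        blob = zlib.compress(payload) if compress else payload
        entries.append((cid, start, end, cursor, len(blob)))
        blobs.append(blob)
        cursor += len(blob)
    full_index_offset = cursor

    rtree = _build_rtree(entries, block_size=64, tree_offset=full_index_offset, bo=bo)

    header = struct.pack(
        bo + "IHHQQQHHQQIQ",
        BIGWIG_MAGIC,
        4,  # container version
        0,  # zoom_level_count: full-resolution only
        chrom_tree_offset,
        full_data_offset,
        full_index_offset,
        0,
        0,
        0,
        summary_offset,
        max_uncompressed if compress else 0,
        0,
    )
    summary_raw = struct.pack(
        bo + "Qdddd",
        summary.bases_covered,
        summary.min_value,
        summary.max_value,
        summary.sum_values,
        summary.sum_squares,
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(summary_raw)
        fh.write(chrom_tree)
        fh.write(struct.pack(bo + "Q", len(sections)))
        for blob in blobs:
            fh.write(blob)
        fh.write(rtree)
    return path
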
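"""Random access into a reference genome FASTA, and one-hot sequence encoding.

Window access follows the faidx convention: a 5-column sidecar index
(name, length, byte offset of first base, bases per line, bytes per line)
turns a window request into byte-offset arithmetic, so only the requested
bytes are read.  The accessor builds and writes the ``.fai`` index itself
when the sidecar is absent; an existing sidecar is trusted as-is.

One-hot encoding uses channel order A, C, G, T.  Case is folded; any
other character — N, IUPAC ambiguity codes, gaps — encodes as the
all-zero channel vector, so the per-position channel sum doubles as a
known-base indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval

#: channel order of the one-hot encoding
BASE_ORDER = "ACGT"

_ONE_HOT_TABLE = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate(BASE_ORDER):
    _ONE_HOT_TABLE[ord(_b)][_i] = 1.0
    _ONE_HOT_TABLE[ord(_b.lower())][_i] = 1.0

_KNOWN_BASE = np.zeros(256, dtype=bool)
for _b in "ACGTacgt":
    _KNOWN_BASE[ord(_b)] = True


@dataclass(frozen=True)
class FaidxEntry:
    length: int
    offset: int  # byte offset of the first base
    linebases: int  # bases per line
    linewidth: int  # bytes per line incl. newline(s)


@dataclass
class EncodedSequenceBatch:
    """One-hot tensor with axes (interval_index, position, channel A/C/G/T)."""

    one_hot: np.ndarray
    raw: Optional[List[str]] = None


class GenomeAccessor:
    """Random access to windows of an indexed FASTA reference genome."""

    def __init__(self, fasta_path):
        self.fasta_path = str(fasta_path)
        fai = Path(self.fasta_path + ".fai")
        if fai.exists():
            self.index = _read_fai(fai)
        else:
            self.index = build_faidx(self.fasta_path)
            _write_fai(fai, self.index)
        self._fh = open(self.fasta_path, "rb")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "GenomeAccessor":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def contig_length(self, name: str) -> int:
        if name not in self.index:
            raise KeyError(f"contig {name!r} not in {self.fasta_path}")
        return self.index[name].length

    def fetch(self, interval: GenomicInterval) -> str:
        return fetch_sequence(self, interval)


def build_faidx(fasta_path) -> Dict[str, FaidxEntry]:
    """Scan a FASTA file and build its faidx-convention index.

    Requires uniform line length within each contig (all lines except the
    last of a contig equally long), the standard precondition for
    offset-arithmetic access.  Handles Unix and Windows newlines.
    """
    index: Dict[str, FaidxEntry] = {}
    name = None
    length = 0
    offset = 0
    linebases = linewidth = 0
    last_line_len = None  # bases on the previous sequence line

    def finish():
        if name is not None:
            if name in index:
                raise ValueError(f"duplicate contig {name!r} in {fasta_path}")
            index[name] = FaidxEntry(length, offset, linebases or length, linewidth)

    with open(str(fasta_path), "rb") as fh:
        pos = 0
        for raw in fh:
            line = raw.rstrip(b"\r\n")
            if raw.startswith(b">"):
                finish()
                name = line[1:].split()[0].decode("ascii") if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"unnamed contig in {fasta_path}")
                length = 0
                offset = pos + len(raw)
                linebases = linewidth = 0
                last_line_len = None
            elif line:
                if name is None:
                    raise ValueError(f"sequence before first header in {fasta_path}")
                if last_line_len is not None and last_line_len != linebases:
                    raise ValueError(
                        f"ragged line lengths in contig {name!r} of {fasta_path}"
                    )
                if linebases == 0:
                    linebases = len(line)
                    linewidth = len(raw) if raw.endswith(b"\n") else len(raw)
                last_line_len = len(line)
                length += len(line)
            pos += len(raw)
        finish()
    return index


def _read_fai(path: Path) -> Dict[str, FaidxEntry]:
    index: Dict[str, FaidxEntry] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        name, length, offset, linebases, linewidth = line.split("\t")[:5]
        index[name] = FaidxEntry(int(length), int(offset), int(linebases), int(linewidth))
    return index


def _write_fai(path: Path, index: Dict[str, FaidxEntry]) -> None:
    with open(path, "w") as fh:
        for name, e in index.items():
            fh.write(f"{name}\t{e.length}\t{e.offset}\t{e.linebases}\t{e.linewidth}\n")


def fetch_sequence(accessor: GenomeAccessor, interval: GenomicInterval) -> str:
    """Fetch the exact uppercased subsequence for a 0-based half-open window."""
    if interval.chrom not in accessor.index:
        raise KeyError(f"contig {interval.chrom!r} not in {accessor.fasta_path}")
    entry = accessor.index[interval.chrom]
    if interval.end > entry.length:
        raise ValueError(
            f"interval {interval} out of bounds: contig {interval.chrom!r} "
            f"has length {entry.length}"
        )
    start_off = entry.offset + (interval.start // entry.linebases) * entry.linewidth + (
        interval.start % entry.linebases
    )
    last = interval.end - 1
    end_off = entry.offset + (last // entry.linebases) * entry.linewidth + (
        last % entry.linebases
    ) + 1
    accessor._fh.seek(start_off)
    raw = accessor._fh.read(end_off - start_off)
    seq = raw.replace(b"\n", b"").replace(b"\r", b"").upper().decode("ascii")
    assert len(seq) == len(interval)
    return seq


def count_unknown_bases(sequence: str) -> int:
    """Number of characters outside {A,C,G,T} (case-insensitive)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return int((~_KNOWN_BASE[arr]).sum())


def one_hot_encode(sequences: Sequence[str], keep_raw: bool = False) -> EncodedSequenceBatch:
    """One-hot encode equal-length sequences into a (B, L, 4) float32 tensor."""
    if len(sequences) == 0:
        return EncodedSequenceBatch(np.zeros((0, 0, 4), dtype=np.float32), raw=[] if keep_raw else None)
    L = len(sequences[0])
    for i, s in enumerate(sequences):
        if len(s) != L:
            raise ValueError(
                f"sequences must share one length; sequence {i} has length "
                f"{len(s)}, expected {L}"
            )
    flat = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    one_hot = _ONE_HOT_TABLE[flat].reshape(len(sequences), L, 4)
    return EncodedSequenceBatch(one_hot, raw=list(sequences) if keep_raw else None)
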
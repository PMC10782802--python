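"""Regions of interest: threshold-derived or table-loaded sampling regions.

Training windows are drawn from a set of (typically larger) genomic
regions — e.g. a train/validation/test split, or, without any external
peak calls, the stretches of the genome where at least one track shows
signal.  :func:`threshold_regions` derives the latter directly from the
track files: a base belongs to a region iff some file's value at that base
is >= the threshold, after merging stretches separated by at most
``merge_gap`` bases and dropping merged regions shorter than
``min_region_length``.

Thresholding is inclusive (``>=``) so that integer-valued coverage tracks
behave intuitively at the threshold itself.  Bases covered by no record
count as 0.0, hence fall below any positive threshold (and above any
non-positive one, which makes the whole chromosome a region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bigwig import ChromTable, TrackFileHandle, decode_section, find_blocks, read_block
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class RegionSet:
    """Per-chromosome sorted, non-overlapping intervals eligible for sampling."""

    regions: Dict[str, List[Tuple[int, int]]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for chrom, ivs in self.regions.items():
            prev_end = -1
            for start, end in ivs:
                if end <= start:
                    raise ValueError(f"region ({start}, {end}) on {chrom} has end <= start")
                if start <= prev_end:
                    raise ValueError(
                        f"regions on {chrom} must be sorted and separated by >= 1 base"
                    )
                prev_end = end

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.regions:
            for start, end in self.regions[chrom]:
                yield GenomicInterval(chrom, start, end)

    def __len__(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def total_bases(self) -> int:
        return sum(e - s for ivs in self.regions.values() for s, e in ivs)

    def covers(self, chrom: str, base: int) -> bool:
        for s, e in self.regions.get(chrom, []):
            if s <= base < e:
                return True
        return False


def merge_intervals(
    intervals: Sequence[Tuple[int, int]], merge_gap: int = 0
) -> List[Tuple[int, int]]:
    """Merge intervals whose separation is <= merge_gap (touching merges at 0)."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - out[-1][1] <= merge_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def threshold_regions(
    handles: Sequence[TrackFileHandle],
    threshold: float,
    merge_gap: int = 0,
    min_region_length: int = 1,
) -> RegionSet:
    """Regions where at least one track's value meets ``threshold``.

    Streams over decoded records per chromosome — whole-chromosome per-base
    arrays are never materialised.  Chromosomes absent from some of the
    files are skipped with a warning (region derivation needs a consistent
    corpus; a partially-covered chromosome would bias sampling).
    """
    if not handles:
        raise ValueError("threshold_regions needs at least one track file")
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")

    common = set(handles[0].chroms.names())
    union = set(common)
    for h in handles[1:]:
        names = set(h.chroms.names())
        common &= names
        union |= names
    for skipped in sorted(union - common):
        logger.warning(
            "chromosome %r missing from some files; skipped in region derivation",
            skipped,
        )

    regions: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in sorted(common):
        size = min(h.chroms.chrom_size(chrom) for h in handles)
        candidate: List[Tuple[int, int]] = []
        if threshold <= 0.0:
            # the 0.0 fill of uncovered bases already meets the threshold
            candidate.append((0, size))
        else:
            for h in handles:
                cid = h.chroms.chrom_id(chrom)
                for block in find_blocks(h, GenomicInterval(chrom, 0, size)):
                    sec = decode_section(read_block(h, block), h.byteorder)
                    if sec.chrom_id != cid:
                        continue
                    hit = sec.values >= threshold
                    for s, e in zip(sec.starts[hit], sec.ends[hit]):
                        s = int(s)
                        e = min(int(e), size)
                        if e > s:
                            candidate.append((s, e))
        merged = merge_intervals(candidate, merge_gap)
        kept = [(s, e) for s, e in merged if e - s >= min_region_length]
        if kept:
            regions[chrom] = kept
    return RegionSet(
        regions,
        provenance=(
            f"threshold_regions(threshold={threshold}, merge_gap={merge_gap}, "
            f"min_region_length={min_region_length}, files={[h.path for h in handles]})"
        ),
    )


def load_regions(path, chrom_table: Optional[ChromTable] = None) -> RegionSet:
    """Load a chrom/start/end table (TSV with header, or headerless BED dialect).

    Overlapping and adjacent input rows are merged.  When ``chrom_table``
    is given, rows are validated against it (unknown chromosome or
    out-of-bounds coordinates are errors).
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = first.strip() != "" and not _looks_like_data_row(first)
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        dtype={0: str},
        comment="#",
    )
    if df.empty:
        return RegionSet({}, provenance=f"load_regions({path})")
    if has_header:
        cols = {c.lower(): c for c in df.columns}
        missing = [c for c in ("chrom", "start", "end") if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing} in header")
        df = df[[cols["chrom"], cols["start"], cols["end"]]]
    else:
        if df.shape[1] < 3:
            raise ValueError(f"{path}: expected at least 3 tab-separated columns")
        df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)

    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(
            f"{path}: start >= end at data row(s) {[int(i) + 1 for i in bad[:10]]}"
        )
    if (df["start"] < 0).any():
        raise ValueError(f"{path}: negative start coordinate")
    if chrom_table is not None:
        unknown = sorted(set(df["chrom"]) - set(chrom_table.names()))
        if unknown:
            raise ValueError(f"{path}: unknown chromosome(s) {unknown}")
        for chrom, grp in df.groupby("chrom"):
            size = chrom_table.chrom_size(str(chrom))
            if (grp["end"] > size).any():
                raise ValueError(
                    f"{path}: region end beyond chromosome {chrom} size {size}"
                )
    regions = {
        str(chrom): merge_intervals(list(zip(grp["start"], grp["end"])))
        for chrom, grp in df.groupby("chrom")
    }
    return RegionSet(regions, provenance=f"load_regions({path})")


def _looks_like_data_row(line: str) -> bool:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        return False
    try:
        int(parts[1]), int(parts[2])
    except ValueError:
        return False
    return True


def save_regions(regions: RegionSet, path) -> str:
    """Write a RegionSet as a tab-separated chrom/start/end table with header."""
    path = str(path)
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for chrom in sorted(regions.regions):
            for s, e in regions.regions[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    return path
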
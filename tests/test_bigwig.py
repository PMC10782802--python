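"""Container-format layer: header parsing, R-tree lookup, section codecs, writer."""

import struct

import numpy as np
import pytest

from trackloader.bigwig import (
    BIGBED_MAGIC,
    BigWigError,
    SECTION_FIXEDSTEP,
    decode_section,
    find_blocks,
    iter_leaf_blocks,
    open_track,
    read_block,
    write_track,
)
from trackloader.batch import query_interval
from trackloader.intervals import GenomicInterval

CHROMS = {"chrA": 5_000, "chrB": 2_000}
RECORDS = {
    "chrA": [(0, 5, 1.0), (5, 10, 2.0), (100, 120, 3.5), (500, 501, 7.0), (900, 1000, 0.25)],
    "chrB": [(10, 20, 2.5), (1500, 1600, 4.0)],
}

ENCODINGS = ["bedgraph", "varstep", "fixedstep"]


def decode_all(handle, chrom):
    records = []
    size = handle.chroms.chrom_size(chrom)
    cid = handle.chroms.chrom_id(chrom)
    for block in find_blocks(handle, GenomicInterval(chrom, 0, size)):
        sec = decode_section(read_block(handle, block), handle.byteorder)
        if sec.chrom_id == cid:
            records.extend(sec.records)
    return records


@pytest.mark.parametrize("section_type", ENCODINGS)
@pytest.mark.parametrize("compress", [True, False])
@pytest.mark.parametrize("byteorder", ["<", ">"])
def test_round_trip_exact(tmp_path, section_type, compress, byteorder):
    """write -> open -> decode reproduces the input runs exactly, any encoding."""
    path = tmp_path / "t.bw"
    write_track(CHROMS, RECORDS, path, section_type=section_type,
                items_per_section=3, compress=compress, byteorder=byteorder)
    with open_track(path) as h:
        assert h.byteorder == byteorder
        assert set(h.chroms.names()) == set(CHROMS)
        for chrom in CHROMS:
            assert h.chroms.chrom_size(chrom) == CHROMS[chrom]
            assert decode_all(h, chrom) == RECORDS[chrom]


def test_byte_order_twins_agree(tmp_path):
    """A big-endian file and its little-endian twin parse identically."""
    le = write_track(CHROMS, RECORDS, tmp_path / "le.bw", byteorder="<")
    be = write_track(CHROMS, RECORDS, tmp_path / "be.bw", byteorder=">")
    with open_track(le) as hle, open_track(be) as hbe:
        assert hle.header.total_summary == hbe.header.total_summary
        assert dict(hle.chroms.items()) == dict(hbe.chroms.items())
        iv = GenomicInterval("chrA", 0, 1000)
        assert np.array_equal(query_interval(hle, iv), query_interval(hbe, iv))


def test_compressed_and_uncompressed_twins_agree(tmp_path):
    comp = write_track(CHROMS, RECORDS, tmp_path / "c.bw", compress=True)
    plain = write_track(CHROMS, RECORDS, tmp_path / "u.bw", compress=False)
    with open_track(comp) as hc, open_track(plain) as hu:
        assert hc.header.uncompress_buf_size > 0
        assert hu.header.uncompress_buf_size == 0
        for chrom in CHROMS:
            iv = GenomicInterval(chrom, 0, CHROMS[chrom])
            assert np.array_equal(query_interval(hc, iv), query_interval(hu, iv))


def test_cross_encoding_equivalence(tmp_path):
    """The same records produce identical profiles under all three encodings."""
    profiles = []
    for st in ENCODINGS:
        p = write_track(CHROMS, RECORDS, tmp_path / f"{st}.bw", section_type=st)
        with open_track(p) as h:
            profiles.append(query_interval(h, GenomicInterval("chrA", 0, 2000)))
    assert np.array_equal(profiles[0], profiles[1])
    assert np.array_equal(profiles[0], profiles[2])


def test_open_rejects_bad_magic(tmp_path):
    p = tmp_path / "zeros.bin"
    p.write_bytes(b"\x00" * 128)
    with pytest.raises(BigWigError, match="not a BigWig file"):
        open_track(p)


def test_open_rejects_bigbed(tmp_path):
    p = tmp_path / "bb.bin"
    p.write_bytes(struct.pack("<I", BIGBED_MAGIC) + b"\x00" * 124)
    with pytest.raises(BigWigError, match="BigBed not supported"):
        open_track(p)


def test_open_rejects_truncated_header(tmp_path):
    p = tmp_path / "trunc.bin"
    p.write_bytes(struct.pack("<I", 0x888FFC26) + b"\x00" * 10)
    with pytest.raises(BigWigError, match="corrupt file"):
        open_track(p)


def test_find_blocks_unknown_chromosome(tmp_path):
    p = write_track(CHROMS, RECORDS, tmp_path / "t.bw")
    with open_track(p) as h:
        with pytest.raises(BigWigError, match="chromosome not found.*chrZ"):
            find_blocks(h, GenomicInterval("chrZ", 0, 10))


def test_find_blocks_beyond_last_covered_base(tmp_path):
    p = write_track(CHROMS, RECORDS, tmp_path / "t.bw")
    with open_track(p) as h:
        assert find_blocks(h, GenomicInterval("chrA", 4000, 5000)) == []


def test_query_spanning_two_sections(tmp_path):
    """items_per_section=2 puts a section boundary inside chrA's run list."""
    p = write_track(CHROMS, RECORDS, tmp_path / "t.bw", items_per_section=2)
    with open_track(p) as h:
        # sections: [(0,5),(5,10)] and [(100,120),(500,501)] and [(900,1000)]
        blocks = find_blocks(h, GenomicInterval("chrA", 8, 110))
        assert len(blocks) == 2


def test_find_blocks_matches_linear_scan(tmp_path):
    """R-tree descent equals a brute-force scan over all leaf entries."""
    rng = np.random.default_rng(5)
    records = {
        "chrA": [(int(s), int(s) + 3, 1.0) for s in range(0, 4500, 7)],
        "chrB": [(int(s), int(s) + 2, 2.0) for s in range(0, 1900, 11)],
    }
    p = write_track(CHROMS, records, tmp_path / "dense.bw", items_per_section=8)
    with open_track(p) as h:
        leaves = list(iter_leaf_blocks(h))
        assert len(leaves) > 64  # force a multi-level R-tree
        for _ in range(200):
            chrom = "chrA" if rng.random() < 0.5 else "chrB"
            size = CHROMS[chrom]
            s = int(rng.integers(0, size - 1))
            e = int(rng.integers(s + 1, size + 1))
            iv = GenomicInterval(chrom, s, e)
            cid = h.chroms.chrom_id(chrom)
            expect = sorted(
                (b for b in leaves if b.chrom_id == cid and b.start < e and s < b.end),
                key=lambda b: b.file_offset,
            )
            assert find_blocks(h, iv) == expect


def test_decode_fixed_step_expansion():
    raw = struct.pack("<IIIIIBBH", 0, 100, 103, 1, 1, SECTION_FIXEDSTEP, 0, 3)
    raw += struct.pack("<fff", 1.0, 2.0, 3.0)
    sec = decode_section(raw)
    assert sec.records == [(100, 101, 1.0), (101, 102, 2.0), (102, 103, 3.0)]


def test_decode_bedgraph_identity():
    raw = struct.pack("<IIIIIBBH", 0, 10, 20, 0, 0, 1, 0, 1)
    raw += struct.pack("<IIf", 10, 20, 2.5)
    sec = decode_section(raw)
    assert sec.records == [(10, 20, 2.5)]


def test_decode_rejects_unknown_type():
    raw = struct.pack("<IIIIIBBH", 0, 0, 1, 0, 1, 9, 0, 0)
    with pytest.raises(BigWigError, match="unsupported section type"):
        decode_section(raw)


def test_decode_rejects_length_mismatch():
    raw = struct.pack("<IIIIIBBH", 0, 0, 10, 0, 0, 1, 0, 2)
    raw += struct.pack("<IIf", 0, 10, 1.0)  # claims 2 items, carries 1
    with pytest.raises(BigWigError, match="corrupt section"):
        decode_section(raw)


def test_random_sections_round_trip(tmp_path):
    """Decoded records equal what the writer encoded, over random record sets."""
    rng = np.random.default_rng(77)
    for trial in range(20):
        pos = 0
        records = []
        while pos < 4_900 and len(records) < 100:
            gap = int(rng.integers(0, 30))
            length = int(rng.integers(1, 40))
            s = pos + gap
            e = min(s + length, 5_000)
            if e <= s:
                break
            records.append((s, e, float(np.float32(rng.exponential()))))
            pos = e
        st = ENCODINGS[trial % 3]
        p = write_track({"chrA": 5_000}, {"chrA": records}, tmp_path / f"r{trial}.bw",
                        section_type=st, items_per_section=7)
        with open_track(p) as h:
            got = decode_all(h, "chrA")
            assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in records]
            assert np.array_equal(
                np.array([v for *_ , v in got], dtype=np.float32),
                np.array([v for *_, v in records], dtype=np.float32),
            )


@pytest.mark.parametrize("records, match", [
    ({"chrA": [(5, 10, 1.0), (0, 4, 2.0)]}, "sorted"),
    ({"chrA": [(0, 10, 1.0), (5, 15, 2.0)]}, "non-overlapping"),
    ({"chrA": [(4_990, 5_010, 1.0)]}, "outside chromosome"),
    ({"chrA": [(10, 10, 1.0)]}, "end <= start"),
])
def test_writer_rejects_invalid_records(tmp_path, records, match):
    with pytest.raises(ValueError, match=match):
        write_track(CHROMS, records, tmp_path / "bad.bw")


def test_reader_is_lazy_and_reads_only_planned_blocks(tmp_path):
    """Opening never touches the data region; queries read only their blocks."""
    p = write_track(CHROMS, RECORDS, tmp_path / "t.bw", items_per_section=2)
    h = open_track(p)
    try:
        data_lo = h.header.full_data_offset
        data_hi = h.header.full_index_offset
        for off, size in h.source.read_log:
            assert off + size <= data_lo or off >= data_hi, "open read data bytes"
        h.source.read_log.clear()
        iv = GenomicInterval("chrA", 0, 150)
        blocks = find_blocks(h, iv)
        for b in blocks:
            read_block(h, b)
        planned = {(b.file_offset, b.compressed_size) for b in blocks}
        for off, size in h.source.read_log:
            in_data = data_lo <= off < data_hi
            assert not in_data or (off, size) in planned
        assert planned  # the query did need data blocks
    finally:
        h.close()


def test_external_reader_agrees_with_writer(tmp_path):
    """A file we wrote is readable by pyBigWig with identical per-base values."""
    pyBigWig = pytest.importorskip("pyBigWig")
    p = write_track(CHROMS, RECORDS, tmp_path / "t.bw", items_per_section=3)
    rng = np.random.default_rng(9)
    bw = pyBigWig.open(str(p))
    with open_track(p) as h:
        for _ in range(100):
            chrom = "chrA" if rng.random() < 0.5 else "chrB"
            size = CHROMS[chrom]
            s = int(rng.integers(0, size - 50))
            iv = GenomicInterval(chrom, s, s + 50)
            ours = query_interval(h, iv, fill_value=float("nan"))
            theirs = np.array(bw.values(iv.chrom, iv.start, iv.end), dtype=np.float32)
            assert np.array_equal(ours, theirs, equal_nan=True)
    bw.close()


def test_reads_externally_written_file(tmp_path):
    """Our reader parses a pyBigWig-written file (compressed, zoomed)."""
    pyBigWig = pytest.importorskip("pyBigWig")
    p = str(tmp_path / "ext.bw")
    bw = pyBigWig.open(p, "w")
    bw.addHeader([("chr1", 1_000)])
    bw.addEntries(["chr1"] * 3, [0, 100, 200], ends=[50, 150, 250], values=[1.0, 2.0, 3.0])
    bw.close()
    with open_track(p) as h:
        assert h.chroms.chrom_size("chr1") == 1_000
        prof = query_interval(h, GenomicInterval("chr1", 0, 250))
        expect = np.zeros(250, dtype=np.float32)
        expect[0:50] = 1.0
        expect[100:150] = 2.0
        expect[200:250] = 3.0
        assert np.array_equal(prof, expect)
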
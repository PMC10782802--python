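"""Epoch iterator: shapes, centring, pairing, super-batch splitting, determinism."""

import numpy as np
import pytest

from trackloader.batch import BatchRequest, query_batch
from trackloader.bigwig import open_track, write_track
from trackloader.dataset import BigWigDataset, split_super_batch
from trackloader.genome import BASE_ORDER
from trackloader.regions import RegionSet


@pytest.fixture()
def small_dataset(corpus):
    ds = BigWigDataset(
        regions_of_interest=RegionSet({"chr1": [(0, 20_000)], "chr2": [(0, 20_000)]}),
        bigwig_path=corpus["paths"],
        reference_genome_path=corpus["fasta"],
        sequence_length=400,
        center_bin_to_predict=400,
        batch_size=8,
        super_batch_size=32,
        batches_per_epoch=5,
        maximum_unknown_bases_fraction=0.1,
        seed=3,
    )
    yield ds
    ds.close()


def test_epoch_shapes_and_length(small_dataset):
    batches = list(small_dataset)
    assert len(batches) == 5
    for seq, prof in batches:
        assert seq.shape == (8, 400, 4)
        assert seq.dtype == np.float32
        assert prof.shape == (8, 4, 400)
        assert prof.dtype == np.float32


def test_epoch_is_bitwise_reproducible(small_dataset):
    a = list(small_dataset)
    b = list(small_dataset)
    for (sa, pa), (sb, pb) in zip(a, b):
        assert sa.tobytes() == sb.tobytes()
        assert pa.tobytes() == pb.tobytes()


def test_single_batch_epoch(corpus):
    ds = BigWigDataset(
        regions_of_interest=RegionSet({"chr1": [(0, 20_000)]}),
        bigwig_path=corpus["paths"],
        reference_genome_path=corpus["fasta"],
        sequence_length=300,
        batch_size=4,
        super_batch_size=4,
        batches_per_epoch=1,
        seed=0,
    )
    try:
        batches = list(ds)
        assert len(batches) == 1
        again = list(ds)
        assert batches[0][0].tobytes() == again[0][0].tobytes()
        assert batches[0][1].tobytes() == again[0][1].tobytes()
    finally:
        ds.close()


def test_centered_window_is_slice_of_full_query(corpus):
    """center_bin 500 of a 1000-base window equals positions [250, 750)."""
    ds = BigWigDataset(
        regions_of_interest=RegionSet({"chr1": [(0, 20_000)], "chr2": [(0, 20_000)]}),
        bigwig_path=corpus["paths"],
        reference_genome_path=corpus["fasta"],
        sequence_length=1000,
        center_bin_to_predict=500,
        batch_size=4,
        super_batch_size=4,
        batches_per_epoch=2,
        seed=5,
    )
    handles = [open_track(p) for p in corpus["paths"]]
    try:
        # replay the dataset's RNG path to recover the windows it drew
        rng = np.random.default_rng(ds.seed)
        from trackloader.sampling import sample_batch

        intervals = sample_batch(ds.regions, ds.sampler_config, ds.genome, 4, rng)
        full = query_batch(BatchRequest(intervals, handles))
        prof0 = next(iter(ds))[1]
        assert np.array_equal(prof0, full[:, :, 250:750])
    finally:
        ds.close()
        for h in handles:
            h.close()


def test_parity_violation_rejected_at_construction(corpus):
    with pytest.raises(ValueError, match="parity"):
        BigWigDataset(
            regions_of_interest=RegionSet({"chr1": [(0, 20_000)]}),
            bigwig_path=corpus["paths"],
            reference_genome_path=corpus["fasta"],
            sequence_length=1000,
            center_bin_to_predict=501,
        )


def test_super_batch_must_be_multiple_of_batch(corpus):
    with pytest.raises(ValueError, match="multiple"):
        BigWigDataset(
            regions_of_interest=RegionSet({"chr1": [(0, 20_000)]}),
            bigwig_path=corpus["paths"],
            reference_genome_path=corpus["fasta"],
            sequence_length=100,
            batch_size=8,
            super_batch_size=12,
        )


def test_split_super_batch_round_trip():
    rng = np.random.default_rng(0)
    seqs = rng.random((1024, 10, 4)).astype(np.float32)
    profs = rng.random((1024, 3, 10)).astype(np.float32)
    chunks = split_super_batch(seqs, profs, 256)
    assert len(chunks) == 4
    assert all(c[0].shape[0] == 256 for c in chunks)
    assert np.concatenate([c[0] for c in chunks]).tobytes() == seqs.tobytes()
    assert np.concatenate([c[1] for c in chunks]).tobytes() == profs.tobytes()
    single = split_super_batch(seqs, profs, 1024)
    assert len(single) == 1 and single[0][0].shape[0] == 1024
    with pytest.raises(ValueError, match="divisible"):
        split_super_batch(seqs, profs, 300)


def test_directory_expansion_defines_file_axis(corpus, tmp_path):
    import shutil
    from pathlib import Path

    d = tmp_path / "tracks"
    d.mkdir()
    # copy in non-lexicographic creation order; axis must still be sorted
    for src in reversed(corpus["paths"]):
        shutil.copy(src, d / Path(src).name)
    ds = BigWigDataset(
        regions_of_interest=RegionSet({"chr1": [(0, 20_000)]}),
        bigwig_path=d,
        reference_genome_path=corpus["fasta"],
        sequence_length=100,
        batch_size=2,
        batches_per_epoch=1,
        seed=1,
    )
    try:
        assert ds.bigwig_paths == sorted(ds.bigwig_paths)
        assert [p.split("/")[-1] for p in ds.bigwig_paths] == [
            p.split("/")[-1] for p in corpus["paths"]
        ]
    finally:
        ds.close()


def test_sentinel_pairing(tmp_path):
    """Row b's sequence and profile come from the same sampled window.

    The genome encodes position p as base 'ACGT'[p % 4]; the track stores
    value(p) = p.  Recovering p from the profile row must predict the
    sequence row exactly.
    """
    n = 8_000
    seq = "".join(BASE_ORDER[p % 4] for p in range(n))
    fasta = tmp_path / "sentinel.fa"
    with open(fasta, "w") as fh:
        fh.write(">c1\n")
        for i in range(0, n, 60):
            fh.write(seq[i : i + 60] + "\n")
    track = write_track(
        {"c1": n},
        {"c1": [(p, p + 1, float(p)) for p in range(n)]},
        tmp_path / "sentinel.bw",
        section_type="fixedstep",
        items_per_section=512,
    )
    ds = BigWigDataset(
        regions_of_interest=RegionSet({"c1": [(0, n)]}),
        bigwig_path=[track],
        reference_genome_path=fasta,
        sequence_length=100,
        center_bin_to_predict=50,
        batch_size=16,
        super_batch_size=32,
        batches_per_epoch=4,
        seed=9,
    )
    off = (100 - 50) // 2
    try:
        for enc, prof in ds:
            for b in range(enc.shape[0]):
                center_start = int(prof[b, 0, 0])  # exact: n < 2**24 in float32
                assert np.array_equal(
                    prof[b, 0, :],
                    np.arange(center_start, center_start + 50, dtype=np.float32),
                )
                window_start = center_start - off
                expect = seq[window_start : window_start + 100]
                decoded = "".join(BASE_ORDER[i] for i in enc[b].argmax(axis=1))
                assert decoded == expect
    finally:
        ds.close()


def test_raw_sequence_encoder(corpus):
    ds = BigWigDataset(
        regions_of_interest=RegionSet({"chr1": [(0, 20_000)]}),
        bigwig_path=corpus["paths"],
        reference_genome_path=corpus["fasta"],
        sequence_length=120,
        batch_size=4,
        batches_per_epoch=1,
        sequence_encoder="raw",
        seed=2,
    )
    try:
        seqs, prof = next(iter(ds))
        assert len(seqs) == 4
        assert all(isinstance(s, str) and len(s) == 120 for s in seqs)
        assert prof.shape == (4, 4, 120)
    finally:
        ds.close()
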
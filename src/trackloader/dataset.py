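"""Epoch-structured dataset iterator: (encoded sequence, profile) batch pairs.

:class:`BigWigDataset` ties the sampler, the genome accessor and the
batched track query into the stream a supervised sequence-to-profile
model trains on::

    dataset = BigWigDataset(
        regions_of_interest="train_regions.tsv",
        bigwig_path="tracks/",
        reference_genome_path="genome.fa",
        sequence_length=1000,
        center_bin_to_predict=1000,
        batch_size=256,
        super_batch_size=1024,
        batches_per_epoch=20,
        maximum_unknown_bases_fraction=0.1,
        sequence_encoder="onehot",
    )
    for encoded_sequence, epigenetic_profiles in dataset:
        ...  # (batch, length, 4) features, (batch, n_files, center_bin) targets

Intervals are drawn in super-batches, resolved against all tracks in one
batched query (disk reads and block decodes amortise over the whole
super-batch), then split into consecutive optimizer-sized batches.  The
profile target covers the centred ``center_bin_to_predict`` bases of each
window; ``center_bin_to_predict`` and ``sequence_length`` must have equal
parity so the centring offset is whole — asymmetric off-by-one windows
are rejected at construction, never silently rounded.

Iteration is deterministic: each ``iter()`` call restarts the RNG from
the configured seed, so two iterations of equally-configured datasets are
bitwise identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, List, Optional, Tuple, Union

import numpy as np

from .batch import BatchRequest, query_batch
from .bigwig import TrackFileHandle, open_track
from .genome import GenomeAccessor, one_hot_encode
from .intervals import GenomicInterval
from .regions import RegionSet, load_regions
from .sampling import SamplerConfig, sample_batch


def split_super_batch(
    sequences: np.ndarray, profiles: np.ndarray, batch_size: int
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Split a super-batch into consecutive optimizer-sized batch pairs.

    Concatenating the chunks in order reproduces the super-batch exactly.
    """
    n = sequences.shape[0]
    if profiles.shape[0] != n:
        raise ValueError(
            f"sequence and profile leading axes differ: {n} vs {profiles.shape[0]}"
        )
    if n % batch_size != 0:
        raise ValueError(f"super-batch of {n} not divisible by batch_size {batch_size}")
    return [
        (sequences[i : i + batch_size], profiles[i : i + batch_size])
        for i in range(0, n, batch_size)
    ]


def _expand_bigwig_paths(bigwig_path) -> List[str]:
    if isinstance(bigwig_path, (str, Path)):
        p = Path(bigwig_path)
        if p.is_dir():
            paths = sorted(
                str(f) for f in p.iterdir()
                if f.suffix.lower() in (".bw", ".bigwig") and f.is_file()
            )
            if not paths:
                raise ValueError(f"no BigWig files (*.bw, *.bigWig) in directory {p}")
            return paths
        return [str(p)]
    return [str(p) for p in bigwig_path]


class BigWigDataset:
    """Iterable over (encoded_sequence, epigenetic_profiles) training batches.

    Parameters
    ----------
    regions_of_interest
        A :class:`RegionSet` or a path to a chrom/start/end table; sampled
        windows lie wholly inside these regions.
    bigwig_path
        A directory (expanded to ``*.bw`` / ``*.bigWig``, lexicographically
        sorted — this ordering defines the file axis of every profile
        tensor), a single file, or an explicit ordered list of files.
    reference_genome_path
        FASTA reference; a faidx sidecar index is built if absent.
    sequence_length
        Window length in bases fed to the model.
    center_bin_to_predict
        Length of the centred sub-window the profile targets cover;
        defaults to ``sequence_length``; must have equal parity with it.
    batch_size, super_batch_size, batches_per_epoch
        ``super_batch_size`` windows are loaded per query and split into
        ``super_batch_size / batch_size`` consecutive batches; an epoch
        yields exactly ``batches_per_epoch`` batches.
    maximum_unknown_bases_fraction
        Windows with a larger fraction of non-ACGT reference bases are
        rejected and resampled (before any track query, so rejects cost
        no decompression).
    sequence_encoder
        ``"onehot"`` for (B, L, 4) float32 tensors or ``"raw"`` for the
        uppercase strings themselves.
    fill_value
        Value assigned to bases no track record covers (default 0.0).
    seed
        Seed of the single RNG stream driving all sampling.
    """

    def __init__(
        self,
        regions_of_interest: Union[RegionSet, str, Path],
        bigwig_path,
        reference_genome_path,
        sequence_length: int = 1000,
        center_bin_to_predict: Optional[int] = None,
        batch_size: int = 256,
        super_batch_size: Optional[int] = None,
        batches_per_epoch: int = 20,
        maximum_unknown_bases_fraction: float = 0.1,
        sequence_encoder: str = "onehot",
        fill_value: float = 0.0,
        seed: int = 0,
        max_resample_rounds: int = 10,
    ):
        if center_bin_to_predict is None:
            center_bin_to_predict = sequence_length
        if super_batch_size is None:
            super_batch_size = batch_size
        if center_bin_to_predict > sequence_length:
            raise ValueError(
                f"center_bin_to_predict ({center_bin_to_predict}) exceeds "
                f"sequence_length ({sequence_length})"
            )
        if center_bin_to_predict < 1:
            raise ValueError("center_bin_to_predict must be >= 1")
        if (sequence_length - center_bin_to_predict) % 2 != 0:
            raise ValueError(
                f"sequence_length ({sequence_length}) and center_bin_to_predict "
                f"({center_bin_to_predict}) must have equal parity so the "
                "centring offset is a whole number of bases"
            )
        if super_batch_size % batch_size != 0 or super_batch_size < batch_size:
            raise ValueError(
                f"super_batch_size ({super_batch_size}) must be a positive "
                f"multiple of batch_size ({batch_size})"
            )
        if batches_per_epoch < 1:
            raise ValueError("batches_per_epoch must be >= 1")
        if sequence_encoder not in ("onehot", "raw"):
            raise ValueError(f"unknown sequence_encoder {sequence_encoder!r}")

        self.bigwig_paths = _expand_bigwig_paths(bigwig_path)
        self.handles: List[TrackFileHandle] = [open_track(p) for p in self.bigwig_paths]
        self.genome = GenomeAccessor(reference_genome_path)
        if isinstance(regions_of_interest, RegionSet):
            self.regions = regions_of_interest
        else:
            self.regions = load_regions(regions_of_interest)
        for iv in self.regions:
            if iv.chrom not in self.genome.index:
                raise ValueError(
                    f"region chromosome {iv.chrom!r} absent from genome "
                    f"{self.genome.fasta_path}"
                )
            for h in self.handles:
                if iv.chrom not in h.chroms:
                    raise ValueError(
                        f"region chromosome {iv.chrom!r} absent from track {h.path}"
                    )

        self.sequence_length = sequence_length
        self.center_bin_to_predict = center_bin_to_predict
        self.batch_size = batch_size
        self.super_batch_size = super_batch_size
        self.batches_per_epoch = batches_per_epoch
        self.sequence_encoder = sequence_encoder
        self.fill_value = fill_value
        self.seed = seed
        self.sampler_config = SamplerConfig(
            sequence_length=sequence_length,
            maximum_unknown_bases_fraction=maximum_unknown_bases_fraction,
            seed=seed,
            max_resample_rounds=max_resample_rounds,
        )

    @property
    def n_files(self) -> int:
        return len(self.handles)

    def close(self) -> None:
        for h in self.handles:
            h.close()
        self.genome.close()

    def _center_offset(self) -> int:
        return (self.sequence_length - self.center_bin_to_predict) // 2

    def _load_super_batch(self, rng: np.random.Generator):
        intervals = sample_batch(
            self.regions, self.sampler_config, self.genome, self.super_batch_size, rng
        )
        sequences = [self.genome.fetch(iv) for iv in intervals]
        off = self._center_offset()
        target_ivs = [
            GenomicInterval(iv.chrom, iv.start + off, iv.end - off) for iv in intervals
        ]
        profiles = query_batch(
            BatchRequest(target_ivs, self.handles, fill_value=self.fill_value)
        )
        if self.sequence_encoder == "onehot":
            encoded = one_hot_encode(sequences).one_hot
        else:
            encoded = np.array(sequences, dtype=object)
        return encoded, profiles

    def __iter__(self) -> Iterator[Tuple[np.ndarray, np.ndarray]]:
        rng = np.random.default_rng(self.seed)
        yielded = 0
        while yielded < self.batches_per_epoch:
            encoded, profiles = self._load_super_batch(rng)
            for seq_chunk, prof_chunk in split_super_batch(
                encoded, profiles, self.batch_size
            ):
                if yielded >= self.batches_per_epoch:
                    break
                yield seq_chunk, prof_chunk
                yielded += 1

    def __len__(self) -> int:
        return self.batches_per_epoch
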
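"""Seeded sampling of fixed-length training windows from a region set.

Windows are drawn with replacement, uniformly over *valid start
positions*: a region of length R can host R - L + 1 starts for window
length L, and each valid start across all eligible regions is equally
likely (picking a region first and a start second would over-weight short
regions).  Regions shorter than L are excluded from the pool.

Sampled windows whose reference sequence is too rich in unknown bases
(fraction of non-ACGT characters above a configurable maximum) are
discarded and replaced by fresh draws, the same trick used by other
genomic samplers to keep assembly gaps out of training batches.  All
randomness flows through an explicit numpy Generator — no global state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .genome import GenomeAccessor, count_unknown_bases
from .intervals import GenomicInterval
from .regions import RegionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    sequence_length: int
    maximum_unknown_bases_fraction: float = 0.1
    seed: int = 0
    max_resample_rounds: int = 10

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if not 0.0 <= self.maximum_unknown_bases_fraction <= 1.0:
            raise ValueError("maximum_unknown_bases_fraction must lie in [0, 1]")
        if self.max_resample_rounds < 1:
            raise ValueError("max_resample_rounds must be positive")


def _eligible_regions(
    regions: RegionSet, length: int
) -> List[Tuple[str, int, int]]:
    eligible = []
    n_short = 0
    for chrom in sorted(regions.regions):
        for s, e in regions.regions[chrom]:
            if e - s >= length:
                eligible.append((chrom, s, e))
            else:
                n_short += 1
    if n_short:
        logger.info(
            "%d region(s) shorter than %d excluded from the sampling pool",
            n_short,
            length,
        )
    return eligible


def sample_intervals(
    regions: RegionSet,
    length: int,
    n: int,
    rng: np.random.Generator,
) -> List[GenomicInterval]:
    """Draw ``n`` windows of ``length`` bases, uniform over valid starts."""
    if n < 0:
        raise ValueError("n must be >= 0")
    eligible = _eligible_regions(regions, length)
    if not eligible:
        raise ValueError(f"no region can host an interval of length {length}")
    counts = np.array([e - s - length + 1 for _, s, e in eligible], dtype=np.int64)
    cum = np.cumsum(counts)
    total = int(cum[-1])
    draws = rng.integers(0, total, size=n)
    region_idx = np.searchsorted(cum, draws, side="right")
    out = []
    for d, ri in zip(draws.tolist(), region_idx.tolist()):
        chrom, s, _e = eligible[ri]
        offset = d - (int(cum[ri - 1]) if ri else 0)
        out.append(GenomicInterval(chrom, s + offset, s + offset + length))
    return out


def filter_by_unknown_bases(
    intervals: Sequence[GenomicInterval],
    genome: GenomeAccessor,
    max_fraction: float,
) -> Tuple[List[GenomicInterval], int]:
    """Keep windows whose unknown-base fraction is <= max_fraction.

    The boundary is inclusive: a window exactly at the maximum is kept.
    Returns (kept intervals in input order, number rejected).
    """
    kept: List[GenomicInterval] = []
    rejected = 0
    for iv in intervals:
        seq = genome.fetch(iv)
        if count_unknown_bases(seq) <= max_fraction * len(iv):
            kept.append(iv)
        else:
            rejected += 1
    return kept, rejected


def sample_batch(
    regions: RegionSet,
    config: SamplerConfig,
    genome: GenomeAccessor,
    n: int,
    rng: np.random.Generator,
) -> List[GenomicInterval]:
    """Sample exactly ``n`` accepted windows, resampling rejected ones.

    Each round draws ceil(1.5 x deficit) candidates; after
    ``config.max_resample_rounds`` rounds with the batch still short, an
    error reports the observed acceptance rate (this guards degenerate
    genomes where nearly every window is unknown sequence).
    """
    accepted: List[GenomicInterval] = []
    drawn = 0
    for _round in range(config.max_resample_rounds):
        deficit = n - len(accepted)
        if deficit <= 0:
            break
        candidates = sample_intervals(
            regions, config.sequence_length, math.ceil(1.5 * deficit), rng
        )
        drawn += len(candidates)
        kept, _rej = filter_by_unknown_bases(
            candidates, genome, config.maximum_unknown_bases_fraction
        )
        accepted.extend(kept)
    if len(accepted) < n:
        rate = len(accepted) / drawn if drawn else 0.0
        raise RuntimeError(
            f"could not collect {n} windows in {config.max_resample_rounds} "
            f"resampling rounds (acceptance rate {rate:.3f}); is the genome "
            f"mostly unknown sequence?"
        )
    return accepted[:n]
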
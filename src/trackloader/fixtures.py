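"""Deterministic synthetic genomes and track files with known ground truth.

Every other module in the package is testable fully offline against
fixtures from here: a random reference genome (i.i.d. uniform ACGT with
i.i.d. N at a configurable rate) and a set of BigWig tracks drawn from a
sparse piecewise-constant signal model — alternating runs of zero
coverage and exponentially-distributed values, with geometric run
lengths.  Long zero stretches punctuated by valued runs mimic the shape
of real coverage tracks (sparse signal over mostly-empty genome) closely
enough that threshold-based region derivation produces realistically
fragmented region sets; assay-specific structure (fragment-length
effects, GC bias) is deliberately not modelled.

Tracks are written through :func:`trackloader.bigwig.write_track`,
cycling through the three section encodings and alternating compressed /
uncompressed storage across files, and the exact per-base value arrays
are returned alongside — the ground truth every query result is checked
against.  Uncovered bases are NaN in the truth arrays; a query with fill
value ``v`` is expected to return the truth with NaN replaced by ``v``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .bigwig import write_track

#: encoding/compression rotation applied across fixture files
_ENCODING_CYCLE = [
    ("bedgraph", True),
    ("fixedstep", True),
    ("varstep", True),
    ("bedgraph", False),
    ("fixedstep", False),
    ("varstep", False),
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic corpus (genome + tracks)."""

    n_chroms: int = 2
    chrom_length: int = 100_000
    n_files: int = 4
    mean_run_length: float = 50.0  # geometric run-length mean, bases
    value_rate: float = 1.0  # exponential rate of run values
    sparsity: float = 0.5  # fraction of runs carrying zero coverage
    n_fraction: float = 0.01  # probability a genome base is N
    seed: int = 0
    items_per_section: int = 64

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1 or self.n_files < 1:
            raise ValueError("counts and lengths must be >= 1")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if not 0.0 <= self.n_fraction <= 1.0:
            raise ValueError("n_fraction must lie in [0, 1]")
        if self.mean_run_length < 1.0:
            raise ValueError("mean_run_length must be >= 1")

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> Dict[str, int]:
        return {name: self.chrom_length for name in self.chrom_names()}


def make_genome(spec: FixtureSpec, out_dir) -> Tuple[str, Dict[str, str]]:
    """Write a random FASTA genome; return (path, per-contig truth strings)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xFA57A]))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "genome.fa"
    truth: Dict[str, str] = {}
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for name in spec.chrom_names():
            bases = alphabet[rng.integers(0, 4, size=spec.chrom_length)]
            if spec.n_fraction > 0:
                mask = rng.random(spec.chrom_length) < spec.n_fraction
                bases = np.where(mask, np.uint8(ord("N")), bases)
            seq = bases.tobytes().decode("ascii")
            truth[name] = seq
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return str(path), truth


def _draw_runs(
    rng: np.random.Generator, length: int, mean_run: float, rate: float, sparsity: float
) -> List[Tuple[int, int, float]]:
    """Alternating coverage/gap runs over [0, length); returns valued runs only."""
    runs: List[Tuple[int, int, float]] = []
    pos = 0
    p = 1.0 / mean_run
    while pos < length:
        run_len = int(rng.geometric(p))
        end = min(pos + run_len, length)
        if rng.random() >= sparsity:
            value = float(np.float32(rng.exponential(1.0 / rate)))
            runs.append((pos, end, value))
        pos = end
    return runs


def make_tracks(
    spec: FixtureSpec, out_dir
) -> Tuple[List[str], List[Dict[str, np.ndarray]]]:
    """Write ``n_files`` BigWig tracks; return (paths, per-file truth arrays).

    Truth arrays are float32 per-base values with NaN at uncovered bases.
    File *i* uses encoding/compression ``_ENCODING_CYCLE[i % 6]``, so any
    corpus of >= 3 files exercises multiple encodings and >= 4 files both
    compression modes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: List[str] = []
    truths: List[Dict[str, np.ndarray]] = []
    chrom_sizes = spec.chrom_sizes()
    for i in range(spec.n_files):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB16, i]))
        section_type, compress = _ENCODING_CYCLE[i % len(_ENCODING_CYCLE)]
        records: Dict[str, List[Tuple[int, int, float]]] = {}
        truth: Dict[str, np.ndarray] = {}
        for name in spec.chrom_names():
            runs = _draw_runs(
                rng, spec.chrom_length, spec.mean_run_length, spec.value_rate, spec.sparsity
            )
            records[name] = runs
            arr = np.full(spec.chrom_length, np.nan, dtype=np.float32)
            for s, e, v in runs:
                arr[s:e] = np.float32(v)
            truth[name] = arr
        path = out_dir / f"track_{i:03d}.bw"
        write_track(
            chrom_sizes,
            records,
            path,
            section_type=section_type,
            items_per_section=spec.items_per_section,
            compress=compress,
        )
        paths.append(str(path))
        truths.append(truth)
    return paths, truths


def make_corpus(spec: FixtureSpec, out_dir):
    """Genome plus tracks in one call; returns (fasta, genome_truth, paths, truths)."""
    fasta, genome_truth = make_genome(spec, out_dir)
    paths, truths = make_tracks(spec, out_dir)
    return fasta, genome_truth, paths, truths
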
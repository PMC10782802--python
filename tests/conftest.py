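import numpy as np
import pytest

from trackloader.bigwig import open_track
from trackloader.fixtures import FixtureSpec, make_corpus
from trackloader.genome import GenomeAccessor
from trackloader.intervals import GenomicInterval


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Small synthetic corpus: genome + 4 tracks (mixed encodings/compression)."""
    out = tmp_path_factory.mktemp("corpus")
    spec = FixtureSpec(n_chroms=2, chrom_length=20_000, n_files=4, seed=11)
    fasta, genome_truth, paths, truths = make_corpus(spec, out)
    return {
        "spec": spec,
        "fasta": fasta,
        "genome_truth": genome_truth,
        "paths": paths,
        "truths": truths,
    }


@pytest.fixture()
def corpus_handles(corpus):
    handles = [open_track(p) for p in corpus["paths"]]
    yield handles
    for h in handles:
        h.close()


@pytest.fixture()
def corpus_genome(corpus):
    with GenomeAccessor(corpus["fasta"]) as acc:
        yield acc


def random_intervals(spec: FixtureSpec, n: int, length: int, rng) -> list:
    """Uniform random fixed-length intervals over a fixture corpus."""
    out = []
    names = spec.chrom_names()
    for _ in range(n):
        chrom = names[int(rng.integers(0, len(names)))]
        start = int(rng.integers(0, spec.chrom_length - length + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def expected_profile(truth_chrom: np.ndarray, iv: GenomicInterval, fill: float) -> np.ndarray:
    """Ground-truth profile slice with NaN (uncovered) replaced by fill."""
    sl = truth_chrom[iv.start : iv.end].copy()
    sl[np.isnan(sl)] = fill
    return sl.astype(np.float32)
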
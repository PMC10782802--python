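# trackloader

Batched BigWig queries and machine-learning dataloading for epigenetic
profile models.

Sequence-to-profile models — networks that take a fixed-length genomic DNA
window and regress the per-base signal of assays such as DNase-seq,
ChIP-seq or ATAC-seq across many experiments at once — need training
batches of the form *B intervals × F track files × L bases*. General-purpose
BigWig readers resolve one region in one file per call, which is too slow to
keep a model fed and pushes people into preprocessing training tensors to
disk. `trackloader` instead serves batches straight from the source files:

* a pure-Python **reader and writer for the BigWig container** (main
  header, chromosome B+ tree, R-tree interval index, DEFLATE-compressed
  data sections in all three encodings — bedGraph, variable-step,
  fixed-step; both byte orders; zoom levels skipped),
* a **batched query engine**: all blocks needed by a batch are planned at
  once (deduplicated per file, ordered for sequential reads), decompressed
  as one stage, decoded once each, and scattered into a dense float32
  tensor of shape `(n_intervals, n_files, interval_length)`,
* **region-of-interest derivation** directly from the tracks (stretches
  where at least one file's value meets a threshold, merged and
  size-filtered) plus TSV/BED-dialect region table IO,
* a **seeded sampler** of fixed-length windows, uniform over valid start
  positions, with rejection-and-resampling of windows too rich in unknown
  (non-ACGT) reference bases,
* **faidx-convention FASTA window access** and one-hot encoding
  (channel order A, C, G, T; unknown bases are all-zero vectors),
* an **epoch-structured dataset iterator** yielding
  `(encoded_sequence, epigenetic_profiles)` batch pairs, loading
  oversized super-batches in one query and splitting them into
  optimizer-sized batches,
* a **fixture generator** for synthetic genomes and tracks with exact
  per-base ground truth, so everything is testable offline, and
* a `trackloader` **CLI** (`info`, `query`, `roi`, `sample`, `fixtures`,
  `benchmark`).

All coordinates are 0-based half-open. Values are float32 end-to-end
(BigWig stores float32). Bases covered by no record receive a
configurable `fill_value` (default `0.0`; use `nan` for parity with
general-purpose readers).

## Worked example

```python
import numpy as np
from trackloader import (
    BigWigDataset, FixtureSpec, make_corpus, open_track, threshold_regions,
)

# synthetic corpus: 2 chromosomes x 100 kb genome, 4 BigWig tracks
fasta, _, track_paths, _ = make_corpus(FixtureSpec(seed=1), "corpus")

# regions where at least one track reaches 0.5, merged across <=100-base
# gaps, at least 1000 bases long
handles = [open_track(p) for p in track_paths]
regions = threshold_regions(handles, threshold=0.5, merge_gap=100,
                            min_region_length=1000)
print(len(regions), regions.total_bases())

dataset = BigWigDataset(
    regions_of_interest=regions,
    bigwig_path="corpus",
    reference_genome_path=fasta,
    sequence_length=1000,
    center_bin_to_predict=1000,
    batch_size=256,
    super_batch_size=1024,
    batches_per_epoch=20,
    maximum_unknown_bases_fraction=0.1,
    sequence_encoder="onehot",
    seed=0,
)
for encoded_sequence, epigenetic_profiles in dataset:
    print(encoded_sequence.shape, epigenetic_profiles.shape)
    break
```

prints

```
64 169348
(256, 1000, 4) (256, 4, 1000)
```

— 64 derived sampling regions covering 169,348 bases, then per training
batch a `(256, 1000, 4)` one-hot sequence tensor and a `(256, 4, 1000)`
profile tensor: 256 windows × 4 track files × 1000 per-base values, with
row *b* of both tensors coming from the same sampled window. Iterating
the dataset again reproduces the epoch bitwise.

The same query is available from the shell:

```sh
trackloader roi corpus -t 0.5 --merge-gap 100 --min-length 1000 -o roi.tsv
trackloader sample --regions roi.tsv --genome corpus/genome.fa -l 1000 -n 8 -o windows.tsv
trackloader query corpus --regions windows.tsv -o tensor.npy
```

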
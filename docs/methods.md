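# Methods

## Problem setting

Supervised models on epigenetic data take a fixed-length DNA window and
predict the per-base assay signal (DNase-seq, ChIP-seq, ATAC-seq, ...)
across many experiments simultaneously. A training step therefore needs,
for a batch of B same-length windows, the dense profiles of all F track
files: a `(B, F, L)` tensor, plus the `(B, L, 4)` one-hot encoding of the
window sequences. The BigWig container — the de-facto standard for such
signal — stores runs of `(start, end, value)` in DEFLATE-compressed
sections indexed by an R-tree, which is efficient for one region in one
file but leaves the batched access pattern to the caller. `trackloader`
implements that batched pattern natively, on the CPU, with all stages
vectorized.

## The container layer

`bigwig.open_track` parses the 64-byte main header (auto-detecting byte
order from the magic number; every later read honours the detected
order), the chromosome B+ tree (name → id, size; exact-match lookup, no
`chr`-prefix aliasing — a name mismatch across files is always an error)
and records the R-tree root offset. Data sections are never read at open
time; `find_blocks` descends the R-tree on demand and returns the leaf
blocks overlapping a query in file-offset order. R-tree and B+-tree
nodes are read lazily and cached per handle. Zoom (downsampled summary)
levels are skipped on read — training-profile regression consumes
full-resolution values only — and never written. BigBed files are
rejected with an explicit message. Corrupt input fails fast with the
file path in the message; nothing is skipped silently.

`decode_section` handles the three section encodings: bedGraph items
carry explicit `(start, end, value)`; variable-step items carry
`(start, value)` with a section-wide span; fixed-step items carry only
values, expanded as `start + i·step` with a section-wide span. Decoding
is `numpy.frombuffer`-based; item counts are checked against the byte
length.

`write_track` emits a zoom-free but otherwise standard file: header,
total-summary record, chromosome B+ tree (single leaf node; chromosome
ids assigned in sorted-name order), a uint64 section count followed by
the (optionally zlib-compressed) sections, and a bottom-up packed R-tree
with branching factor 64 over sections already sorted by
`(chrom_id, start)` — correctness over balancing heuristics. Sections
hold at most `items_per_section` records (default 64, deliberately small
so that desk-scale fixtures already exercise multi-block queries) and
are split further wherever the chosen encoding cannot represent the run
structure (a variable-step section needs one span; a fixed-step section
needs one span and arithmetically spaced starts). This makes every legal
record set writable under every encoding, which the cross-encoding
equivalence tests rely on. Files we write are read back by pyBigWig with
identical per-base values, and we read pyBigWig-written files; both
directions are covered in the test suite, with the external reader used
strictly as an independent oracle.

## Batched queries

`query_batch` is contractually equivalent to stacking B × F independent
single-interval queries, but executes as: plan (every needed block
listed once per file with the interval indices it serves, ordered by
`(file_index, file_offset)` for sequential reads) → decompress (a pure
mapping block → bytes, so the stage may be parallelised without changing
output; uncompressed files pass through) → decode (each block once;
runs grouped per file and chromosome, kept sorted) → scatter. The
scatter is fully vectorized: per `(interval, file)` pair, the overlapping
run range is found by binary search and expanded with
`repeat`/`cumsum` index arithmetic rather than a per-run Python loop —
the CPU analogue of a GPU scatter kernel.

Choices the container standard does not dictate:

* **fill_value** — bases covered by no record get 0.0 by default (the
  useful convention for regression targets); `fill_value=nan` is exposed
  for parity with general-purpose readers. Users should be aware the
  container itself does not define this.
* **out-of-bounds intervals** are a hard error, never clamped: silent
  clamping would change what tensor row *b* means. Producing in-bounds
  intervals is the sampler's job.
* **double coverage** (two records covering one base) violates the
  container's single-coverage assumption and raises.
* **float width** is float32 end-to-end, matching on-disk storage.
* No cross-batch caching: a handle keeps only header, chromosome table
  and index nodes resident; block reuse is memoized within one batch.

## Regions of interest

`threshold_regions` marks a base as interesting iff at least one file's
value there is **≥** the threshold (inclusive, so integer-valued
coverage tracks behave intuitively at the threshold; note some
descriptions of this operation say "exceeds"), then merges stretches
separated by ≤ `merge_gap` bases and drops merged regions shorter than
`min_region_length`. Uncovered bases count as 0.0, so a non-positive
threshold covers whole chromosomes. The scan streams over decoded
records — candidate intervals are record subranges, merged incrementally
— and never materialises per-base arrays; the refinement-invariance of
gap-merging makes this equal to the per-base definition, which the tests
check against a brute-force oracle. `merge_gap` defaults to 0;
`min_region_length` should normally be set to the training
`sequence_length` so every kept region can host at least one window
(regions are not shrunk to guarantee fit — the sampler excludes
too-short regions instead). Chromosomes absent from some files are
skipped with a warning. Monotonicity (raising the threshold never adds
bases; widening the gap never increases the region count) is asserted as
a property.

## Sampling

Windows are drawn with replacement, uniformly over valid start positions
(region weighted by `region_length − length + 1`), via one cumulative-sum
lookup per batch. Unknown-base rejection keeps a window iff
`#non-ACGT / L ≤ maximum_unknown_bases_fraction` (boundary inclusive,
case-insensitive; IUPAC ambiguity codes count as unknown). Each
resampling round draws `ceil(1.5 × deficit)` candidates;
`max_resample_rounds` (default 10) bounds the loop and produces a
diagnostic error with the observed acceptance rate on degenerate (e.g.
all-N) genomes. Under i.i.d. N placement at rate p the acceptance rate
approaches `(1 − p)^L`, checked loosely in the suite. All randomness
flows through one explicit `numpy.random.Generator`; nothing global.

## Genome access and encoding

FASTA window access follows the faidx convention; the accessor builds
the 5-column `.fai` sidecar itself when absent (uniform line lengths per
contig required; Unix and Windows newlines supported) and is
cross-checked against pyfaidx in the tests. One-hot encoding uses
channel order A, C, G, T with case folding; unknown bases are all-zero
vectors rather than 0.25-uniform, preserving the invariant that the
channel sum equals the known-base indicator.

## The dataset iterator

`BigWigDataset` mirrors the construction surface shown in the README.
`super_batch_size` windows are sampled, filtered (rejection happens on
the sequence before any track query, so rejected windows cost no
decompression), fetched, queried in one `query_batch` call over the
centred target sub-window `[start + off, end − off)` with
`off = (sequence_length − center_bin_to_predict) / 2`, and split into
consecutive `batch_size` chunks. Equal parity of `sequence_length` and
`center_bin_to_predict` is required at construction — the classic
off-by-one misalignment in this domain is rejected, not rounded. The
sampler guarantees the *full* sequence window (not just the centre bin)
lies inside a region — the stricter reading. The file axis is the
lexicographically sorted expansion of the track directory, frozen at
construction. Each `iter()` restarts the RNG from the configured seed,
so epochs are bitwise reproducible; an epoch is exactly
`batches_per_epoch` batches regardless of rejection behaviour. The
iterator yields plain numpy tensors; framework adapters (and any
zero-copy exchange) are left to the user, as is model code.

## Synthetic fixtures

The generator emulates sparse coverage tracks: per chromosome, a
sequence of runs with geometric lengths (default mean 50 bases), each
run either a zero-coverage gap (probability `sparsity`, default 0.5 —
defined per run, which gives the same expected base fraction) or a
constant value drawn from an exponential distribution (rate 1.0).
Defaults are 2 chromosomes × 100,000 bases × 4 files — seconds-scale on
one CPU while still producing hundreds of sections per file and
realistically fragmented threshold regions. Genomes are i.i.d. uniform
ACGT with i.i.d. N at rate `n_fraction` (default 0.01). Files cycle
through the three encodings and both compression modes. Exact per-base
truth arrays (NaN at uncovered bases) are returned with the files and
are the oracle for the core agreement tests. Not modelled, hence not
demonstrated by passing tests: real assay statistics such as
fragment-length effects, GC bias, or correlated signal across files.

## Numerical and degenerate-input notes

Values survive the writer/reader loop bitwise because they are stored
and compared as float32 throughout. Empty batches yield `(0, F, 0)`
tensors; empty region tables yield empty region sets; a chromosome with
no records simply returns fill. The uniformity acceptance check uses
4σ binomial bounds at 50,000 draws — wide enough that a correct sampler
fails with probability ≪ 10⁻³ across the tested starts. Benchmark
numbers from the CLI are machine-dependent throughput estimates and are
never treated as correctness values.
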
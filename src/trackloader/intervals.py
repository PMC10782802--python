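"""Genomic interval primitives shared across the package.

All coordinates in this package are 0-based, half-open ``[start, end)``,
matching the BigWig container convention.  Chromosome names are matched
exactly (no ``chr`` prefix normalisation); a name mismatch between files
is always surfaced as an error rather than silently aliased.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored 0-based half-open coordinate pair."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end}) "
                f"on {self.chrom}"
            )
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"
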
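"""Strand-aware genomic intervals.

All coordinates in the package are 0-based, half-open ``[start, end)``.
Conversion from 1-based closed conventions (GTF, VCF) happens only at
I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A genomic span on one strand.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; must satisfy ``end > start``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Transcription-direction 5' boundary coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """Transcription-direction 3' boundary coordinate."""
        return self.end if self.strand == "+" else self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True iff the two spans share >= 1 nt on the same chromosome.

        Bookended intervals sharing only a boundary coordinate do not
        overlap under half-open semantics.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"
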
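"""Shared domain types.

All coordinates are 0-based half-open throughout the package; conversion to
1-based inclusive happens only at the GFF3/reporting boundary (see
:mod:`ervkit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUC_ALPHABET = frozenset("ACGTN")

__all__ = ["NucSequence", "GenomicInterval", "HitRecord", "NUC_ALPHABET"]


@dataclass(frozen=True)
class NucSequence:
    """An identified nucleotide sequence over the alphabet {A, C, G, T, N}.

    Parameters
    ----------
    id :
        Sequence identifier, unique within any collection it belongs to.
    residues :
        Non-empty uppercase nucleotide string.
    description :
        Optional free-text description (FASTA header remainder).
    """

    id: str
    residues: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int, new_id: str | None = None) -> "NucSequence":
        """Extract residues[start:end] as a new sequence (0-based half-open)."""
        if not (0 <= start < end <= len(self.residues)):
            raise ValueError(
                f"invalid slice [{start}, {end}) on sequence {self.id!r} "
                f"of length {len(self.residues)}"
            )
        return NucSequence(
            id=new_id or f"{self.id}:{start}-{end}",
            residues=self.residues[start:end],
        )

    def reverse_complement(self, new_id: str | None = None) -> "NucSequence":
        comp = str.maketrans("ACGTN", "TGCAN")
        return NucSequence(
            id=new_id or f"{self.id}_rc",
            residues=self.residues.translate(comp)[::-1],
            description=self.description,
        )


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval on a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Smaller of the two overlap fractions; 0 when disjoint."""
        if not self.overlaps(other):
            return 0.0
        ov = min(self.end, other.end) - max(self.start, other.start)
        return min(ov / len(self), ov / len(other))

    def slice(self, seq: NucSequence) -> str:
        if seq.id != self.contig_id:
            raise ValueError(
                f"interval on {self.contig_id!r} applied to sequence {seq.id!r}"
            )
        if self.end > len(seq):
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds contig length {len(seq)}"
            )
        return seq.residues[self.start : self.end]


@dataclass(frozen=True)
class HitRecord:
    """One row of a generic homology-hit table (BLAST-like tabular output)."""

    query_id: str
    subject_id: str
    identity: float  # percent, 0-100
    coverage: float  # percent, 0-100
    e_value: float
    species: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity out of [0, 100]: {self.identity}")
        if not (0.0 <= self.coverage <= 100.0):
            raise ValueError(f"coverage out of [0, 100]: {self.coverage}")
        if self.e_value < 0:
            raise ValueError(f"negative e-value: {self.e_value}")
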
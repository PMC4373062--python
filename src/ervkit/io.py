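"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython's SeqIO; GFF3 and the tabular formats are simple
enough to emit directly.  Internal coordinates are 0-based half-open and gain
+1 on the start (only) when crossing the GFF3 boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import NUC_ALPHABET, HitRecord, NucSequence

if TYPE_CHECKING:  # pragma: no cover
    from .detect import ProvirusCall

logger = logging.getLogger(__name__)

__all__ = [
    "FastaError",
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_hits_tsv",
    "write_hits_tsv",
]


class FastaError(ValueError):
    """Malformed or unusable FASTA input."""


def _normalize_residues(raw: str, seq_id: str) -> str:
    """Uppercase, map U->T, collapse anything else outside {A,C,G,T,N} to N."""
    up = raw.upper().replace("U", "T")
    if set(up) <= NUC_ALPHABET:
        return up
    bad = sorted(set(up) - NUC_ALPHABET)
    logger.warning(
        "sequence %s: %d non-{A,C,G,T,N} characters (%s) mapped to N",
        seq_id,
        sum(up.count(c) for c in bad),
        ",".join(bad),
    )
    table = str.maketrans({c: "N" for c in bad})
    return up.translate(table)


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file into a list of :class:`NucSequence`.

    Residues are uppercased, U is mapped to T and any other character outside
    {A,C,G,T,N} is mapped to N with a logged warning.

    Raises
    ------
    FastaError
        If the file holds no records, contains a duplicate id, or contains a
        zero-length record.
    """
    path = Path(path)
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise FastaError(f"{path}: zero-length record {rec.id!r}")
        desc = rec.description[len(rec.id) :].strip() or None
        records.append(
            NucSequence(id=rec.id, residues=_normalize_residues(raw, rec.id), description=desc)
        )
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[NucSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences to FASTA, wrapped at ``width`` columns.

    ``read_fasta(write_fasta(x)) == x`` up to line wrapping.
    """
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    path = Path(path)
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def _gff3_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(
    calls: Iterable["ProvirusCall"],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write provirus calls as GFF3: one parent feature per provirus with
    child features for each LTR and each internal ORF.

    Internal 0-based half-open intervals become 1-based inclusive GFF3 spans
    (start+1, end).  An empty call list yields a valid header-only file.
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    for n, call in enumerate(calls, start=1):
        contig = call.ltr_pair.left.contig_id
        if contig_lengths is not None:
            clen = contig_lengths.get(contig)
            if clen is not None and call.ltr_pair.right.end > clen:
                raise ValueError(
                    f"call on {contig} ends at {call.ltr_pair.right.end} "
                    f"past contig length {clen}"
                )
        pid = f"provirus{n:03d}"
        span = (call.ltr_pair.left.start, call.ltr_pair.right.end)
        strand = call.strand
        attrs = (
            f"ID={pid};ltr_divergence={call.divergence.value:.6g};"
            f"ltr_identity={call.ltr_pair.identity:.4f}"
        )
        lines.append(
            "\t".join(
                [contig, "ervkit", "provirus", str(span[0] + 1), str(span[1]), ".",
                 strand, ".", attrs]
            )
        )
        for tag, iv in (("five_prime_LTR", call.ltr_pair.left), ("three_prime_LTR", call.ltr_pair.right)):
            lines.append(
                "\t".join(
                    [contig, "ervkit", "long_terminal_repeat", str(iv.start + 1),
                     str(iv.end), ".", strand, ".",
                     f"ID={pid}.{tag};Parent={pid};Name={_gff3_escape(tag)}"]
                )
            )
        for k, orf in enumerate(call.orfs, start=1):
            lines.append(
                "\t".join(
                    [contig, "ervkit", "open_reading_frame", str(orf.start + 1),
                     str(orf.end), ".", orf.strand, ".",
                     f"ID={pid}.orf{k};Parent={pid}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


_HIT_COLUMNS = ["query_id", "subject_id", "identity", "coverage", "e_value", "species"]


def read_hits_tsv(path: str | Path) -> list[HitRecord]:
    """Read a homology-hit table (TSV with a header row).

    Malformed rows are reported with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing hit-table columns {missing}")
    hits: list[HitRecord] = []
    for i, row in df.iterrows():
        lineno = int(i) + 2  # header is line 1
        try:
            hits.append(
                HitRecord(
                    query_id=str(row["query_id"]),
                    subject_id=str(row["subject_id"]),
                    identity=float(row["identity"]),
                    coverage=float(row["coverage"]),
                    e_value=float(row["e_value"]),
                    species=str(row["species"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed hit row at line {lineno}: {exc}") from exc
    return hits


def write_hits_tsv(hits: Sequence[HitRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(h) for h in hits], columns=_HIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
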
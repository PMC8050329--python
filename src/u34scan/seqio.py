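"""Sequence and table I/O for the U34 target-prediction pipeline.

Reads and validates the two sequence inputs the pipeline consumes — coding
sequences (CDS) and protein sequences, both FASTA — plus the tab-separated
result tables that carry differential-expression labels and secondary-structure
annotations. All coordinates in the package are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGT")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

SeqKind = Literal["nucleotide", "protein"]


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence (nucleotide or amino-acid)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("sequence id must be non-empty")
        if not self.seq:
            raise SequenceValidationError(f"{self.id}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CodingSequence:
    """One gene's CDS with its codon decomposition.

    The unit of all codon statistics: ``codons`` is the in-frame list of
    3-mers whose concatenation is ``nt``.
    """

    gene_id: str
    nt: str
    codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        nt = self.nt.upper()
        if len(nt) % 3 != 0 or len(nt) < 6:
            raise SequenceValidationError(
                f"{self.gene_id}: CDS length {len(nt)} is not a multiple of 3 >= 6"
            )
        bad = set(nt) - NUCLEOTIDES
        if bad:
            raise SequenceValidationError(
                f"{self.gene_id}: disallowed nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "nt", nt)
        object.__setattr__(
            self, "codons", tuple(nt[i : i + 3] for i in range(0, len(nt), 3))
        )

    @property
    def ends_in_stop(self) -> bool:
        return self.codons[-1] in STOP_CODONS


def _validate_alphabet(rec_id: str, seq: str, kind: SeqKind) -> None:
    alphabet = NUCLEOTIDES if kind == "nucleotide" else AMINO_ACIDS
    bad = set(seq) - alphabet
    if bad:
        raise SequenceValidationError(
            f"{rec_id}: characters {sorted(bad)} not allowed for kind={kind!r}"
        )


def read_fasta(path: str | Path, kind: SeqKind = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the record id; file
    order is preserved. Wrapped and single-line FASTA are both accepted.
    An empty file yields an empty list.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with path.open() as handle:
        # reject leading junk before the first header, which SeqIO silently skips
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                )
            break
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        _validate_alphabet(rec.id, seq, kind)
        records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    """Read an orfeome FASTA, dropping records that fail CDS validation.

    Records with ambiguity codes (N etc.), lengths not a multiple of 3, or
    other alphabet violations are excluded with a logged warning rather than
    guessed at: codon frequencies must be exact counts. A CDS not ending in a
    stop codon is accepted with a warning.
    """
    path = Path(path)
    out: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            cds = CodingSequence(gene_id=rec.id, nt=seq)
        except SequenceValidationError as exc:
            logger.warning("excluding CDS %s from orfeome: %s", rec.id, exc)
            continue
        if not cds.ends_in_stop:
            logger.warning("CDS %s does not end in a stop codon; all codons counted", rec.id)
        out.append(cds)
    return out


def translate_cds(cds: CodingSequence) -> str:
    """Translate under the standard genetic code.

    The terminal stop codon is not emitted; an internal stop raises.
    """
    coding = cds.codons[:-1] if cds.ends_in_stop else cds.codons
    for i, codon in enumerate(coding):
        if codon in STOP_CODONS:
            raise SequenceValidationError(
                f"{cds.gene_id}: internal stop codon {codon} at codon index {i}"
            )
    return str(Seq("".join(coding)).translate())


def read_table(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    """Read a tab-separated table with a header row.

    Raises ``ValueError`` naming any missing required column.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV with header; round-trip stable with read_table."""
    df.to_csv(path, sep="\t", index=False)
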
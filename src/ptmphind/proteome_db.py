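"""Parse proteome FASTA databases into a flat (Protein_ID, Sequence) table.

Shotgun-proteomics search engines report peptide hits against an accession
taken from the search database header.  Before modified peptides can be
mapped back onto full-length proteins, the database has to be reduced to a
two-column table keyed by exactly that accession.  This module handles the
two common header dialects (UniProt ``>sp|ACC|NAME`` / ``>tr|ACC|NAME`` and
RefSeq/``custom`` first-token headers), optionally drops decoy ("reverse")
and contaminant entries that search engines append for FDR estimation, and
round-trips the parsed table through a tab-delimited text file.
"""

from __future__ import annotations

import os
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import IO, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "DatabaseError",
    "ProteinRecord",
    "ParsedProteome",
    "parse_fasta_db",
    "write_parsed_db",
    "read_parsed_db",
    "DIALECTS",
    "DEFAULT_FILTER_PREFIXES",
]

DIALECTS = ("uniprot", "refseq", "custom")

#: Header-token prefixes dropped when filtering is on.  Matched
#: case-insensitively against the raw first token of the FASTA header,
#: before any dialect-specific accession extraction, so "Reverse_sp|..."
#: and "CONTAMINANT_P12345" variants are all caught.
DEFAULT_FILTER_PREFIXES = ("reverse", "contaminant")

PARSED_DB_COLUMNS = ("Protein_ID", "Sequence")


class DatabaseError(ValueError):
    """A proteome database violates the parsing contract (hard error)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: accession token plus full amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id or any(c.isspace() for c in self.protein_id):
            raise DatabaseError(
                f"invalid protein ID {self.protein_id!r}: must be a non-empty "
                "token without whitespace"
            )
        if not self.sequence:
            raise DatabaseError(f"protein {self.protein_id!r} has an empty sequence")


@dataclass
class ParsedProteome:
    """Ordered collection of :class:`ProteinRecord` with unique accessions."""

    records: list[ProteinRecord]
    source_dialect: str = "custom"
    _index: dict[str, ProteinRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.protein_id in index:
                raise DatabaseError(f"duplicate protein ID {rec.protein_id!r}")
            index[rec.protein_id] = rec
        self._index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParsedProteome):
            return NotImplemented
        return self.records == other.records

    def get(self, protein_id: str) -> ProteinRecord | None:
        """Return the record for ``protein_id``, or None when absent."""
        return self._index.get(protein_id)

    @property
    def ids(self) -> list[str]:
        return [rec.protein_id for rec in self.records]


@contextmanager
def _as_text_handle(source: str | os.PathLike | IO[str], mode: str) -> Iterator[IO[str]]:
    """Yield a text handle for a path or pass an open stream through."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, mode, encoding="utf-8", newline="") as handle:
            yield handle
    else:
        yield source


def _extract_id(raw_token: str, db_source: str) -> str:
    if db_source == "uniprot":
        parts = raw_token.split("|")
        # ">sp|ACC|NAME" and ">tr|ACC|NAME" carry the accession in the
        # middle field; anything without two pipes falls back to the token.
        if len(parts) >= 3 and parts[1]:
            return parts[1]
    return raw_token


def parse_fasta_db(
    fasta: str | os.PathLike | IO[str],
    db_source: str = "uniprot",
    filt: bool = False,
    filter_prefixes: Sequence[str] = DEFAULT_FILTER_PREFIXES,
) -> ParsedProteome:
    """Parse a FASTA proteome into a :class:`ParsedProteome`.

    Parameters
    ----------
    fasta
        Path to a FASTA file, or an open text stream.  Multi-line sequences
        and CRLF line endings are accepted.
    db_source
        Header dialect: ``uniprot`` (accession = second ``|`` field),
        ``refseq`` or ``custom`` (accession = first whitespace token).
    filt
        When True, drop entries whose raw header token starts
        (case-insensitively) with any of ``filter_prefixes`` — decoy
        ("reverse") and contaminant entries by default.
    filter_prefixes
        Prefixes used by the filter; override for search engines that tag
        decoys differently (e.g. ``rev_``).

    Raises
    ------
    DatabaseError
        Empty database, duplicate accession, entry without sequence lines,
        or an internal ``*`` in a sequence.  Terminal ``*`` stop characters
        are stripped silently.
    """
    if db_source not in DIALECTS:
        raise DatabaseError(
            f"unknown db_source {db_source!r}; expected one of {DIALECTS}"
        )
    prefixes = tuple(p.lower() for p in filter_prefixes)

    records: list[ProteinRecord] = []
    n_entries = 0
    with _as_text_handle(fasta, "r") as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            n_entries += 1
            raw_token = entry.id
            if filt and raw_token.lower().startswith(prefixes):
                continue
            sequence = str(entry.seq).upper().strip("*")
            if not sequence:
                raise DatabaseError(
                    f"entry {raw_token!r} has a header but no sequence lines"
                )
            if "*" in sequence:
                raise DatabaseError(
                    f"entry {raw_token!r} contains an internal stop character '*'"
                )
            records.append(ProteinRecord(_extract_id(raw_token, db_source), sequence))

    if n_entries == 0:
        raise DatabaseError("empty database: no FASTA entries found")
    return ParsedProteome(records, source_dialect=db_source)


def write_parsed_db(proteome: ParsedProteome, out: str | os.PathLike | IO[str]) -> None:
    """Write the two-column tab-delimited parsed-database table."""
    with _as_text_handle(out, "w") as handle:
        handle.write("\t".join(PARSED_DB_COLUMNS) + "\n")
        for rec in proteome:
            handle.write(f"{rec.protein_id}\t{rec.sequence}\n")


def read_parsed_db(source: str | os.PathLike | IO[str]) -> ParsedProteome:
    """Read a table written by :func:`write_parsed_db`.

    The dialect of the original FASTA is not recorded in the table, so the
    result always carries ``source_dialect="custom"``.
    """
    with _as_text_handle(source, "r") as handle:
        lines = handle.read().splitlines()
    if not lines:
        raise DatabaseError("empty parsed-database file")
    header = tuple(lines[0].rstrip("\r").split("\t"))
    if header != PARSED_DB_COLUMNS:
        raise DatabaseError(
            f"bad parsed-database header {lines[0]!r}; expected "
            f"{chr(9).join(PARSED_DB_COLUMNS)!r}"
        )
    records: list[ProteinRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise DatabaseError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        records.append(ProteinRecord(fields[0], fields[1]))
    return ParsedProteome(records, source_dialect="custom")
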
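"""Resolve PTM sites on experimental peptides and map them onto proteins.

Search engines report a modified peptide together with candidate
modification positions and per-residue localization scores (ptmRS-style
probabilities on a 0-100 scale).  The pipeline implemented here takes one
such row at a time and

1. parses the ``;``-separated candidate-site and score fields,
2. selects the ``Total_Sites`` best-scoring candidates,
3. finds every occurrence of the peptide in its named protein,
4. converts peptide coordinates to 1-based protein coordinates, and
5. extracts a fixed-width flanking window (2*w+1 residues, ``_``-padded
   past the sequence ends) around each mapped site.

Ambiguity is reported per row as a three-level flag:

``none``
    unique peptide occurrence, clean score-based selection;
``site``
    the selection was uncertain — a score tie across the selection
    boundary, or a chosen score below the score floor;
``position``
    the peptide occurs more than once in the protein (dominates ``site``);
    every occurrence is mapped and reported.

Row-level problems (unknown protein, peptide absent from the protein,
malformed fields) become per-row statuses; they never abort a batch.
"""

from __future__ import annotations

import csv
import os
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .proteome_db import ParsedProteome, _as_text_handle

__all__ = [
    "MalformedRowError",
    "SiteCandidate",
    "ModifiedPeptideInput",
    "LocalizedSite",
    "LocalizationRow",
    "parse_site_string",
    "resolve_sites",
    "find_peptide_occurrences",
    "extract_flank",
    "phind_ptms",
    "read_modified_peptides",
    "write_localization_table",
    "read_localization_table",
    "INPUT_COLUMNS",
    "OUTPUT_COLUMNS",
    "DEFAULT_HALF_WIDTH",
    "DEFAULT_PAD",
    "DEFAULT_SCORE_FLOOR",
]

INPUT_COLUMNS = (
    "Identifier",
    "Protein_ID",
    "Peptide_Seq",
    "Total_Sites",
    "PTM_Loc",
    "PTM_Score",
)

OUTPUT_COLUMNS = (
    "Identifier",
    "Protein_ID",
    "Pep_Loc",
    "Prot_Loc",
    "PTM_Score",
    "Flank_Seq",
    "Ambiguity",
    "Prot_Seq",
    "Status",
)

DEFAULT_HALF_WIDTH = 7  # 15-mer windows, the usual motif-analysis width
DEFAULT_PAD = "_"
DEFAULT_SCORE_FLOOR = 75.0  # on the ptmRS-style 0-100 probability scale

STATUS_OK = "ok"
STATUS_PROTEIN_NOT_FOUND = "protein_not_found"
STATUS_PEPTIDE_NOT_FOUND = "peptide_not_found"
STATUS_MALFORMED = "malformed"


class MalformedRowError(ValueError):
    """An experimental input row violates the schema (degrades to a status)."""


@dataclass(frozen=True)
class SiteCandidate:
    """One candidate modification site on a peptide.

    ``pep_pos`` is 1-based within the peptide.  ``residue`` is the annotated
    amino acid when the ``S5``-style token form was used, None for the bare
    integer form.
    """

    pep_pos: int
    score: float
    residue: str | None = None


@dataclass
class ModifiedPeptideInput:
    """One row of the six-column modified-peptide input table.

    ``ptm_loc`` / ``ptm_score`` hold the raw ``;``-separated field text;
    candidate parsing happens during localization so a bad field degrades
    to a per-row status instead of failing the whole table.  ``error`` is
    set by the reader for schema-level problems it already detected.
    """

    identifier: str
    protein_id: str
    peptide_seq: str
    total_sites: int
    ptm_loc: str
    ptm_score: str
    error: str | None = None


@dataclass(frozen=True)
class LocalizedSite:
    """A single site resolved to peptide and protein coordinates."""

    pep_loc: int
    prot_loc: int
    score: float
    flank_seq: str


@dataclass
class LocalizationRow:
    """One output row: ``;``-joined per-site lists plus row-level flags.

    ``message`` carries diagnostic detail for non-ok rows; it is logged,
    not serialized (the output table has exactly the nine public columns).
    """

    identifier: str
    protein_id: str
    pep_loc: str = ""
    prot_loc: str = ""
    ptm_score: str = ""
    flank_seq: str = ""
    ambiguity: str = ""
    prot_seq: str = ""
    status: str = STATUS_OK
    message: str = field(default="", compare=False)

    def as_record(self) -> list[str]:
        return [
            self.identifier,
            self.protein_id,
            self.pep_loc,
            self.prot_loc,
            self.ptm_score,
            self.flank_seq,
            self.ambiguity,
            self.prot_seq,
            self.status,
        ]


# ---------------------------------------------------------------------------
# 1. candidate-field parsing

_SITE_TOKEN_RE = re.compile(r"^([A-Za-z]?)(\d+)$")


def parse_site_string(
    ptm_loc_field: str, ptm_score_field: str, peptide_seq: str
) -> list[SiteCandidate]:
    """Parse parallel ``;``-separated location and score fields.

    Location tokens are either bare 1-based integers (``"5"``) or a residue
    letter plus position (``"S5"``); annotated residues are checked against
    ``peptide_seq``.  Scores pair positionally with locations.

    Raises
    ------
    MalformedRowError
        Empty field, unequal list lengths, unparsable token, position out
        of peptide range, or residue letter disagreeing with the peptide.
    """
    if not str(ptm_loc_field).strip() or not str(ptm_score_field).strip():
        raise MalformedRowError("empty PTM_Loc or PTM_Score field")
    loc_tokens = [t.strip() for t in str(ptm_loc_field).split(";")]
    score_tokens = [t.strip() for t in str(ptm_score_field).split(";")]
    if len(loc_tokens) != len(score_tokens):
        raise MalformedRowError(
            f"{len(loc_tokens)} PTM_Loc entries but {len(score_tokens)} PTM_Score entries"
        )
    candidates: list[SiteCandidate] = []
    for loc_tok, score_tok in zip(loc_tokens, score_tokens):
        m = _SITE_TOKEN_RE.match(loc_tok)
        if m is None:
            raise MalformedRowError(f"unparsable PTM_Loc token {loc_tok!r}")
        residue = m.group(1).upper() or None
        pep_pos = int(m.group(2))
        if not 1 <= pep_pos <= len(peptide_seq):
            raise MalformedRowError(
                f"PTM_Loc token {loc_tok!r}: position outside peptide of length "
                f"{len(peptide_seq)}"
            )
        if residue is not None and peptide_seq[pep_pos - 1] != residue:
            raise MalformedRowError(
                f"PTM_Loc token {loc_tok!r}: peptide has "
                f"{peptide_seq[pep_pos - 1]!r} at position {pep_pos}"
            )
        try:
            score = float(score_tok)
        except ValueError:
            raise MalformedRowError(f"non-numeric PTM_Score token {score_tok!r}") from None
        candidates.append(SiteCandidate(pep_pos, score, residue))
    return candidates


# ---------------------------------------------------------------------------
# 2. site selection


def resolve_sites(
    candidates: Sequence[SiteCandidate],
    total_sites: int,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> tuple[list[SiteCandidate], bool]:
    """Select the ``total_sites`` best-scoring candidates.

    Ties are broken toward the lower peptide position, the usual reading of
    ptmRS output where the first-listed isoform is preferred.  The returned
    list is in ascending peptide-position order.

    The boolean flags site-level ambiguity: a score tie straddling the
    selection boundary, or any chosen score below ``score_floor``.
    """
    if not 1 <= total_sites <= len(candidates):
        raise MalformedRowError(
            f"Total_Sites={total_sites} but {len(candidates)} candidate site(s)"
        )
    ranked = sorted(candidates, key=lambda c: (-c.score, c.pep_pos))
    chosen, rejected = ranked[:total_sites], ranked[total_sites:]
    ambiguous = bool(rejected) and chosen[-1].score == rejected[0].score
    ambiguous = ambiguous or any(c.score < score_floor for c in chosen)
    return sorted(chosen, key=lambda c: c.pep_pos), ambiguous


# ---------------------------------------------------------------------------
# 3. peptide search


def find_peptide_occurrences(peptide_seq: str, protein_seq: str) -> list[int]:
    """All 1-based start positions of ``peptide_seq`` in ``protein_seq``.

    Overlapping occurrences are included; matching is exact on characters
    (no I/L equivalence).  An empty result is a valid outcome.
    """
    if not peptide_seq or not protein_seq:
        raise ValueError("peptide and protein sequences must be non-empty")
    starts: list[int] = []
    pos = protein_seq.find(peptide_seq)
    while pos != -1:
        starts.append(pos + 1)
        pos = protein_seq.find(peptide_seq, pos + 1)
    return starts


# ---------------------------------------------------------------------------
# 4. flanking-window extraction


def extract_flank(
    protein_seq: str, prot_loc: int, w: int = DEFAULT_HALF_WIDTH, pad: str = DEFAULT_PAD
) -> str:
    """Fixed-width window of 2*w+1 residues centered on ``prot_loc``.

    Positions falling outside the protein are replaced by ``pad``, so
    N- and C-terminal sites still yield full-width windows.
    """
    n = len(protein_seq)
    if not 1 <= prot_loc <= n:
        raise ValueError(f"prot_loc {prot_loc} outside protein of length {n}")
    if w < 1:
        raise ValueError("half-width w must be >= 1")
    return "".join(
        protein_seq[i - 1] if 1 <= i <= n else pad
        for i in range(prot_loc - w, prot_loc + w + 1)
    )


# ---------------------------------------------------------------------------
# 5. the batch driver


def _format_score(score: float) -> str:
    return format(score, "g")


def _localize_row(
    row: ModifiedPeptideInput,
    proteome: ParsedProteome,
    w: int,
    pad: str,
    score_floor: float,
    drop_truncated: bool,
) -> LocalizationRow:
    out = LocalizationRow(identifier=row.identifier, protein_id=row.protein_id)
    if row.error:
        out.status, out.message = STATUS_MALFORMED, row.error
        return out

    record = proteome.get(row.protein_id)
    if record is None:
        out.status = STATUS_PROTEIN_NOT_FOUND
        out.message = f"protein {row.protein_id!r} not in parsed database"
        return out

    try:
        if not row.peptide_seq:
            raise MalformedRowError("empty Peptide_Seq")
        candidates = parse_site_string(row.ptm_loc, row.ptm_score, row.peptide_seq)
        chosen, site_ambiguous = resolve_sites(candidates, row.total_sites, score_floor)
    except MalformedRowError as exc:
        out.status, out.message = STATUS_MALFORMED, str(exc)
        return out

    occurrences = find_peptide_occurrences(row.peptide_seq, record.sequence)
    if not occurrences:
        out.status = STATUS_PEPTIDE_NOT_FOUND
        out.prot_seq = record.sequence
        out.message = f"peptide not found in protein {row.protein_id!r}"
        return out

    sites: list[LocalizedSite] = []
    for start in occurrences:  # ascending; grouped per occurrence
        for cand in chosen:  # ascending pep_pos within each occurrence
            prot_loc = start + cand.pep_pos - 1
            flank = extract_flank(record.sequence, prot_loc, w, pad)
            if drop_truncated and pad in flank:
                continue
            sites.append(LocalizedSite(cand.pep_pos, prot_loc, cand.score, flank))

    if len(occurrences) > 1:
        out.ambiguity = "position"
    elif site_ambiguous:
        out.ambiguity = "site"
    else:
        out.ambiguity = "none"
    out.pep_loc = ";".join(str(s.pep_loc) for s in sites)
    out.prot_loc = ";".join(str(s.prot_loc) for s in sites)
    out.ptm_score = ";".join(_format_score(s.score) for s in sites)
    out.flank_seq = ";".join(s.flank_seq for s in sites)
    out.prot_seq = record.sequence
    return out


def phind_ptms(
    inputs: Iterable[ModifiedPeptideInput],
    proteome: ParsedProteome,
    w: int = DEFAULT_HALF_WIDTH,
    pad: str = DEFAULT_PAD,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    drop_truncated: bool = False,
) -> list[LocalizationRow]:
    """Localize every input row against the parsed proteome.

    Returns one :class:`LocalizationRow` per input row, in input order.
    Per-row failures become statuses (``protein_not_found``,
    ``peptide_not_found``, ``malformed``); no row aborts the batch.  When a
    peptide occurs at several positions, all mappings are reported
    (``;``-joined, grouped by occurrence in ascending start order) and the
    row is flagged ``position``-ambiguous.

    ``drop_truncated`` omits site mappings whose window would touch a
    sequence boundary instead of padding them; the four per-site lists stay
    parallel.
    """
    return [
        _localize_row(row, proteome, w, pad, score_floor, drop_truncated)
        for row in inputs
    ]


# ---------------------------------------------------------------------------
# table I/O


def _sniff_delimiter(sample: str) -> str:
    # ';' is the in-field multi-site separator, so only ',' and TAB are
    # candidate column delimiters.
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_modified_peptides(
    source: str | os.PathLike | IO[str], delimiter: str | None = None
) -> list[ModifiedPeptideInput]:
    """Read the six-column modified-peptide table (CSV or TSV).

    The header must spell the six column names exactly
    (``Identifier,Protein_ID,Peptide_Seq,Total_Sites,PTM_Loc,PTM_Score``);
    anything else is a hard error.  Row-level schema problems (wrong field
    count, non-integer Total_Sites, duplicated Identifier) are recorded on
    the row and surface later as ``malformed`` statuses.
    """
    with _as_text_handle(source, "r") as handle:
        text = handle.read()
    if not text.strip():
        raise MalformedRowError("empty input table")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])
    reader = csv.reader(text.lstrip("﻿").splitlines(), delimiter=delimiter)
    header = tuple(h.strip() for h in next(reader))
    if header != INPUT_COLUMNS:
        raise MalformedRowError(
            f"bad input header {list(header)}; the six columns must be spelled "
            f"exactly {list(INPUT_COLUMNS)}"
        )
    rows: list[ModifiedPeptideInput] = []
    seen: set[str] = set()
    for lineno, fields in enumerate(reader, start=2):
        if not fields or all(not f.strip() for f in fields):
            continue
        if len(fields) != len(INPUT_COLUMNS):
            rows.append(
                ModifiedPeptideInput(
                    identifier=fields[0].strip() if fields else f"line{lineno}",
                    protein_id="",
                    peptide_seq="",
                    total_sites=0,
                    ptm_loc="",
                    ptm_score="",
                    error=f"line {lineno}: expected 6 fields, got {len(fields)}",
                )
            )
            continue
        identifier, protein_id, peptide_seq, total_sites_raw, ptm_loc, ptm_score = (
            f.strip() for f in fields
        )
        error: str | None = None
        try:
            total_sites = int(total_sites_raw)
        except ValueError:
            total_sites = 0
            error = f"line {lineno}: non-integer Total_Sites {total_sites_raw!r}"
        if identifier in seen:
            error = f"line {lineno}: duplicate Identifier {identifier!r}"
        seen.add(identifier)
        rows.append(
            ModifiedPeptideInput(
                identifier=identifier,
                protein_id=protein_id,
                peptide_seq=peptide_seq.upper(),
                total_sites=total_sites,
                ptm_loc=ptm_loc,
                ptm_score=ptm_score,
                error=error,
            )
        )
    return rows


def write_localization_table(
    rows: Iterable[LocalizationRow], out: str | os.PathLike | IO[str]
) -> None:
    """Write the nine-column localization CSV (RFC 4180 quoting)."""
    with _as_text_handle(out, "w") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(OUTPUT_COLUMNS)
        for row in rows:
            writer.writerow(row.as_record())


def read_localization_table(
    source: str | os.PathLike | IO[str],
) -> list[LocalizationRow]:
    """Read a CSV written by :func:`write_localization_table`."""
    with _as_text_handle(source, "r") as handle:
        reader = csv.reader(handle.read().splitlines())
    try:
        header = tuple(next(iter(reader)))
    except StopIteration:
        raise MalformedRowError("empty localization table") from None
    rows: list[LocalizationRow] = []
    if header != OUTPUT_COLUMNS:
        raise MalformedRowError(
            f"bad localization header {list(header)}; expected {list(OUTPUT_COLUMNS)}"
        )
    for lineno, fields in enumerate(reader, start=2):
        if not fields or all(not f for f in fields):
            continue
        if len(fields) != len(OUTPUT_COLUMNS):
            raise MalformedRowError(
                f"line {lineno}: expected {len(OUTPUT_COLUMNS)} fields, got {len(fields)}"
            )
        rows.append(LocalizationRow(*fields))
    return rows
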
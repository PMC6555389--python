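"""Bridge localization output to motif-enrichment tools.

Tools in the motif-x family take a "pre-aligned" foreground — equal-width
sequences with the modified residue at the center — plus a background list.
This module flattens the ``;``-joined ``Flank_Seq`` fields of successful
localization rows into such a list, filtered to one central residue at a
time (enrichment is computed per center), with optional ambiguity-based
row exclusion and exact-string deduplication.
"""

from __future__ import annotations

import os
from typing import IO, Iterable, Sequence

from .proteome_db import _as_text_handle
from .ptm_localization import STATUS_OK, LocalizationRow

__all__ = ["foreground_from_rows", "write_sequence_list", "AMBIGUITY_POLICIES"]

#: keep_all passes every ok row through; drop_position removes rows whose
#: peptide matched multiple protein positions; drop_all also removes rows
#: with uncertain site selection.
AMBIGUITY_POLICIES = ("keep_all", "drop_position", "drop_all")


def foreground_from_rows(
    rows: Iterable[LocalizationRow],
    central_char: str = "any",
    exclude_ambiguous: str = "keep_all",
    dedup: bool = False,
) -> list[str]:
    """Flatten Flank_Seq windows from status=ok rows into a foreground list.

    ``central_char`` keeps only windows with that residue at the center
    (``"any"`` disables the filter).  All windows must share one odd
    length — mixing extraction widths is an error.  Order is preserved;
    ``dedup`` keeps the first occurrence of each distinct window.
    """
    if exclude_ambiguous not in AMBIGUITY_POLICIES:
        raise ValueError(
            f"exclude_ambiguous must be one of {AMBIGUITY_POLICIES}, "
            f"got {exclude_ambiguous!r}"
        )
    flattened: list[str] = []
    for row in rows:
        if row.status != STATUS_OK:
            continue
        if exclude_ambiguous == "drop_position" and row.ambiguity == "position":
            continue
        if exclude_ambiguous == "drop_all" and row.ambiguity != "none":
            continue
        if row.flank_seq:
            flattened.extend(row.flank_seq.split(";"))

    lengths = {len(w) for w in flattened}
    if len(lengths) > 1:
        raise ValueError(
            f"inconsistent window lengths {sorted(lengths)}: rows were "
            "extracted with different widths"
        )
    if lengths and next(iter(lengths)) % 2 == 0:
        raise ValueError("windows must have odd length (a defined center)")

    if central_char != "any":
        if len(central_char) != 1:
            raise ValueError(f"central_char must be one letter or 'any', got {central_char!r}")
        center = central_char.upper()
        flattened = [w for w in flattened if w[len(w) // 2] == center]

    if dedup:
        seen: set[str] = set()
        unique: list[str] = []
        for w in flattened:
            if w not in seen:
                seen.add(w)
                unique.append(w)
        flattened = unique
    return flattened


def write_sequence_list(
    windows: Sequence[str], out: str | os.PathLike | IO[str]
) -> None:
    """One window per line, no header, newline-terminated."""
    if len({len(w) for w in windows}) > 1:
        raise ValueError("all windows in a sequence list must have equal length")
    with _as_text_handle(out, "w") as handle:
        for w in windows:
            handle.write(w + "\n")
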
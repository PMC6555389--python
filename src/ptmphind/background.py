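"""Proteome-specific background motif extraction.

Motif-enrichment statistics need a null set: the windows around *every*
occurrence of the central residue (S, T or Y for phosphorylation) across
the proteome that was actually searched.  Using another species' background
or a small random subset can distort enrichment, so the default here keeps
one window per occurrence — padded at sequence boundaries so the window
count equals the residue count exactly.  A drop-truncated mode omits
boundary windows for downstream tools that reject non-residue characters,
and a seeded subsampler produces fixed-size backgrounds for tools that
expect them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO

import numpy as np

from .proteome_db import ParsedProteome, _as_text_handle
from .ptm_localization import DEFAULT_HALF_WIDTH, DEFAULT_PAD, extract_flank

__all__ = ["BackgroundSet", "extract_background", "subsample_background", "write_background"]


@dataclass
class BackgroundSet:
    """All fixed-width windows centered on one residue across a proteome.

    ``provenance`` runs parallel to ``windows``: the (protein_id, 1-based
    protein position) each window was cut from.
    """

    central_char: str
    w: int
    windows: list[str] = field(default_factory=list)
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)


def extract_background(
    proteome: ParsedProteome,
    central_char: str,
    w: int = DEFAULT_HALF_WIDTH,
    pad: str = DEFAULT_PAD,
    drop_truncated: bool = False,
    dedup: bool = False,
) -> BackgroundSet:
    """Enumerate every window centered on ``central_char`` in the proteome.

    Proteins are visited in input order, positions ascending, one window
    per occurrence of the central residue, with the same padding semantics
    as :func:`~ptmphind.ptm_localization.extract_flank`.  With
    ``drop_truncated`` windows touching a sequence boundary are omitted;
    with ``dedup`` only the first occurrence of each distinct window string
    is kept (backgrounds are *not* deduplicated by default, so window
    frequencies reflect true occurrence counts).
    """
    if len(central_char) != 1 or not central_char.isalpha():
        raise ValueError(
            f"central_char must be a single letter, got {central_char!r}"
        )
    central = central_char.upper()
    bg = BackgroundSet(central_char=central, w=w)
    seen: set[str] = set()
    for record in proteome:
        seq = record.sequence
        for idx, residue in enumerate(seq):
            if residue != central:
                continue
            prot_loc = idx + 1
            window = extract_flank(seq, prot_loc, w, pad)
            if drop_truncated and pad in window:
                continue
            if dedup:
                if window in seen:
                    continue
                seen.add(window)
            bg.windows.append(window)
            bg.provenance.append((record.protein_id, prot_loc))
    return bg


def subsample_background(bg: BackgroundSet, n: int, seed: int) -> BackgroundSet:
    """Uniform sample of min(n, len) windows without replacement.

    Deterministic under ``seed``; the selected windows keep their original
    relative order and their provenance entries.
    """
    if n < 0:
        raise ValueError("subsample size must be >= 0")
    if n >= len(bg):
        return BackgroundSet(bg.central_char, bg.w, list(bg.windows), list(bg.provenance))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(bg), size=n, replace=False))
    return BackgroundSet(
        bg.central_char,
        bg.w,
        [bg.windows[i] for i in keep],
        [bg.provenance[i] for i in keep],
    )


def write_background(
    bg: BackgroundSet, out: str | os.PathLike | IO[str], with_provenance: bool = False
) -> None:
    """Write the background as a plain sequence list (one window per line).

    With ``with_provenance`` a 3-column TSV (protein_id, prot_loc, window)
    is written instead.
    """
    with _as_text_handle(out, "w") as handle:
        if with_provenance:
            handle.write("Protein_ID\tProt_Loc\tWindow\n")
            for (pid, loc), window in zip(bg.provenance, bg.windows):
                handle.write(f"{pid}\t{loc}\t{window}\n")
        else:
            for window in bg.windows:
                handle.write(window + "\n")
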
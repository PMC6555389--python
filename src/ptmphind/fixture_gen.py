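"""Synthetic proteomes and modified-peptide tables with known ground truth.

The generator emulates what a phospho-proteomics search pipeline hands to
the localization step: tryptic-like peptides (cut after K/R, 7-25 residues)
carrying modification sites on S/T/Y with ptmRS-style 0-100 localization
scores — confident true sites in [95, 100], optional low-scoring decoy
candidates in [0, 5], optional planted score ties for ambiguity testing.
Every generated row is paired with a ground-truth record (exact protein
position and 15-mer flank), so recovery by the localization pipeline can be
checked site by site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np

from .proteome_db import ParsedProteome, ProteinRecord, _as_text_handle
from .ptm_localization import (
    INPUT_COLUMNS,
    ModifiedPeptideInput,
    extract_flank,
    find_peptide_occurrences,
)

__all__ = [
    "GroundTruthSite",
    "generate_proteome",
    "generate_modified_peptides",
    "write_peptide_table",
    "write_truth_table",
    "AMINO_ACIDS",
    "TRUTH_COLUMNS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
TRUTH_COLUMNS = ("Identifier", "Protein_ID", "True_Prot_Loc", "Residue", "True_Flank")

_TRUTH_HALF_WIDTH = 7  # truth flanks are recorded at the default 15-mer width


@dataclass(frozen=True)
class GroundTruthSite:
    """One planted modification site with its exact protein coordinates."""

    identifier: str
    protein_id: str
    true_prot_loc: int
    true_flank: str
    residue: str


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 500),
    seed: int = 42,
    frequencies: Iterable[float] | None = None,
) -> ParsedProteome:
    """Random proteome with IDs SYN0001..., i.i.d. residues.

    Residues are drawn uniformly from the 20 standard amino acids unless a
    20-vector of ``frequencies`` (ordered as ``AMINO_ACIDS``) is given.
    Deterministic under ``seed``.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad length_range {length_range}")
    p = None
    if frequencies is not None:
        p = np.asarray(list(frequencies), dtype=float)
        if p.shape != (20,) or (p < 0).any() or p.sum() == 0:
            raise ValueError("frequencies must be 20 non-negative values")
        p = p / p.sum()
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=p))
        records.append(ProteinRecord(f"SYN{i + 1:04d}", seq))
    return ParsedProteome(records, source_dialect="custom")


def _tryptic_fragments(sequence: str) -> list[tuple[int, str]]:
    """(1-based start, fragment) pairs from cutting after every K/R."""
    cuts = [0] + [i + 1 for i, c in enumerate(sequence) if c in "KR"]
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    return [
        (cuts[i] + 1, sequence[cuts[i] : cuts[i + 1]])
        for i in range(len(cuts) - 1)
        if cuts[i + 1] > cuts[i]
    ]


def _repeated_kmers(
    record: ProteinRecord, modifiable: frozenset[str], kmin: int = 4, kmax: int = 6
) -> list[tuple[str, list[int]]]:
    """Substrings of length kmin..kmax occurring >=2 times and containing a
    modifiable residue; used to plant position-ambiguous peptides."""
    found: list[tuple[str, list[int]]] = []
    seq = record.sequence
    for k in range(kmin, kmax + 1):
        counts: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            counts.setdefault(seq[i : i + k], []).append(i + 1)
        for kmer, starts in sorted(counts.items()):
            if len(starts) >= 2 and any(c in modifiable for c in kmer):
                found.append((kmer, starts))
    return found


def generate_modified_peptides(
    proteome: ParsedProteome,
    n_peptides: int = 100,
    modifiable: str = "STY",
    sites_per_peptide_range: tuple[int, int] = (1, 3),
    decoy_candidate_rate: float = 0.3,
    ambiguous_fraction: float = 0.0,
    seed: int = 42,
    require_unique: bool = True,
    repeat_fraction: float = 0.0,
) -> tuple[list[ModifiedPeptideInput], list[GroundTruthSite]]:
    """Cut modified peptides from a proteome and record their ground truth.

    Each peptide is a tryptic-like fragment (after K/R, length 7-25) with at
    least one modifiable residue.  ``total_sites`` true sites get scores in
    [95, 100]; with probability ``decoy_candidate_rate`` extra candidate
    residues are added with scores in [0, 5]; with probability
    ``ambiguous_fraction`` a tied-score candidate is planted instead,
    producing a row the localizer must flag ``site``-ambiguous.  With
    ``require_unique`` only fragments occurring exactly once in their
    protein are used, so every true site maps back unambiguously.
    ``repeat_fraction`` rows instead use short substrings that occur at
    least twice in the protein (flagged ``position`` by the localizer).

    Returns the input rows (Table-style, ``S5``-form PTM_Loc tokens) and
    the parallel ground-truth records.  Deterministic under ``seed``.
    """
    mod_set = frozenset(modifiable.upper())
    if not mod_set:
        raise ValueError("modifiable residue set must be non-empty")
    if not any(c in mod_set for rec in proteome for c in rec.sequence):
        raise ValueError("proteome contains no modifiable residues")
    lo_sites, hi_sites = sites_per_peptide_range
    if not 1 <= lo_sites <= hi_sites:
        raise ValueError(f"bad sites_per_peptide_range {sites_per_peptide_range}")

    pool: list[tuple[ProteinRecord, int, str]] = []
    for rec in proteome:
        for start, frag in _tryptic_fragments(rec.sequence):
            if not 7 <= len(frag) <= 25:
                continue
            if not any(c in mod_set for c in frag):
                continue
            if require_unique and len(find_peptide_occurrences(frag, rec.sequence)) != 1:
                continue
            pool.append((rec, start, frag))
    if not pool:
        raise ValueError("no usable tryptic fragments in the proteome")

    repeat_pool: list[tuple[ProteinRecord, str, list[int]]] = []
    if repeat_fraction > 0:
        for rec in proteome:
            for kmer, starts in _repeated_kmers(rec, mod_set):
                repeat_pool.append((rec, kmer, starts))
        if not repeat_pool:
            raise ValueError("no repeated modifiable substrings to plant")

    rng = np.random.default_rng(seed)
    inputs: list[ModifiedPeptideInput] = []
    truth: list[GroundTruthSite] = []
    for k in range(n_peptides):
        identifier = f"pep{k + 1:04d}"
        if repeat_pool and rng.random() < repeat_fraction:
            rec, frag, starts = repeat_pool[int(rng.integers(len(repeat_pool)))]
            start = starts[0]
            pep_pos = next(i + 1 for i, c in enumerate(frag) if c in mod_set)
            score = round(float(rng.uniform(95, 100)), 2)
            candidates = [(pep_pos, score)]
            total_sites = 1
            true_positions = [pep_pos]
        else:
            rec, start, frag = pool[int(rng.integers(len(pool)))]
            mod_positions = [i + 1 for i, c in enumerate(frag) if c in mod_set]
            total_sites = min(
                int(rng.integers(lo_sites, hi_sites + 1)), len(mod_positions)
            )
            chosen_idx = rng.choice(len(mod_positions), size=total_sites, replace=False)
            true_positions = sorted(mod_positions[i] for i in chosen_idx)
            remaining = [p for p in mod_positions if p not in set(true_positions)]
            candidates = [
                (p, round(float(rng.uniform(95, 100)), 2)) for p in true_positions
            ]
            if remaining and rng.random() < ambiguous_fraction:
                # tie the lowest-scoring true site with an extra candidate at
                # a higher position, so rank order keeps the true site but
                # the tie straddles the selection boundary
                low_pos, low_score = min(candidates, key=lambda c: (c[1], c[0]))
                later = [p for p in remaining if p > low_pos]
                tie_pos = later[0] if later else remaining[0]
                candidates.append((tie_pos, low_score))
                remaining = [p for p in remaining if p != tie_pos]
            elif remaining and rng.random() < decoy_candidate_rate:
                n_decoys = min(len(remaining), int(rng.integers(1, 3)))
                decoy_idx = rng.choice(len(remaining), size=n_decoys, replace=False)
                for i in sorted(decoy_idx):
                    candidates.append(
                        (remaining[i], round(float(rng.uniform(0, 5)), 2))
                    )
        candidates.sort(key=lambda c: c[0])
        inputs.append(
            ModifiedPeptideInput(
                identifier=identifier,
                protein_id=rec.protein_id,
                peptide_seq=frag,
                total_sites=total_sites,
                ptm_loc=";".join(f"{frag[p - 1]}{p}" for p, _ in candidates),
                ptm_score=";".join(f"{s:.2f}" for _, s in candidates),
            )
        )
        for pep_pos in true_positions:
            prot_loc = start + pep_pos - 1
            residue = frag[pep_pos - 1]
            assert rec.sequence[prot_loc - 1] == residue  # construction invariant
            truth.append(
                GroundTruthSite(
                    identifier=identifier,
                    protein_id=rec.protein_id,
                    true_prot_loc=prot_loc,
                    true_flank=extract_flank(rec.sequence, prot_loc, _TRUTH_HALF_WIDTH),
                    residue=residue,
                )
            )
    return inputs, truth


def write_peptide_table(
    inputs: Iterable[ModifiedPeptideInput], out: str | os.PathLike | IO[str]
) -> None:
    """Write rows in the six-column CSV layout the localizer reads."""
    with _as_text_handle(out, "w") as handle:
        handle.write(",".join(INPUT_COLUMNS) + "\n")
        for row in inputs:
            handle.write(
                f"{row.identifier},{row.protein_id},{row.peptide_seq},"
                f"{row.total_sites},{row.ptm_loc},{row.ptm_score}\n"
            )


def write_truth_table(
    truth: Iterable[GroundTruthSite], out: str | os.PathLike | IO[str]
) -> None:
    """Write the ground-truth sites as CSV."""
    with _as_text_handle(out, "w") as handle:
        handle.write(",".join(TRUTH_COLUMNS) + "\n")
        for site in truth:
            handle.write(
                f"{site.identifier},{site.protein_id},{site.true_prot_loc},"
                f"{site.residue},{site.true_flank}\n"
            )
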
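# Methods

## Problem and model

Mass-spectrometry search engines report modified peptides with candidate
modification positions and per-residue localization confidences (ptmRS- or
Ascore-style probabilities, treated here as opaque scores on a 0–100
scale; `ptmphind` consumes scores, it never recomputes them). The package
resolves those peptide-level assignments into protein-level sites in four
deterministic string operations: candidate selection, substring search,
coordinate translation, and fixed-width window extraction. There is no
statistical model — correctness is exact recovery, which is why the
validation harness is built around planted ground truth rather than
estimation error.

## Coordinates and windows

All positions are 1-based and inclusive, both within the peptide
(`Pep_Loc`) and the protein (`Prot_Loc`), matching biological residue
numbering ("S473"). For a site at protein position `l` in a sequence of
length `n`, the flanking window covers `l-w … l+w`; positions outside
`[1, n]` are replaced by the pad character.

* `w` (half-width), default **7**: 15-mer windows, the convention of
  motif-x-style enrichment tools and phosphosite databases. Configurable;
  the `background` subcommand also accepts `--full-width 2w+1` for users
  who think in total widths.
* `pad`, default **`_`**: keeps all windows at exactly `2w+1` characters,
  which pre-aligned motif tools require. The pad count at a site is
  `max(0, w-(l-1)) + max(0, w-(n-l))`, an invariant the tests check.
* drop-truncated mode removes any mapping whose window would contain a
  pad character. In the localization output this removes the entry from
  all four parallel `;`-joined lists (keeping them parallel); in
  background extraction it removes the window. Padding is the default in
  both places because dropping boundary windows would bias terminus-
  adjacent residues out of foregrounds and backgrounds.

## Site selection and ambiguity

When a row lists more candidates than its declared `Total_Sites`, the
`Total_Sites` highest-scoring candidates are chosen; exact score ties are
broken toward the lower peptide position (the first-listed isoform in
typical search-engine output). The row-level `Ambiguity` flag has three
values:

* `none` — unique peptide occurrence and a clean selection;
* `site` — the selection boundary fell on a score tie, or a chosen score
  is below `score_floor` (default **75** on the 0–100 scale, the
  customary "confidently localized" threshold for ptmRS-style
  probabilities);
* `position` — the peptide occurs more than once in its protein. All
  occurrences are mapped and reported, grouped per occurrence in
  ascending start order, and this flag dominates `site` because no score
  can rescue an ambiguous genomic placement.

Downstream, `export-foreground` can keep all rows (default), drop
`position`-ambiguous rows, or drop everything not flagged `none`.

## Error handling

A broken reference database (duplicate accession, entry without sequence,
internal `*`) is a hard error: every downstream row would inherit the
corruption invisibly. A broken experimental row (unequal `PTM_Loc` /
`PTM_Score` lengths, residue letter disagreeing with the peptide,
position off the peptide, non-integer `Total_Sites`, duplicated
`Identifier`) degrades to a `malformed` status on that row only; unknown
accessions and peptides absent from their protein likewise become
`protein_not_found` / `peptide_not_found` statuses. Batches never abort
on row errors, and the CLI exits 0 when statuses are the only problems.
Search is restricted to each row's named accession; matching is exact and
case-insensitive only in the sense that all sequences are uppercased on
ingest (no I/L equivalence). Terminal `*` stop characters are stripped
from database sequences; UniProt isoform suffixes (`P12345-2`) are kept
verbatim.

## Synthetic data generator

`fixture_gen` emulates what a phospho-proteomics pipeline hands to the
localization step, with full ground truth:

* proteomes of i.i.d. uniform residues over the 20 standard amino acids
  (a frequency vector can be supplied; frequencies do not affect the
  exact-recovery property being tested);
* tryptic-like peptides cut after K/R (no proline rule, no missed
  cleavages), lengths 7–25, each containing at least one modifiable
  residue (default S/T/Y), and by default required to occur exactly once
  in their protein so the true mapping is unique;
* 1–3 true sites per peptide with scores uniform in [95, 100]; with
  probability `decoy_candidate_rate` (default 0.3) extra low-confidence
  candidates at other modifiable residues with scores in [0, 5]; with
  probability `ambiguous_fraction` a candidate tied exactly with the
  lowest-scoring true site, which the localizer must flag `site`;
* a `repeat_fraction` switch that instead emits short (4–6 residue)
  substrings occurring at least twice in their protein, which the
  localizer must flag `position`.

The generator does not emulate missed cleavages, modification masses,
spectral noise, I/L indistinguishability, or realistic residue and score
distributions. Passing the recovery test therefore demonstrates that the
coordinate arithmetic, window extraction and bookkeeping are exact — not
that localization scores from real instruments are trustworthy, which is
the search engine's problem, not this package's.

## Validation sizes and determinism

The recovery experiment uses 20 proteins of 200–500 residues and 100
peptides (a few hundred planted sites), which exercises every code path
while keeping the whole suite in seconds; the randomized invariant checks
use 1000 search pairs, 1000 window triples, 50 background proteomes and
100 round-trip proteomes. All randomness flows through explicit integer
seeds (NumPy `default_rng`), so every table, fixture and pipeline output
is byte-reproducible; the end-to-end CLI pipeline on the bundled demo is
tested for byte-identical reruns.

## Known limitations

* Input is limited to the six-column delimited table and FASTA databases;
  standardized PTM interchange formats (e.g. mzTab) are not read.
* No re-scoring, no peptide-spectrum-match handling, and no motif
  enrichment or logo rendering — the outputs are formatted to feed
  existing enrichment tools.
* Redundant or isoform-duplicated database entries are not collapsed;
  users should deduplicate before parsing, since a peptide matching two
  accessions is only searched in the one its row names.
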
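# ptmphind

Shotgun proteomics localizes post-translational modifications (PTMs) —
phosphorylation, acetylation, ubiquitination and others — to specific
residues of the *peptides* observed in the mass spectrometer. Most of the
downstream biology, however, is stated in protein coordinates ("S473 of
AKT1") and most motif-enrichment tools want fixed-width sequence windows
centered on the modified residue. `ptmphind` closes that gap for
proteomics practitioners: it maps each modified peptide back onto its
full-length protein, converts candidate site positions from peptide to
protein coordinates, extracts equal-width flanking windows, flags
ambiguous assignments, and builds proteome-specific background window
sets for motif-enrichment statistics.

## The method

For a peptide $p$ reported against protein accession $a$ with candidate
modification positions $\{(r_i, q_i, s_i)\}$ (residue letter, 1-based
peptide position, localization score on the ptmRS-style 0–100 scale) and a
declared number of true sites $m$:

1. the $m$ highest-scoring candidates are selected (ties broken toward
   the lower peptide position);
2. every occurrence of $p$ in the sequence of $a$ is found by exact,
   overlap-aware substring search; each occurrence start $t$ maps a
   chosen site to protein position $\ell = t + q_i - 1$;
3. the flanking window is the substring covering $\ell - w \ldots \ell + w$
   ($2w+1$ residues, default $w = 7$, i.e. 15-mers), with positions past
   either sequence end padded with `_` so all windows share one width;
4. each row carries a three-level ambiguity flag: `none`, `site` (a score
   tie across the selection boundary, or a chosen score below the floor,
   default 75), or `position` (the peptide occurs more than once in the
   protein; all mappings are reported).

Background sets enumerate the window around *every* occurrence of a
chosen central residue (e.g. S, T or Y) across the parsed proteome, so
the background size equals the residue count — the null set that
motif-enrichment tools such as motif-x expect.

## Worked example

The package bundles a synthetic 3-protein demo proteome and a 3-row
modified-peptide table. The four pipeline steps:

```sh
ptmphind parse-db --fasta "$(python -c 'import ptmphind;print(ptmphind.demo_proteome_path())')" --out parsed.tsv
ptmphind phind --input "$(python -c 'import ptmphind;print(ptmphind.demo_peptides_path())')" --parsed-db parsed.tsv --out localized.csv
ptmphind export-foreground --localized localized.csv --center S --out fg.txt
ptmphind background --parsed-db parsed.tsv --center S --width 7 --out bg.txt
```

`localized.csv` then contains (protein sequences abbreviated here):

```
Identifier,Protein_ID,Pep_Loc,Prot_Loc,PTM_Score,Flank_Seq,Ambiguity,Prot_Seq,Status
id1,P10001,3,13,99.5,IAKQRQISFVKSHFS,none,MKTAYIAK...,ok
id2,P10002,1;2,19;20,98;97,RAKAKTRSSRAGLQF;AKAKTRSSRAGLQFP,none,MSGRGKQG...,ok
id3,P10003,2,23,55,SRSSGRVYYFNHITN,site,MADEEKLP...,ok
```

Row `id1`: peptide `QISFVK` sits at protein positions 11–16 of P10001, so
its third residue (S) is protein position 13, and the 15-mer window
around it is `IAKQRQISFVKSHFS`. Row `id2` carries two phosphosites on
adjacent serines (protein positions 19 and 20), reported as `;`-joined
parallel lists. Row `id3` is localized but flagged `site`-ambiguous
because its best score (55) is below the 75 floor. `fg.txt` holds the
three serine-centered windows one per line; `bg.txt` holds all 17
serine-centered 15-mers in the demo proteome — the matching background.

`ptmphind simulate` generates synthetic proteomes and peptide tables with
a ground-truth site list (see `docs/methods.md`) for validating the
pipeline end to end.

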
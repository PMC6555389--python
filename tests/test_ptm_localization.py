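"""Site parsing, selection, peptide search, flank extraction, and the batch driver."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptmphind.proteome_db import ParsedProteome, ProteinRecord
from ptmphind.ptm_localization import (
    MalformedRowError,
    ModifiedPeptideInput,
    OUTPUT_COLUMNS,
    SiteCandidate,
    extract_flank,
    find_peptide_occurrences,
    parse_site_string,
    phind_ptms,
    read_localization_table,
    read_modified_peptides,
    resolve_sites,
    write_localization_table,
)


def row(identifier="id1", protein_id="P1", peptide_seq="PEPSIDE", total_sites=1,
        ptm_loc="S4", ptm_score="100", error=None):
    return ModifiedPeptideInput(identifier, protein_id, peptide_seq,
                                total_sites, ptm_loc, ptm_score, error)


# --- parse_site_string -------------------------------------------------------

def test_parse_residue_annotated_tokens():
    cands = parse_site_string("S5;T7", "99.2;0.8", "AKDMSVTKR")
    assert [(c.residue, c.pep_pos, c.score) for c in cands] == [
        ("S", 5, 99.2), ("T", 7, 0.8)]


def test_parse_bare_integer_tokens():
    cands = parse_site_string("5", "100", "AKDMS")
    assert [(c.residue, c.pep_pos, c.score) for c in cands] == [(None, 5, 100.0)]


@pytest.mark.parametrize(
    "loc,score,pep,match",
    [
        ("S5;T7", "99.2", "AKDMSVTKR", "entries"),          # length mismatch
        ("S5", "99.2", "AKDTX", "S5"),                      # residue mismatch
        ("S0", "1", "SSS", "S0"),                           # position < 1
        ("S9", "1", "SSS", "S9"),                           # past peptide end
        ("5S", "1", "AKDMS", "5S"),                         # bad token shape
        ("5", "high", "AKDMS", "high"),                     # bad score
        ("", "1", "AKDMS", "empty"),
    ],
)
def test_parse_malformed_fields(loc, score, pep, match):
    with pytest.raises(MalformedRowError, match=match):
        parse_site_string(loc, score, pep)


# --- resolve_sites -----------------------------------------------------------

def C(pos, score, res=None):
    return SiteCandidate(pos, score, res)


@pytest.mark.parametrize(
    "cands,total,exp_pos,exp_amb",
    [
        ([C(5, 99.0, "S"), C(7, 1.0, "T")], 1, [5], False),   # clear argmax
        ([C(2, 50.0, "S"), C(4, 50.0, "S")], 1, [2], True),   # boundary tie
        ([C(2, 100.0, "S"), C(6, 100.0, "T")], 2, [2, 6], False),  # all used
        ([C(3, 70.0)], 1, [3], True),                          # below floor 75
        ([C(9, 99.0), C(2, 99.0), C(5, 1.0)], 2, [2, 9], False),  # tie inside selection
    ],
)
def test_site_selection(cands, total, exp_pos, exp_amb):
    chosen, ambiguous = resolve_sites(cands, total)
    assert [c.pep_pos for c in chosen] == exp_pos
    assert ambiguous is exp_amb


def test_selection_tiebreak_prefers_lower_position():
    chosen, ambiguous = resolve_sites([C(8, 90.0), C(3, 90.0)], 1)
    assert [c.pep_pos for c in chosen] == [3]
    assert ambiguous  # the tie straddles the boundary either way


def test_selection_requires_enough_candidates():
    with pytest.raises(MalformedRowError):
        resolve_sites([C(1, 99.0)], 2)


# --- find_peptide_occurrences ------------------------------------------------

def brute_force_occurrences(pep: str, prot: str) -> list[int]:
    return [i + 1 for i in range(len(prot) - len(pep) + 1)
            if prot[i:i + len(pep)] == pep]


@pytest.mark.parametrize(
    "pep,prot,expected",
    [
        ("AA", "AAAA", [1, 2, 3]),          # overlapping hits
        ("PEPTIDE", "MKPEPTIDEK", [3]),
        ("XYZ", "MKPEPTIDEK", []),
    ],
)
def test_occurrence_examples(pep, prot, expected):
    assert find_peptide_occurrences(pep, prot) == expected


@given(st.data())
def test_occurrences_match_brute_force(data):
    """Overlap-aware search agrees with checking every start position."""
    alphabet = data.draw(st.sampled_from(["AB", "AC", "ACDEFG", "ACDEFGHIKLMNPQRSTVWY"]))
    prot = data.draw(st.text(alphabet=alphabet, min_size=1, max_size=60))
    pep = data.draw(st.text(alphabet=alphabet, min_size=1, max_size=6))
    assert find_peptide_occurrences(pep, prot) == brute_force_occurrences(pep, prot)


# --- extract_flank -----------------------------------------------------------

@pytest.mark.parametrize(
    "seq,loc,w,expected",
    [
        ("MKTS", 4, 3, "MKTS___"),
        ("MKTS", 1, 2, "__MKT"),
        ("ABCDEFG", 4, 3, "ABCDEFG"),
    ],
)
def test_flank_examples(seq, loc, w, expected):
    assert extract_flank(seq, loc, w, "_") == expected


@given(st.data())
def test_flank_algebra(data):
    """Length, center, pad-count formula and substring property all hold."""
    seq = data.draw(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=50))
    loc = data.draw(st.integers(1, len(seq)))
    w = data.draw(st.integers(1, 12))
    window = extract_flank(seq, loc, w, "_")
    assert len(window) == 2 * w + 1
    assert window[w] == seq[loc - 1]
    expected_pads = max(0, w - (loc - 1)) + max(0, w - (len(seq) - loc))
    assert window.count("_") == expected_pads
    assert window.strip("_") in seq


def test_flank_precondition_errors():
    with pytest.raises(ValueError):
        extract_flank("MKT", 4, 2)
    with pytest.raises(ValueError):
        extract_flank("MKT", 1, 0)


# --- phind_ptms --------------------------------------------------------------

def test_localization_of_unique_peptide(tiny_proteome):
    # "PEPSIDE" starts at position 3 of MKPEPSIDEK, so peptide S4 is the
    # serine at protein position 6; the w=3 window is positions 3..9.
    [out] = phind_ptms([row()], tiny_proteome, w=3)
    assert out.status == "ok"
    assert (out.pep_loc, out.prot_loc, out.flank_seq) == ("4", "6", "PEPSIDE")
    assert out.prot_seq[int(out.prot_loc) - 1] == "S" == out.flank_seq[3]
    assert out.ambiguity == "none"
    assert out.prot_seq == "MKPEPSIDEK"


def test_protein_not_found_keeps_other_fields_empty(tiny_proteome):
    [out] = phind_ptms([row(protein_id="NOPE")], tiny_proteome)
    assert out.status == "protein_not_found"
    assert out.prot_loc == "" and out.flank_seq == "" and out.prot_seq == ""


def test_peptide_not_found(tiny_proteome):
    [out] = phind_ptms([row(peptide_seq="WWWW", ptm_loc="1")], tiny_proteome)
    assert out.status == "peptide_not_found"
    assert out.prot_seq == "MKPEPSIDEK"


def test_repeated_peptide_reports_all_occurrences(tiny_proteome):
    [out] = phind_ptms(
        [row(identifier="id2", protein_id="P2", peptide_seq="AA", ptm_loc="1",
             ptm_score="100")],
        tiny_proteome, w=2)
    assert out.status == "ok"
    assert out.prot_loc == "1;2;3"
    assert out.pep_loc == "1;1;1"
    assert out.ambiguity == "position"
    assert out.flank_seq == "__AAA;_AAAA;AAAA_"


def test_position_ambiguity_dominates_site_ambiguity(tiny_proteome):
    [out] = phind_ptms(
        [row(protein_id="P2", peptide_seq="AA", total_sites=1,
             ptm_loc="1;2", ptm_score="50;50")],
        tiny_proteome)
    assert out.ambiguity == "position"


def test_low_score_flags_site_ambiguity(tiny_proteome):
    [out] = phind_ptms([row(ptm_score="60")], tiny_proteome)
    assert out.status == "ok" and out.ambiguity == "site"


def test_multisite_lists_are_parallel_and_sorted(tiny_proteome):
    [out] = phind_ptms(
        [row(protein_id="P3", peptide_seq="TAYSTYK", total_sites=2,
             ptm_loc="Y3;S4;Y6", ptm_score="10;99;98")],
        tiny_proteome, w=2)
    assert out.status == "ok"
    assert out.pep_loc == "4;6"
    assert out.prot_loc == "6;8"       # peptide starts at protein position 3
    assert out.ptm_score == "99;98"
    assert [w[2] for w in out.flank_seq.split(";")] == ["S", "Y"]


def test_drop_truncated_removes_boundary_mappings(tiny_proteome):
    [kept] = phind_ptms([row()], tiny_proteome, w=7)
    assert "_" in kept.flank_seq
    [dropped] = phind_ptms([row()], tiny_proteome, w=7, drop_truncated=True)
    assert dropped.flank_seq == "" and dropped.status == "ok"


def test_malformed_rows_do_not_perturb_their_neighbors(tiny_proteome):
    good = row()
    bad1 = row(identifier="b1", ptm_loc="S4;S5", ptm_score="1")
    bad2 = row(identifier="b2", total_sites=9)
    batch = phind_ptms([bad1, good, bad2], tiny_proteome)
    assert [r.status for r in batch] == ["malformed", "ok", "malformed"]
    [alone] = phind_ptms([good], tiny_proteome)
    assert batch[1] == alone


def test_coordinate_consistency_invariants(tiny_proteome):
    rows = [
        row(),
        row(identifier="id2", protein_id="P3", peptide_seq="TAYSTYK",
            total_sites=2, ptm_loc="S4;Y6", ptm_score="99;98"),
    ]
    for inp, out in zip(rows, phind_ptms(rows, tiny_proteome, w=4)):
        assert out.status == "ok"
        for pep_loc, prot_loc, flank in zip(
            out.pep_loc.split(";"), out.prot_loc.split(";"), out.flank_seq.split(";")
        ):
            pep_loc, prot_loc = int(pep_loc), int(prot_loc)
            assert out.prot_seq[prot_loc - 1] == flank[4] == inp.peptide_seq[pep_loc - 1]
            start = prot_loc - pep_loc + 1  # occurrence start implied by the pair
            assert out.prot_seq[start - 1 : start - 1 + len(inp.peptide_seq)] == inp.peptide_seq


# --- table I/O ---------------------------------------------------------------

def test_input_reader_strict_header_and_sniffing():
    csv_text = "Identifier,Protein_ID,Peptide_Seq,Total_Sites,PTM_Loc,PTM_Score\nid1,P1,PEPSIDE,1,S4,99\n"
    tsv_text = csv_text.replace(",", "\t").replace("S4\t99", "S4\t99")
    assert read_modified_peptides(io.StringIO(csv_text))[0].peptide_seq == "PEPSIDE"
    rows = read_modified_peptides(io.StringIO(tsv_text))
    assert rows[0].protein_id == "P1" and rows[0].error is None
    with pytest.raises(MalformedRowError, match="exactly"):
        read_modified_peptides(io.StringIO(csv_text.replace("PTM_Score", "Score")))


def test_input_reader_marks_bad_rows_not_batches(tiny_proteome):
    text = (
        "Identifier,Protein_ID,Peptide_Seq,Total_Sites,PTM_Loc,PTM_Score\n"
        "id1,P1,PEPSIDE,1,S4,99\n"
        "id2,P1,PEPSIDE,two,S4,99\n"
        "id1,P1,PEPSIDE,1,S4,99\n"
        "short,row\n"
    )
    rows = read_modified_peptides(io.StringIO(text))
    assert [r.error is None for r in rows] == [True, False, False, False]
    statuses = [r.status for r in phind_ptms(rows, tiny_proteome)]
    assert statuses == ["ok", "malformed", "malformed", "malformed"]


def test_output_table_layout(tiny_proteome):
    rows = phind_ptms(
        [row(), row(identifier="id2", protein_id="P2", peptide_seq="AA",
                    ptm_loc="1", ptm_score="100")],
        tiny_proteome, w=2)
    buf = io.StringIO()
    write_localization_table(rows, buf)
    lines = buf.getvalue().splitlines()
    assert lines[0] == "Identifier,Protein_ID,Pep_Loc,Prot_Loc,PTM_Score,Flank_Seq,Ambiguity,Prot_Seq,Status"
    assert all(len(line.split(",")) == 9 for line in lines)
    assert "1;2;3" in lines[2] and '"' not in lines[2]  # ';' needs no quoting
    assert read_localization_table(io.StringIO(buf.getvalue())) == rows


def test_empty_output_table_is_header_only():
    buf = io.StringIO()
    write_localization_table([], buf)
    assert buf.getvalue() == ",".join(OUTPUT_COLUMNS) + "\n"
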
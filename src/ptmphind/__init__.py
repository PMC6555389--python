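"""ptmphind: PTM site localization and flanking-motif extraction.

Maps modified peptides from shotgun-proteomics experiments onto their
full-length proteins, extracts fixed-width flanking windows around each
modification site, and builds proteome-specific background motif sets for
downstream motif-enrichment tools.
"""

from importlib import resources
from pathlib import Path

__version__ = "0.1.0"

from .background import (
    BackgroundSet,
    extract_background,
    subsample_background,
    write_background,
)
from .fixture_gen import (
    GroundTruthSite,
    generate_modified_peptides,
    generate_proteome,
    write_peptide_table,
    write_truth_table,
)
from .motif_export import foreground_from_rows, write_sequence_list
from .proteome_db import (
    DatabaseError,
    ParsedProteome,
    ProteinRecord,
    parse_fasta_db,
    read_parsed_db,
    write_parsed_db,
)
from .ptm_localization import (
    LocalizationRow,
    LocalizedSite,
    MalformedRowError,
    ModifiedPeptideInput,
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


def demo_proteome_path() -> Path:
    """Path to the bundled 3-protein synthetic demo FASTA."""
    return Path(str(resources.files(__name__) / "data" / "demo_proteome.fasta"))


def demo_peptides_path() -> Path:
    """Path to the bundled synthetic demo modified-peptide table."""
    return Path(str(resources.files(__name__) / "data" / "demo_peptides.csv"))
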
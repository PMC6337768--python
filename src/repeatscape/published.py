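"""Published summary counts for the spinach draft-genome repeat annotation.

These are literature-reported values for *Spinacia oleracea* (draft
assembly ~996 Mb; shotgun reads averaging 301 bp): the full-length
LTR retroelement tally and its Copia/Gypsy split, Table-style masked
base-pair totals, and the read set used for satellite discovery.  They
serve as inputs for arithmetic cross-checks (shares, percentages,
coverage) — the percentages below are *recomputed* from the printed
counts, never copied.
"""

from __future__ import annotations

# full-length LTR retroelements and their classification
FULL_LENGTH_LTR_RE = 11_640
COPIA_COUNT = 5_303
GYPSY_COUNT = 3_709
UNCLASSIFIED_COUNT = 2_628

# masked base pairs of the main superfamilies (full-length set)
COPIA_BP = 51_884_973
GYPSY_BP = 40_349_864
UNCLASSIFIED_BP = 18_203_221
LTR_RE_TOTAL_BP = 110_438_058
FULL_LENGTH_TE_TOTAL_BP = 125_231_331

# whole-genome masking
TOTAL_MASKED_BP = 637_890_846

# assembly and read set
ASSEMBLY_BP = 996_000_000  # draft assembly size used for Table percentages
GENOME_SIZE_BP = 989_000_000  # estimated genome size used for read coverage
SATELLITE_READS = 2_000_000
SATELLITE_READ_LENGTH = 301


def copia_share_pct() -> float:
    """Copia fraction of classified+unclassified full-length LTR-REs (%)."""
    return 100.0 * COPIA_COUNT / FULL_LENGTH_LTR_RE


def gypsy_share_pct() -> float:
    return 100.0 * GYPSY_COUNT / FULL_LENGTH_LTR_RE


def unclassified_share_pct() -> float:
    return 100.0 * UNCLASSIFIED_COUNT / FULL_LENGTH_LTR_RE


def pct_of_assembly(bp: int) -> float:
    return 100.0 * bp / ASSEMBLY_BP


def read_coverage_x() -> float:
    """Genome equivalents represented by the satellite read set."""
    return SATELLITE_READS * SATELLITE_READ_LENGTH / GENOME_SIZE_BP
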
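"""Bundled toy reference libraries.

Three small reference sets back the pipeline and its synthetic test bed:

* a tRNA 3'-end library (18-mers) used both to plant primer-binding
  sites and to detect them;
* a lineage-labelled retroelement domain peptide library (GAG, PR, INT,
  RT, RH consensus peptides plus one RT variant per Copia/Gypsy
  lineage), generated from a fixed-seed hierarchical mutation process so
  that lineages within a superfamily are more similar to each other than
  across superfamilies, and the four Chromovirus Gypsy lineages
  (Tekay/Del, Galadriel, Reina, CRM) form a subgroup distinct from
  Ogre/Tat and Athila;
* a labelled nucleotide repeat library standing in for homology-based
  masking libraries (LINE and Helitron exemplars).

Real libraries (GyDB/Pfam-derived peptides, Repbase nucleotide sets)
are pluggable through the same FASTA interfaces; these synthetic sets
exist so every stage is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COPIA_LINEAGES = ("Ale/Retrofit", "Angela", "Bianca", "Ivana", "SIRE", "TAR", "Tork")
GYPSY_LINEAGES = ("Athila", "Ogre/Tat", "Tekay/Del", "CRM", "Galadriel", "Reina")
CHROMOVIRUS_LINEAGES = ("Tekay/Del", "CRM", "Galadriel", "Reina")
NON_CHROMOVIRUS_LINEAGES = ("Ogre/Tat", "Athila")
DOMAINS = ("GAG", "PR", "INT", "RT", "RH")
DOMAIN_LENGTHS = {"GAG": 130, "PR": 100, "INT": 180, "RT": 240, "RH": 130}

# Domain order along the pol polyprotein distinguishes the superfamilies:
# Copia integrase precedes reverse transcriptase, Gypsy is the reverse.
DOMAIN_ORDER = {
    "Copia": ("GAG", "PR", "INT", "RT", "RH"),
    "Gypsy": ("GAG", "PR", "RT", "RH", "INT"),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# One unambiguous sense codon per amino acid; used to back-translate
# reference peptides into plantable coding sequence.
CODON_TABLE = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

# Hand-curated toy tRNA 3'-terminal 18-mers (all end in the universal
# CCA); the PBS of a planted element is the reverse complement of one of
# these.  Ids sort lexicographically for deterministic tie-breaks.
TRNA_3PRIME = {
    "tRNA-Ala": "GGGTCGATTCGATCACCA",
    "tRNA-Arg": "CTCCGGTTCGATTCCGCA",  # toy entry; 3' CCA not enforced here
    "tRNA-Asp": "GGGTTCGATTCCCGACCA",
    "tRNA-Gly": "GTGGTTCGATTCCACCCA",
    "tRNA-Lys": "CTGGGTTCAAGTCCCACA",
    "tRNA-Met": "TGGTAGCTCAGTTGGCCA",
    "tRNA-Ser": "CGGGTTCGATTCCCGGCA",
    "tRNA-iMet": "TCGGTTCGATCCCGACCA",
}

_LIBRARY_SEED = 19018  # fixed: the bundled library is a frozen fixture


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_peptide(peptide: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute ``fraction`` of residues to a different random residue."""
    chars = list(peptide)
    n_mut = rng.binomial(len(chars), fraction)
    sites = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for i in sites:
        choices = AMINO_ACIDS.replace(chars[i], "")
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def back_translate(peptide: str) -> str:
    """Deterministic back-translation using the fixed codon table."""
    return "".join(CODON_TABLE[aa] for aa in peptide)


@dataclass
class ReferenceLibrary:
    """Bundled domain/tRNA/repeat references used across the pipeline."""

    domain_consensus: dict[str, str]
    rt_lineage: dict[tuple[str, str], str]
    trna: dict[str, str] = field(default_factory=lambda: dict(TRNA_3PRIME))
    repeat_nt: list[tuple[str, str, str]] = field(default_factory=list)  # (name, class/superfamily label, seq)

    def lineages(self) -> list[tuple[str, str]]:
        return sorted(self.rt_lineage)

    def rt_for(self, superfamily: str, lineage: str) -> str:
        return self.rt_lineage[(superfamily, lineage)]


def build_reference_library() -> ReferenceLibrary:
    """Deterministically build the bundled toy reference library.

    RT lineage variants descend from one root RT through superfamily
    ancestors (25% divergence from the root), a Chromovirus /
    non-Chromovirus split inside Gypsy (10% each), and 10% lineage-level
    divergence, giving within-superfamily identities around 0.8 and
    across-superfamily identities near the noise floor.
    """
    rng = np.random.default_rng(_LIBRARY_SEED)
    consensus = {d: _random_peptide(rng, DOMAIN_LENGTHS[d]) for d in DOMAINS}

    rt_root = consensus["RT"]
    copia_anc = mutate_peptide(rt_root, 0.25, rng)
    gypsy_anc = mutate_peptide(rt_root, 0.25, rng)
    chromo_anc = mutate_peptide(gypsy_anc, 0.10, rng)
    nonchromo_anc = mutate_peptide(gypsy_anc, 0.10, rng)

    rt_lineage: dict[tuple[str, str], str] = {}
    for lineage in COPIA_LINEAGES:
        rt_lineage[("Copia", lineage)] = mutate_peptide(copia_anc, 0.10, rng)
    for lineage in GYPSY_LINEAGES:
        anc = chromo_anc if lineage in CHROMOVIRUS_LINEAGES else nonchromo_anc
        rt_lineage[("Gypsy", lineage)] = mutate_peptide(anc, 0.10, rng)

    nt_bases = np.array(list("ACGT"))
    repeat_nt = []
    for i, (label, length) in enumerate(
        (
            ("nonLTR/LINE", 3000),
            ("nonLTR/LINE", 2500),
            ("DNA/Helitron", 4000),
            ("DNA/TIR", 1200),
        )
    ):
        seq = "".join(rng.choice(nt_bases, size=length))
        repeat_nt.append((f"toyrep-{i}", label, seq))
    return ReferenceLibrary(domain_consensus=consensus, rt_lineage=rt_lineage, repeat_nt=repeat_nt)


_cached: ReferenceLibrary | None = None


def default_library() -> ReferenceLibrary:
    """Singleton accessor for the bundled library (it is deterministic)."""
    global _cached
    if _cached is None:
        _cached = build_reference_library()
    return _cached
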
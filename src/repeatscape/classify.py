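"""Superfamily and lineage classification of LTR retroelements.

Precedence follows the annotation narrative: domain order first (Copia
integrase precedes reverse transcriptase, Gypsy the reverse), homology
fallback against a labelled repeat library second (BLAST-like local
hits accepted at E < 1e-10 nucleotide / E < 1e-15 translated), unknown
last.  Lineages are assigned from the best-identity RT reference with a
minimum identity and a margin over the runner-up, mirroring how close
lineages (e.g. SIRE and Ivana) stay unresolved without clear evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignment import (
    KA_K_NT,
    KA_K_PROT,
    KA_LAMBDA_NT,
    KA_LAMBDA_PROT,
    evalue,
    global_prot_identity,
    prot_aligner,
)
from .annotate import AnnotatedElement, DomainHit, six_frame_translations
from .masking import best_local_nt_hit
from .references import COPIA_LINEAGES, GYPSY_LINEAGES, ReferenceLibrary, default_library

EVALUE_NT = 1e-10
EVALUE_PROT = 1e-15

VALID_LINEAGES = {
    "Copia": set(COPIA_LINEAGES),
    "Gypsy": set(GYPSY_LINEAGES),
    "unknown": {"unknown"},
}


@dataclass
class LineageLabel:
    superfamily: str  # Copia | Gypsy | unknown
    lineage: str
    evidence: str  # domain_order | homology | none

    def __post_init__(self):
        if self.superfamily not in VALID_LINEAGES:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        if self.lineage != "unknown" and self.lineage not in VALID_LINEAGES[self.superfamily]:
            raise ValueError(f"lineage {self.lineage!r} inconsistent with {self.superfamily}")


def classify_superfamily(domains: list[DomainHit]) -> str:
    """INT before RT -> Copia; RT before INT -> Gypsy; else unknown."""
    best: dict[str, DomainHit] = {}
    for hit in domains:
        if hit.domain in ("INT", "RT"):
            prev = best.get(hit.domain)
            if prev is None or hit.score > prev.score:
                best[hit.domain] = hit
    if "INT" not in best or "RT" not in best:
        return "unknown"
    mid = {d: (h.pep_interval[0] + h.pep_interval[1]) / 2 for d, h in best.items()}
    return "Copia" if mid["INT"] < mid["RT"] else "Gypsy"


def homology_classify(element_seq: str,
                      labelled_library: list[tuple[str, str, str, str]]) -> LineageLabel:
    """Classify by the best accepted local hit against a labelled library.

    ``labelled_library`` entries are (superfamily, lineage, kind, sequence)
    where kind is 'nt' or 'prot'.  Nucleotide hits are accepted at
    E < 1e-10, translated hits at E < 1e-15 (strict inequality).
    """
    if not labelled_library:
        raise ValueError("empty library")
    best: tuple[float, float, LineageLabel] | None = None  # (evalue, -score, label)
    frames = None
    aligner = prot_aligner("local")
    for superfamily, lineage, kind, ref in labelled_library:
        if kind == "nt":
            hit = best_local_nt_hit(element_seq, ref)
            if hit is None:
                continue
            score = hit.score
            e = evalue(score, len(element_seq), len(ref), KA_LAMBDA_NT, KA_K_NT)
            threshold = EVALUE_NT
        else:
            if frames is None:
                frames = six_frame_translations(element_seq)
            score = max(aligner.score(pep, ref) for _, pep in frames if len(pep) >= 10)
            e = evalue(score, len(element_seq) // 3, len(ref), KA_LAMBDA_PROT, KA_K_PROT)
            threshold = EVALUE_PROT
        if e < threshold:
            key = (e, -score)
            if best is None or key < (best[0], best[1]):
                best = (e, -score, LineageLabel(superfamily, lineage, "homology"))
    if best is None:
        return LineageLabel("unknown", "unknown", "none")
    return best[2]


def assign_lineage(rt_peptide: str, refs: ReferenceLibrary | None = None,
                   min_identity: float = 0.45, min_margin: float = 0.02,
                   superfamily: str | None = None) -> tuple[str, str]:
    """(superfamily, lineage) of the best-identity RT reference.

    Assigned only if the best global identity reaches ``min_identity``
    and beats the runner-up from a different lineage by ``min_margin``;
    otherwise unknown.  ``superfamily`` restricts the reference set.
    """
    refs = refs or default_library()
    scored = []
    for (sf, lineage), ref in sorted(refs.rt_lineage.items()):
        if superfamily and sf != superfamily:
            continue
        scored.append((global_prot_identity(rt_peptide, ref), sf, lineage))
    if not scored:
        return ("unknown", "unknown")
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_id, best_sf, best_lin = scored[0]
    if best_id < min_identity:
        return ("unknown", "unknown")
    if len(scored) > 1 and best_id - scored[1][0] < min_margin:
        return ("unknown", "unknown")
    return (best_sf, best_lin)


def classify_element(element: AnnotatedElement,
                     refs: ReferenceLibrary | None = None,
                     homology_library: list[tuple[str, str, str, str]] | None = None,
                     element_seq: str | None = None) -> LineageLabel:
    """Full classification with domain-order-first precedence."""
    refs = refs or default_library()
    superfamily = classify_superfamily(element.domains)
    if superfamily != "unknown":
        rt_hit = next((d for d in element.domains if d.domain == "RT"), None)
        lineage = "unknown"
        if rt_hit is not None and rt_hit.peptide:
            _, lineage = assign_lineage(rt_hit.peptide, refs, superfamily=superfamily)
        return LineageLabel(superfamily, lineage, "domain_order")
    if homology_library and element_seq:
        label = homology_classify(element_seq, homology_library)
        if label.superfamily != "unknown":
            return label
    return LineageLabel("unknown", "unknown", "none")
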
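"""Internal-feature annotation of LTR retroelement candidates.

A structurally detected candidate is only kept as a putative full-length
element if its internal region shows at least one hallmark of
retrotransposition competence: a 15-18 nt primer-binding site (PBS)
complementary to a tRNA 3' end near the 5' LTR, a 10-30 nt polypurine
tract (PPT) just upstream of the 3' LTR, or one of the five canonical
protein domains (GAG, PR, RT, RH, INT) found by six-frame translated
alignment against a reference peptide library.  Candidates with none of
these are discarded.  An element carrying PBS, PPT and all five domains
is flagged as putatively intact (retrotransposition-competent).

This module also detects terminal-inverted-repeat DNA transposons
(TIR elements and MITEs) by an inverted-repeat + TSD signature search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .alignment import (
    KA_K_PROT,
    KA_LAMBDA_PROT,
    alignment_identity,
    bit_score,
    chain_diagonal_matches,
    global_nt_identity,
    kmer_positions,
    nt_aligner,
    prot_aligner,
    revcomp,
)
from .detect import LTRCandidate
from .references import DOMAINS, ReferenceLibrary, default_library

PURINES = frozenset("AG")

DOMAIN_BIT_FLOOR = 50.0


@dataclass
class PbsHit:
    offset_from_5ltr: int
    length: int
    trna_id: str
    mismatches: int

    def __post_init__(self):
        if not 15 <= self.length <= 18:
            raise ValueError("PBS length must be in [15, 18]")


@dataclass
class PptHit:
    offset_from_3ltr: int  # distance from PPT end to the 3'LTR inner boundary
    length: int
    purine_fraction: float

    def __post_init__(self):
        if not 10 <= self.length <= 30:
            raise ValueError("PPT length must be in [10, 30]")


@dataclass
class DomainHit:
    domain: str
    frame: int  # 1..3 forward, 4..6 reverse
    pep_interval: tuple[int, int]  # nt coordinates on the element
    score: float  # bit score
    best_ref: tuple[str, str]  # (superfamily, lineage); ('unknown','unknown') for consensus
    identity: float
    peptide: str = ""  # matched peptide segment (for lineage assignment)

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain label {self.domain!r}")


@dataclass
class AnnotatedElement:
    """A candidate plus its internal annotations."""

    candidate: LTRCandidate
    pbs: PbsHit | None = None
    ppt: PptHit | None = None
    domains: list[DomainHit] = field(default_factory=list)

    def has_feature(self) -> bool:
        return self.pbs is not None or self.ppt is not None or bool(self.domains)

    def domain_labels(self) -> set[str]:
        return {d.domain for d in self.domains}


def find_pbs(internal_seq: str, trna_library: dict[str, str], window: int = 30,
             max_mismatch: int = 1) -> PbsHit | None:
    """Best tRNA-complementary match near the 5' LTR inner boundary.

    The PBS anneals to the tRNA 3' end, so the element carries the
    reverse complement of the tRNA's terminal 15-18 nt, starting within
    ``window`` bp of the 5' LTR.  Ties: fewer mismatches, longer match,
    lexicographically smaller tRNA id.
    """
    if not trna_library:
        raise ValueError("empty tRNA library")
    best: tuple | None = None
    for trna_id in sorted(trna_library):
        tail = trna_library[trna_id]
        for length in range(18, 14, -1):
            if length > len(tail):
                continue
            probe = revcomp(tail[-length:])
            for offset in range(0, min(window, len(internal_seq) - length) + 1):
                segment = internal_seq[offset : offset + length]
                if len(segment) < length:
                    break
                mism = sum(1 for a, b in zip(segment, probe) if a != b)
                if mism > max_mismatch:
                    continue
                key = (mism, -length, trna_id, offset)
                if best is None or key < best[0]:
                    best = (key, PbsHit(offset, length, trna_id, mism))
    return best[1] if best else None


def find_ppt(internal_seq: str, window: int = 30, min_len: int = 10,
             max_len: int = 30, min_purine: float = 0.85) -> PptHit | None:
    """Highest-purine-fraction window ending near the 3' LTR inner boundary.

    Ties are broken toward longer windows, then the most 3' position.
    """
    n = len(internal_seq)
    is_purine = [1 if b in PURINES else 0 for b in internal_seq]
    prefix = [0]
    for v in is_purine:
        prefix.append(prefix[-1] + v)
    best: tuple | None = None
    for end in range(max(min_len, n - window), n + 1):
        for length in range(min_len, min(max_len, end) + 1):
            frac = (prefix[end] - prefix[end - length]) / length
            key = (frac, length, end)
            if best is None or key > best[0]:
                best = (key, PptHit(n - end, length, frac))
    if best is None or best[0][0] < min_purine:
        return None
    return best[1]


_RAW_FLOOR = (DOMAIN_BIT_FLOOR * math.log(2.0) + math.log(KA_K_PROT)) / KA_LAMBDA_PROT


def six_frame_translations(seq: str) -> list[tuple[int, str]]:
    """(frame, peptide) for frames 1-3 (+) and 4-6 (-)."""
    out = []
    rc = revcomp(seq)
    for f in range(3):
        fwd = seq[f : f + 3 * ((len(seq) - f) // 3)]
        rev = rc[f : f + 3 * ((len(rc) - f) // 3)]
        out.append((f + 1, str(Seq(fwd).translate())))
        out.append((f + 4, str(Seq(rev).translate())))
    return sorted(out)


def _pep_to_nt_interval(frame: int, pep_start: int, pep_end: int, nt_len: int) -> tuple[int, int]:
    if frame <= 3:
        start = (frame - 1) + 3 * pep_start
        end = (frame - 1) + 3 * pep_end
    else:
        # coordinates on the reverse strand map back from the 3' end
        rc_start = (frame - 4) + 3 * pep_start
        rc_end = (frame - 4) + 3 * pep_end
        start, end = nt_len - rc_end, nt_len - rc_start
    return max(0, start), min(nt_len, end)


def find_domains(internal_seq: str, refs: ReferenceLibrary | None = None,
                 bit_floor: float = DOMAIN_BIT_FLOOR) -> list[DomainHit]:
    """Detect canonical protein domains by translated local alignment.

    Each of the six translation frames is aligned (BLOSUM62, affine
    -11/-1) against the per-domain consensus peptides; hits scoring at
    least ``bit_floor`` bits are kept, reduced to the best hit per
    domain.  RT hits are then re-scored against the lineage-labelled RT
    library to fill ``best_ref``.
    """
    refs = refs or default_library()
    if not refs.domain_consensus:
        raise ValueError("empty domain reference set")
    aligner = prot_aligner("local")
    frames = six_frame_translations(internal_seq)
    best_per_domain: dict[str, DomainHit] = {}
    for domain, ref_pep in refs.domain_consensus.items():
        for frame, pep in frames:
            if len(pep) < 10:
                continue
            score = aligner.score(pep, ref_pep)
            if score < _RAW_FLOOR:
                continue
            bits = bit_score(score, KA_LAMBDA_PROT, KA_K_PROT)
            aln = aligner.align(pep, ref_pep)[0]
            identity, _ = alignment_identity(aln)
            blocks = aln.aligned[0]
            pep_start, pep_end = int(blocks[0][0]), int(blocks[-1][1])
            interval = _pep_to_nt_interval(frame, pep_start, pep_end, len(internal_seq))
            hit = DomainHit(domain=domain, frame=frame, pep_interval=interval,
                            score=bits, best_ref=("unknown", "unknown"),
                            identity=identity, peptide=pep[pep_start:pep_end])
            prev = best_per_domain.get(domain)
            if prev is None or hit.score > prev.score:
                best_per_domain[domain] = hit
    # lineage refinement for RT
    rt = best_per_domain.get("RT")
    if rt is not None and refs.rt_lineage:
        frame_pep = dict(frames)[rt.frame]
        best_label, best_sc = ("unknown", "unknown"), -math.inf
        for (superfamily, lineage), ref_pep in sorted(refs.rt_lineage.items()):
            sc = aligner.score(frame_pep, ref_pep)
            if sc > best_sc:
                best_sc, best_label = sc, (superfamily, lineage)
        rt.best_ref = best_label
    return [best_per_domain[d] for d in DOMAINS if d in best_per_domain]


def annotate_element(contig: str, candidate: LTRCandidate,
                     refs: ReferenceLibrary | None = None,
                     pbs_window: int = 30, pbs_max_mismatch: int = 1,
                     ppt_window: int = 30) -> AnnotatedElement:
    """Annotate the internal region between the two LTRs of a candidate."""
    refs = refs or default_library()
    internal = contig[candidate.ltr5[1] : candidate.ltr3[0]]
    pbs = find_pbs(internal, refs.trna, window=pbs_window, max_mismatch=pbs_max_mismatch)
    ppt = find_ppt(internal, window=ppt_window)
    domains = find_domains(internal, refs)
    # domain intervals are relative to the internal region; lift to element
    shift = candidate.ltr5[1] - candidate.start
    lifted = [
        DomainHit(d.domain, d.frame,
                  (d.pep_interval[0] + shift, d.pep_interval[1] + shift),
                  d.score, d.best_ref, d.identity, d.peptide)
        for d in domains
    ]
    return AnnotatedElement(candidate=candidate, pbs=pbs, ppt=ppt, domains=lifted)


def filter_full_length(elements: list[AnnotatedElement]) -> list[AnnotatedElement]:
    """Keep elements showing PBS or PPT or at least one protein domain.

    This is the full-length filter: candidates with none of the
    hallmarks are discarded.  Order is preserved and the filter is
    monotone (adding a feature can only retain, never reject).
    """
    return [e for e in elements if e.has_feature()]


def flag_intact(element: AnnotatedElement) -> bool:
    """True iff PBS, PPT and all five protein domains are present."""
    return (element.pbs is not None and element.ppt is not None
            and element.domain_labels() == set(DOMAINS))


# --- TIR / MITE detection --------------------------------------------------


@dataclass
class TirConfig:
    tir_min: int = 10
    tir_max: int = 100
    element_min: int = 50
    element_max: int = 5000
    tsd_min: int = 2
    tsd_max: int = 10
    min_tir_identity: float = 0.85
    seed_kmer: int = 12
    min_seeds: int = 3
    min_verified_tir: int = 15  # shortest TIR the seed search can confirm
    mite_max_length: int = 800


@dataclass
class TirCandidate:
    contig: str
    start: int
    end: int
    tir_length: int
    tir_identity: float
    tsd: str
    element_class: str  # 'TIR' or 'MITE'


def detect_tir_elements(contig: str, cfg: TirConfig | None = None,
                        refs: ReferenceLibrary | None = None,
                        contig_name: str = "chr1") -> list[TirCandidate]:
    """Inverted-repeat + TSD signature search for DNA transposons.

    Seeds are exact k-mers matching the reverse complement of a
    downstream k-mer within the element-length window; anti-diagonal
    chains are verified by aligning the left TIR against the reverse
    complement of the right TIR.  Elements shorter than
    ``mite_max_length`` with no internal protein domain are classed as
    MITEs, the rest as TIR elements.
    """
    cfg = cfg or TirConfig()
    refs = refs or default_library()
    k = cfg.seed_kmer
    index = kmer_positions(contig, k, max_per_kmer=50)
    matches: list[tuple[int, int]] = []
    for i in range(len(contig) - k + 1):
        rc = revcomp(contig[i : i + k])
        for j in index.get(rc, ()):
            # left TIR k-mer at i pairs with right TIR k-mer ending at j + k
            span = j + k - i
            if cfg.element_min <= span <= cfg.element_max and j > i + k:
                matches.append((i, j))
    # inverted repeats pair on anti-diagonals (i + j constant); mirror the
    # right coordinate so the generic diagonal chainer applies
    mirror = len(contig)
    anti = [(i, mirror - j) for i, j in matches]
    chains = chain_diagonal_matches(anti, k, band=8, max_gap=cfg.tir_max,
                                    min_seeds=cfg.min_seeds)
    out: list[TirCandidate] = []
    for qs, qe, ts, te, _ in chains:
        # exact-match extents delimit the TIR pair symmetrically
        el_start, el_end = qs, mirror - ts + k
        tir_len = qe - qs
        if tir_len < max(cfg.min_verified_tir, cfg.tir_min) or tir_len > cfg.tir_max:
            continue
        span = el_end - el_start
        if not cfg.element_min <= span <= cfg.element_max or span < 2 * tir_len:
            continue
        left_tir = contig[el_start : el_start + tir_len]
        right_tir = contig[el_end - tir_len : el_end]
        identity = global_nt_identity(left_tir, revcomp(right_tir))
        if identity < cfg.min_tir_identity:
            continue
        # a palindromic TSD (e.g. TA) is absorbed into the inverted repeat
        # by the aligner; trim symmetric palindromic edges until a TSD is
        # found immediately outside the element
        tsd = ""
        for trim in range(0, cfg.tsd_max // 2 + 2):
            tsd = _tir_tsd(contig, el_start + trim, el_end - trim, cfg)
            if tsd:
                el_start += trim
                el_end -= trim
                tir_len -= trim
                break
        if not tsd:
            continue
        internal = contig[el_start + tir_len : el_end - tir_len]
        is_mite = (el_end - el_start) < cfg.mite_max_length
        if is_mite and len(internal) >= 60:
            if find_domains(internal, refs):
                is_mite = False
        out.append(TirCandidate(contig=contig_name, start=el_start, end=el_end,
                                tir_length=tir_len, tir_identity=identity,
                                tsd=tsd, element_class="MITE" if is_mite else "TIR"))
    return _dedup_tir(out)


def _tir_tsd(contig: str, start: int, end: int, cfg: TirConfig) -> str:
    if start < cfg.tsd_max or end + cfg.tsd_max > len(contig):
        return ""
    for length in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
        if contig[start - length : start] == contig[end : end + length]:
            return contig[start - length : start]
    return ""


def _dedup_tir(cands: list[TirCandidate]) -> list[TirCandidate]:
    ordered = sorted(cands, key=lambda c: (-c.tir_identity, -(c.end - c.start), c.start))
    kept: list[TirCandidate] = []
    for cand in ordered:
        if any(c.start < cand.end and cand.start < c.end for c in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: c.start)
    return kept
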
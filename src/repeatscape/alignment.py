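"""Shared pairwise-alignment utilities.

All nucleotide alignments in the pipeline use one scoring scheme
(match +1, mismatch -1, gap open -4, gap extend -1; a gap of length L
costs 4 + (L - 1)) and all protein alignments use BLOSUM62 with affine
gaps -11/-1, so identities and scores are comparable across modules.
Sequence identity is always computed over aligned columns with gap
columns excluded.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

NT_MATCH = 1.0
NT_MISMATCH = -1.0
NT_GAP_OPEN = -4.0
NT_GAP_EXTEND = -1.0

PROT_GAP_OPEN = -11.0
PROT_GAP_EXTEND = -1.0

# Karlin-Altschul parameters used to convert raw local-alignment scores to
# bit scores / E-values.  The protein values are the standard ungapped
# BLOSUM62 pair; the nucleotide lambda solves 0.25*e^l + 0.75*e^-l = 1 for
# the +1/-1 scheme (lambda = ln 3), with K fixed as a module constant.
KA_LAMBDA_PROT = 0.267
KA_K_PROT = 0.041
KA_LAMBDA_NT = math.log(3.0)
KA_K_NT = 0.1

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def nt_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = NT_MATCH
    aligner.mismatch_score = NT_MISMATCH
    aligner.open_gap_score = NT_GAP_OPEN
    aligner.extend_gap_score = NT_GAP_EXTEND
    return aligner


@lru_cache(maxsize=None)
def prot_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = PROT_GAP_OPEN
    aligner.extend_gap_score = PROT_GAP_EXTEND
    return aligner


def alignment_identity(alignment) -> tuple[float, int]:
    """(identity, aligned_columns) for a Bio.Align.Alignment.

    Identity = identical columns / aligned columns; columns containing a
    gap are excluded from both numerator and denominator.
    """
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return 0.0, 0
    return counts.identities / aligned, aligned


def global_nt_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment of two DNA sequences."""
    if not a or not b:
        raise ValueError("empty sequence")
    alignment = nt_aligner("global").align(a, b)[0]
    return alignment_identity(alignment)[0]


def global_prot_identity(a: str, b: str) -> float:
    """Identity of the optimal global BLOSUM62 alignment of two peptides."""
    if not a or not b:
        raise ValueError("empty sequence")
    alignment = prot_aligner("global").align(a, b)[0]
    return alignment_identity(alignment)[0]


def bit_score(raw_score: float, lam: float, k: float) -> float:
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int, lam: float, k: float) -> float:
    """Karlin-Altschul expect value for a local alignment raw score."""
    try:
        return k * m * n * math.exp(-lam * raw_score)
    except OverflowError:
        return math.inf


# --- k-mer seeding ---------------------------------------------------------


def kmer_positions(seq: str, k: int, max_per_kmer: int | None = None) -> dict[str, list[int]]:
    """Map every k-mer (A/C/G/T only) of ``seq`` to its start positions.

    ``max_per_kmer`` drops hyper-abundant k-mers (simple-repeat seeds)
    entirely, which bounds downstream pair enumeration.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    if max_per_kmer is not None:
        index = {k_: v for k_, v in index.items() if len(v) <= max_per_kmer}
    return index


def chain_diagonal_matches(
    matches: list[tuple[int, int]],
    k: int,
    band: int = 32,
    max_gap: int = 500,
    min_seeds: int = 1,
) -> list[tuple[int, int, int, int, int]]:
    """Chain co-diagonal k-mer matches into blocks.

    ``matches`` are (query_pos, target_pos) pairs of exact k-mer hits.
    Matches whose diagonals (target_pos - query_pos) differ by at most
    ``band`` and that are separated by at most ``max_gap`` on the query are
    chained.  Returns (q_start, q_end, t_start, t_end, n_seeds) blocks with
    end coordinates exclusive, sorted by q_start.
    """
    if not matches:
        return []
    matches = sorted(matches, key=lambda m: (m[1] - m[0], m[0]))
    chains: list[tuple[int, int, int, int, int]] = []
    q0, t0 = matches[0]
    qs, qe, ts, te, n = q0, q0 + k, t0, t0 + k, 1
    prev_diag, prev_q = t0 - q0, q0
    for q, t in matches[1:]:
        diag = t - q
        if abs(diag - prev_diag) <= band and 0 <= q - prev_q <= max_gap:
            qe, te = max(qe, q + k), max(te, t + k)
            n += 1
        else:
            if n >= min_seeds:
                chains.append((qs, qe, ts, te, n))
            qs, qe, ts, te, n = q, q + k, t, t + k, 1
        prev_diag, prev_q = diag, q
    if n >= min_seeds:
        chains.append((qs, qe, ts, te, n))
    chains.sort(key=lambda c: c[0])
    return chains
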
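"""Repeat masking and genome-composition reporting.

The genome is masked sequentially with an ordered list of labelled
repeat libraries: each pass sees only the sequence left unmasked by the
previous passes, and the combined intervals are mutually disjoint, so
no base is counted twice in the composition report.  Matching is
seed-and-extend: exact shared 13-mers chained on diagonals, verified by
global (edit-distance) alignment of the chained segments; genome
segments at >= 80% identity over >= 80 bp inherit the library entry's
hierarchical ``class/superfamily`` label.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import pandas as pd

from .alignment import chain_diagonal_matches, kmer_positions


@dataclass
class RepeatInterval:
    contig: str
    start: int
    end: int
    label: str  # hierarchical, e.g. LTR/Copia, DNA/TIR, unknown
    source_pass: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocalNtHit:
    score: float  # matches - edits (edit-distance surrogate for +1/-1 scoring)
    identity: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]


def _seed_chains(query: str, target_index: dict[str, list[int]], k: int,
                 band: int = 32, max_gap: int = 200, min_seeds: int = 2):
    matches = []
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        for j in target_index.get(kmer, ()):
            matches.append((j, i))  # (genome_pos, library_pos)
    return chain_diagonal_matches(matches, k, band=band, max_gap=max_gap,
                                  min_seeds=min_seeds)


def _verify_segment(gseg: str, lseg: str) -> tuple[float, float]:
    """(score, identity) from a global edit-distance alignment."""
    res = edlib.align(gseg, lseg, mode="NW", task="distance")
    dist = res["editDistance"]
    aln_len = max(len(gseg), len(lseg))
    identity = 1.0 - dist / aln_len
    score = aln_len - 2 * dist  # matches minus penalties, +1/-1 flavour
    return score, identity


def best_local_nt_hit(query: str, target: str, k: int = 13) -> LocalNtHit | None:
    """Best chained-and-verified local match of ``query`` against ``target``.

    A fast surrogate for Smith-Waterman: exact k-mer seeds chained on
    diagonals, the chained span verified by edit-distance alignment.
    Cannot report a hit for pairs sharing no exact k-mer.
    """
    index = kmer_positions(target, k)
    chains = _seed_chains(query, index, k)
    best: LocalNtHit | None = None
    for ts, te, qs, qe, _ in chains:
        score, identity = _verify_segment(query[qs:qe], target[ts:te])
        hit = LocalNtHit(score=score, identity=identity,
                         query_span=(qs, qe), target_span=(ts, te))
        if best is None or hit.score > best.score:
            best = hit
    return best


def mask_with_library(genome: str, library: list[tuple[str, str, str]],
                      min_identity: float = 0.80, min_length: int = 80,
                      k: int = 13, contig: str = "chr1",
                      source_pass: str = "library") -> list[RepeatInterval]:
    """Mask ``genome`` with labelled library entries (name, label, seq).

    Overlapping hits from different entries are resolved by higher score
    (identity x length), the loser keeping only its non-overlapping part.
    """
    if not library:
        raise ValueError("empty library")
    genome_index = kmer_positions(genome, k)
    hits: list[tuple[float, int, int, str]] = []  # (score, gstart, gend, label)
    for name, label, seq in library:
        for gs, ge, ls, le, _ in _seed_chains(seq, genome_index, k):
            _, identity = _verify_segment(genome[gs:ge], seq[ls:le])
            if identity >= min_identity and ge - gs >= min_length:
                hits.append((identity * (ge - gs), gs, ge, label))
    hits.sort(key=lambda h: (-h[0], h[1]))
    covered: list[tuple[int, int]] = []
    out: list[RepeatInterval] = []
    for _, gs, ge, label in hits:
        for piece_s, piece_e in _subtract(gs, ge, covered):
            out.append(RepeatInterval(contig, piece_s, piece_e, label, source_pass))
            covered.append((piece_s, piece_e))
    out.sort(key=lambda r: r.start)
    return _merge_adjacent(out)


def _subtract(start: int, end: int, covered: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Parts of [start, end) not covered by any interval in ``covered``."""
    pieces = [(start, end)]
    for cs, ce in covered:
        next_pieces = []
        for s, e in pieces:
            if ce <= s or e <= cs:
                next_pieces.append((s, e))
                continue
            if s < cs:
                next_pieces.append((s, cs))
            if ce < e:
                next_pieces.append((ce, e))
        pieces = next_pieces
        if not pieces:
            break
    return [(s, e) for s, e in pieces if e > s]


def _merge_adjacent(intervals: list[RepeatInterval]) -> list[RepeatInterval]:
    merged: list[RepeatInterval] = []
    for iv in intervals:
        if (merged and merged[-1].end == iv.start
                and merged[-1].label == iv.label
                and merged[-1].source_pass == iv.source_pass):
            merged[-1].end = iv.end
        else:
            merged.append(iv)
    return merged


def sequential_mask(genome: str, passes: list[tuple[str, list[tuple[str, str, str]]]],
                    min_identity: float = 0.80, min_length: int = 80,
                    contig: str = "chr1") -> list[RepeatInterval]:
    """Run masking passes in order; later passes see only unmasked sequence.

    ``passes`` is an ordered list of (pass_name, library).  Intervals from
    a later pass are clipped against everything already masked, so the
    result is mutually non-overlapping and first-pass-wins on labels.
    """
    all_intervals: list[RepeatInterval] = []
    covered: list[tuple[int, int]] = []
    for pass_name, library in passes:
        if not library:
            continue
        raw = mask_with_library(genome, library, min_identity=min_identity,
                                min_length=min_length, contig=contig,
                                source_pass=pass_name)
        for iv in raw:
            for s, e in _subtract(iv.start, iv.end, covered):
                all_intervals.append(RepeatInterval(contig, s, e, iv.label, pass_name))
        covered.extend((iv.start, iv.end) for iv in all_intervals
                       if iv.source_pass == pass_name)
    all_intervals.sort(key=lambda r: (r.contig, r.start))
    return all_intervals


def soft_mask(genome: str, intervals: list[RepeatInterval]) -> str:
    """Lower-case the masked intervals of the genome."""
    chars = list(genome)
    for iv in intervals:
        chars[iv.start : iv.end] = [c.lower() for c in chars[iv.start : iv.end]]
    return "".join(chars)


def composition_report(intervals: list[RepeatInterval], genome_length: int) -> pd.DataFrame:
    """Per-label and per-class masked bp and percent of genome.

    Labels are hierarchical ``class/superfamily``; the report contains
    one row per label, one subtotal row per class, and a grand total.
    Input intervals must be non-overlapping (use :func:`sequential_mask`).
    """
    ordered = sorted(intervals, key=lambda r: (r.contig, r.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.contig == b.contig and b.start < a.end:
            raise ValueError(f"overlapping intervals at {a.contig}:{b.start}")
    rows = []
    by_label: dict[str, tuple[int, int]] = {}
    for iv in ordered:
        n, bp = by_label.get(iv.label, (0, 0))
        by_label[iv.label] = (n + 1, bp + iv.length)
    by_class: dict[str, tuple[int, int]] = {}
    for label, (n, bp) in sorted(by_label.items()):
        cls = label.split("/")[0]
        rows.append({"class": cls, "label": label, "n": n, "total_bp": bp,
                     "pct_genome": 100.0 * bp / genome_length})
        cn, cbp = by_class.get(cls, (0, 0))
        by_class[cls] = (cn + n, cbp + bp)
    for cls, (n, bp) in sorted(by_class.items()):
        rows.append({"class": cls, "label": f"{cls} (subtotal)", "n": n,
                     "total_bp": bp, "pct_genome": 100.0 * bp / genome_length})
    total_bp = sum(iv.length for iv in ordered)
    rows.append({"class": "all", "label": "total", "n": len(ordered),
                 "total_bp": total_bp, "pct_genome": 100.0 * total_bp / genome_length})
    return pd.DataFrame(rows, columns=["class", "label", "n", "total_bp", "pct_genome"])
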
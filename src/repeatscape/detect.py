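"""Signature-based detection of full-length LTR retrotransposon candidates.

A candidate is a pair of near-identical direct repeats (the LTRs)
whose starts are 1-20 kb apart, each 100-5000 bp long, at least 60%
identical, beginning TG and ending CA, and ideally flanked by a 4-8 bp
target-site duplication.  Detection is seed-and-chain (exact shared
12-mers on one diagonal band) followed by local-alignment refinement of
the LTR boundaries and terminus snapping.

Tandem arrays also contain well-separated direct repeats; a candidate
whose putative LTR continues into the adjacent internal sequence at
LTR-level identity is rejected as a tandem-array artefact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import nt_aligner, alignment_identity, global_nt_identity


@dataclass
class DetectorConfig:
    """Structural constraints on reported candidates."""

    ltr_min: int = 100
    ltr_max: int = 5000
    dist_min: int = 1000      # between LTR start positions
    dist_max: int = 20000
    min_similarity: float = 0.60
    tsd_min: int = 4
    tsd_max: int = 8
    require_tg_ca: bool = True
    seed_kmer: int = 12
    max_seed_gap: int = 600
    min_seeds: int = 3
    snap_window: int = 15     # terminus search radius around aligned ends
    refine_pad: int = 60
    max_per_kmer: int = 40    # drop hyper-abundant seed k-mers

    def __post_init__(self):
        if not self.ltr_min < self.ltr_max:
            raise ValueError("ltr_min must be < ltr_max")
        if not self.dist_min < self.dist_max:
            raise ValueError("dist_min must be < dist_max")
        if not 0.0 < self.min_similarity <= 1.0:
            raise ValueError("min_similarity must be in (0, 1]")


@dataclass
class LTRCandidate:
    contig: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_similarity: float
    tsd: str = ""
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


def ltr_similarity(ltr5: str, ltr3: str) -> float:
    """Fraction of identical columns in the optimal global alignment
    (gap columns excluded)."""
    return global_nt_identity(ltr5, ltr3)


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; windows containing non-ACGT get code -1."""
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = arr[j : j + n]
        codes = codes * 4 + np.where(window < 0, 0, window)
        bad |= window < 0
    codes[bad] = -1
    return codes


def find_direct_repeat_seeds(contig: str, cfg: DetectorConfig) -> list[dict]:
    """Chain exact k-mer matches into candidate direct-repeat regions.

    Returns regions as dicts with keys ltr5/ltr3 (approximate intervals)
    and n_seeds, for :func:`refine_boundaries`.
    """
    if len(contig) < cfg.dist_min:
        return []
    k = cfg.seed_kmer
    codes = _kmer_codes(contig, k)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    # run boundaries of equal codes
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(sorted_codes)]))
    matches: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        t = e - s
        if t < 2 or t > cfg.max_per_kmer or sorted_codes[s] < 0:
            continue
        pos = np.sort(order[s:e])
        for i in range(t - 1):
            for j in range(i + 1, t):
                sep = pos[j] - pos[i]
                if sep < cfg.dist_min:
                    continue
                if sep > cfg.dist_max:
                    break
                matches.append((int(pos[i]), int(pos[j])))

    from .alignment import chain_diagonal_matches

    chains = chain_diagonal_matches(matches, k, band=32,
                                    max_gap=cfg.max_seed_gap,
                                    min_seeds=cfg.min_seeds)
    regions = [
        {"ltr5": (qs, qe), "ltr3": (ts, te), "n_seeds": n}
        for qs, qe, ts, te, n in chains
        if qe <= ts  # LTR copies must not overlap
    ]
    return _merge_regions(regions)


def _merge_regions(regions: list[dict]) -> list[dict]:
    """Union regions whose 5' and 3' blocks both overlap."""
    regions = sorted(regions, key=lambda r: r["ltr5"])
    merged: list[dict] = []
    for region in regions:
        for prev in merged:
            if (_overlaps(prev["ltr5"], region["ltr5"])
                    and _overlaps(prev["ltr3"], region["ltr3"])):
                prev["ltr5"] = (min(prev["ltr5"][0], region["ltr5"][0]),
                                max(prev["ltr5"][1], region["ltr5"][1]))
                prev["ltr3"] = (min(prev["ltr3"][0], region["ltr3"][0]),
                                max(prev["ltr3"][1], region["ltr3"][1]))
                prev["n_seeds"] += region["n_seeds"]
                break
        else:
            merged.append(dict(region))
    return merged


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _snap_terminus(contig: str, pos: int, motif: str, window: int,
                   anchor: str = "start") -> int | None:
    """Nearest position within +/-window where the terminus motif sits.

    For ``anchor='start'`` the motif must begin at the returned position;
    for ``anchor='end'`` it must end at it (exclusive coordinate).
    """
    for delta in sorted(range(-window, window + 1), key=lambda d: (abs(d), d)):
        p = pos + delta
        if anchor == "start":
            if 0 <= p and contig[p : p + 2] == motif:
                return p
        else:
            if p >= 2 and contig[p - 2 : p] == motif:
                return p
    return None


def refine_boundaries(contig: str, region: dict, cfg: DetectorConfig,
                      contig_name: str = "chr1") -> LTRCandidate | None:
    """Align the two repeat copies, snap termini, and validate constraints."""
    pad = cfg.refine_pad
    a0 = max(0, region["ltr5"][0] - pad)
    a1 = min(len(contig), region["ltr5"][1] + pad)
    b0 = max(0, region["ltr3"][0] - pad)
    b1 = min(len(contig), region["ltr3"][1] + pad)
    w5, w3 = contig[a0:a1], contig[b0:b1]
    if not w5 or not w3:
        return None
    aligner = nt_aligner("local")
    alignments = aligner.align(w5, w3)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    blocks5, blocks3 = aln.aligned
    if len(blocks5) == 0:
        return None
    l5s, l5e = a0 + int(blocks5[0][0]), a0 + int(blocks5[-1][1])
    l3s, l3e = b0 + int(blocks3[0][0]), b0 + int(blocks3[-1][1])

    if cfg.require_tg_ca:
        snapped = []
        for pos, motif, anchor in ((l5s, "TG", "start"), (l3s, "TG", "start"),
                                   (l5e, "CA", "end"), (l3e, "CA", "end")):
            s = _snap_terminus(contig, pos, motif, cfg.snap_window, anchor)
            if s is None:
                return None
            snapped.append(s)
        l5s, l3s, l5e, l3e = snapped

    len5, len3 = l5e - l5s, l3e - l3s
    if min(len5, len3) <= 0:
        return None
    for length in (len5, len3):
        if not cfg.ltr_min <= length <= cfg.ltr_max:
            return None
    if max(len5, len3) > 1.2 * min(len5, len3):
        return None
    if l5e > l3s:
        return None
    if not cfg.dist_min <= l3s - l5s <= cfg.dist_max:
        return None

    ltr5_seq, ltr3_seq = contig[l5s:l5e], contig[l3s:l3e]
    similarity = ltr_similarity(ltr5_seq, ltr3_seq)
    if similarity < cfg.min_similarity:
        return None

    # tandem-array guard: a true LTR must not continue into the internal
    # region; in a satellite array the "LTR" repeats on both sides.
    inner5 = contig[l5e : l5e + len5]
    inner3 = contig[max(0, l3s - len3) : l3s]
    if len(inner5) >= cfg.ltr_min and global_nt_identity(ltr5_seq, inner5) >= cfg.min_similarity:
        return None
    if len(inner3) >= cfg.ltr_min and global_nt_identity(ltr3_seq, inner3) >= cfg.min_similarity:
        return None

    return LTRCandidate(contig=contig_name, start=l5s, end=l3e,
                        ltr5=(l5s, l5e), ltr3=(l3s, l3e),
                        ltr_similarity=similarity)


def verify_tsd(contig: str, candidate: LTRCandidate, cfg: DetectorConfig) -> str:
    """Longest exact 4-8 bp match between the flanks; '' if none."""
    if candidate.start < cfg.tsd_max or candidate.end + cfg.tsd_max > len(contig):
        warnings.warn("insufficient flank for TSD verification", stacklevel=2)
        return ""
    for length in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
        left = contig[candidate.start - length : candidate.start]
        right = contig[candidate.end : candidate.end + length]
        if left == right:
            return left
    return ""


def _dedup_candidates(candidates: list[LTRCandidate]) -> list[LTRCandidate]:
    """Overlapping candidates: keep higher similarity, then longer element."""
    ordered = sorted(candidates,
                     key=lambda c: (-c.ltr_similarity, -c.length, c.start))
    kept: list[LTRCandidate] = []
    for cand in ordered:
        if any(c.contig == cand.contig and _overlaps((c.start, c.end), (cand.start, cand.end))
               for c in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: (c.contig, c.start))
    return kept


def detect_ltr_candidates(contig: str, cfg: DetectorConfig | None = None,
                          contig_name: str = "chr1") -> list[LTRCandidate]:
    """Full detection on one contig: seed, refine, TSD-verify, dedup."""
    cfg = cfg or DetectorConfig()
    regions = find_direct_repeat_seeds(contig, cfg)
    candidates = []
    for region in regions:
        cand = refine_boundaries(contig, region, cfg, contig_name)
        if cand is None:
            continue
        cand.tsd = verify_tsd(contig, cand, cfg)
        candidates.append(cand)
    return _dedup_candidates(candidates)


def detect_genome(contigs: dict[str, str],
                  cfg: DetectorConfig | None = None) -> list[LTRCandidate]:
    """Run detection over every contig of a genome."""
    cfg = cfg or DetectorConfig()
    out: list[LTRCandidate] = []
    for name in contigs:  # insertion order; coordinates are per-contig
        out.extend(detect_ltr_candidates(contigs[name], cfg, contig_name=name))
    return out
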
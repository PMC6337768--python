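"""Satellite DNA discovery from unassembled reads.

Reads are compared all-against-all (with an exact-13-mer prefilter that
can only prune, never add, pairs); two reads are connected when a local
alignment covers at least 55% of the shorter read at 90% or better
identity.  Connected components of this similarity graph are repeat
clusters; clusters whose reads are generated by one dominant sequence
cycle (tandem arrays) are classified circular, clusters dominated by a
single hub read are star-like, everything else is linear/other.  For
circular/star clusters the monomer length and consensus come from a
greedy maximum-weight walk of the k=21 de Bruijn graph, and the
cluster's genome proportion is its read count over all sampled reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np

from .alignment import nt_aligner, revcomp
from .simulate import as_rng

MIN_SIMILARITY = 0.90
MIN_COVERAGE = 0.55
PREFILTER_K = 13
DEBRUIJN_K = 21
MIN_TOPOLOGY_CLUSTER = 20
MIN_CYCLE_SUPPORT = 0.70


@dataclass
class ReadCluster:
    member_read_ids: list[str]
    topology: str = "linear/other"  # circular | star | linear/other
    monomer_length: int | None = None
    consensus: str | None = None
    genome_proportion: float = 0.0

    @property
    def size(self) -> int:
        return len(self.member_read_ids)


def sample_reads(reads: list[tuple[str, str]], n: int, seed) -> list[tuple[str, str]]:
    """Uniform sample of ``n`` reads without replacement."""
    if n > len(reads):
        raise ValueError("cannot sample more reads than available")
    rng = as_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]


def _read_edge(a: str, b: str, min_similarity: float, min_coverage: float) -> bool:
    """Edge rule: local alignment covering >= min_coverage of the shorter
    read at >= min_similarity identity, on either strand."""
    aligner = nt_aligner("local")
    shorter = min(len(a), len(b))
    # conservative score lower bound for any qualifying alignment:
    # >=55% of the shorter read aligned at >=90% identity scores at least
    # 0.55 * L * (0.9 - 4 * 0.1) even if every non-match opens a gap
    score_floor = min(30.0, min_coverage * shorter * (2 * min_similarity - 1) * 0.5)
    for target in (b, revcomp(b)):
        if aligner.score(a, target) < score_floor:
            continue
        alignments = aligner.align(a, target)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        counts = aln.counts()
        aligned = counts.identities + counts.mismatches
        if aligned == 0:
            continue
        identity = counts.identities / aligned
        blocks_a, blocks_b = aln.aligned
        span_a = int(blocks_a[-1][1] - blocks_a[0][0])
        span_b = int(blocks_b[-1][1] - blocks_b[0][0])
        coverage = (span_a if len(a) <= len(b) else span_b) / shorter
        if identity >= min_similarity and coverage >= min_coverage:
            return True
    return False


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_similarity_graph(reads: list[tuple[str, str]],
                           min_similarity: float = MIN_SIMILARITY,
                           min_coverage: float = MIN_COVERAGE,
                           prefilter_k: int | None = PREFILTER_K,
                           min_shared_kmers: int = 2) -> nx.Graph:
    """Similarity graph over reads (nodes are read ids).

    With ``prefilter_k`` set, only pairs sharing at least
    ``min_shared_kmers`` exact canonical k-mers are aligned; a pair
    satisfying the 90%/55% rule shares dozens of 13-mers, so the
    prefilter prunes chance collisions without creating edges.  Pass
    ``prefilter_k=None`` for the exhaustive all-pairs version.
    """
    if not reads:
        return nx.Graph()
    graph = nx.Graph()
    graph.add_nodes_from(rid for rid, _ in reads)
    seqs = dict(reads)
    if prefilter_k is None:
        pairs = {(reads[i][0], reads[j][0])
                 for i in range(len(reads)) for j in range(i + 1, len(reads))}
    else:
        buckets: dict[str, list[str]] = {}
        for rid, seq in reads:
            seen = set()
            for i in range(len(seq) - prefilter_k + 1):
                kmer = _canonical(seq[i : i + prefilter_k])
                if "N" not in kmer and kmer not in seen:
                    seen.add(kmer)
                    buckets.setdefault(kmer, []).append(rid)
        shared: Counter[tuple[str, str]] = Counter()
        for members in buckets.values():
            if len(members) < 2 or len(members) > 2000:
                continue
            for i in range(len(members) - 1):
                for j in range(i + 1, len(members)):
                    a, b = members[i], members[j]
                    shared[(a, b) if a < b else (b, a)] += 1
        pairs = {p for p, c in shared.items() if c >= min_shared_kmers}
    for a, b in sorted(pairs):
        if _read_edge(seqs[a], seqs[b], min_similarity, min_coverage):
            graph.add_edge(a, b)
    return graph


def cluster_graph(graph: nx.Graph) -> list[list[str]]:
    """Connected components, size-sorted descending, singletons dropped."""
    comps = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def _orient_reads(seqs: list[str], k: int = PREFILTER_K) -> list[str]:
    """Flip reads onto the strand sharing more k-mers with the longest read."""
    ref = max(seqs, key=len)
    ref_kmers = {ref[i : i + k] for i in range(len(ref) - k + 1)}
    oriented = []
    for seq in seqs:
        fwd = sum(seq[i : i + k] in ref_kmers for i in range(len(seq) - k + 1))
        rc = revcomp(seq)
        rev = sum(rc[i : i + k] in ref_kmers for i in range(len(rc) - k + 1))
        oriented.append(rc if rev > fwd else seq)
    return oriented


def _dominant_cycle(seqs: list[str], k: int = DEBRUIJN_K,
                    max_steps: int = 50000) -> str | None:
    """Greedy max-weight walk of the de Bruijn graph; returns the cycle
    sequence (one monomer unit) or None if the walk never closes."""
    counts: Counter[str] = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    if not counts:
        return None
    start = max(sorted(counts), key=lambda km: counts[km])
    path = [start]
    index = {start: 0}
    for _ in range(max_steps):
        prefix = path[-1][1:]
        candidates = [(counts[prefix + b], prefix + b) for b in "ACGT"
                      if counts.get(prefix + b, 0) > 0]
        if not candidates:
            return None
        candidates.sort(key=lambda c: (-c[0], c[1]))
        nxt = candidates[0][1]
        if nxt in index:
            cycle_nodes = path[index[nxt]:]
            return "".join(node[0] for node in cycle_nodes)
        index[nxt] = len(path)
        path.append(nxt)
    return None


def _cycle_support(seqs: list[str], consensus: str, min_identity: float = 0.85,
                   min_read_coverage: float = 0.80) -> float:
    """Fraction of reads that align to the tandem-repeated consensus."""
    if not consensus:
        return 0.0
    reps = max(2, int(np.ceil(max(len(s) for s in seqs) / len(consensus))) + 1)
    target = consensus * reps
    supported = 0
    for seq in seqs:
        best = None
        for query in (seq, revcomp(seq)):
            res = edlib.align(query, target, mode="HW", task="distance")
            d = res["editDistance"]
            if d >= 0 and (best is None or d < best):
                best = d
        if best is None:
            continue
        identity = 1.0 - best / len(seq)
        if identity >= min_identity:
            supported += 1
    return supported / len(seqs)


def _autocorrelation_period(seq: str, min_lag: int = 20,
                            max_lag: int | None = None) -> int | None:
    """Smallest strong self-match lag (tandem period) of a read."""
    n = len(seq)
    max_lag = max_lag or n // 2
    best = None
    for lag in range(min_lag, max_lag + 1):
        matches = sum(1 for i in range(n - lag) if seq[i] == seq[i + lag])
        frac = matches / (n - lag)
        if frac >= 0.8 and (best is None or frac > best[0]):
            best = (frac, lag)
    return best[1] if best else None


def classify_topology(cluster: list[str], reads: dict[str, str],
                      graph: nx.Graph | None = None,
                      min_cluster: int = MIN_TOPOLOGY_CLUSTER,
                      min_support: float = MIN_CYCLE_SUPPORT) -> tuple[str, str | None]:
    """(topology, cycle_consensus) of one cluster.

    Circular: a single dominant de Bruijn cycle explains >= min_support
    of the member reads.  Star: no cycle, but one hub read is connected
    to >= 70% of the cluster.  Otherwise (or below ``min_cluster``
    members): linear/other.
    """
    if len(cluster) < min_cluster:
        return "linear/other", None
    seqs = _orient_reads([reads[r] for r in cluster])
    consensus = _dominant_cycle(seqs)
    if consensus is not None and len(consensus) >= DEBRUIJN_K:
        if _cycle_support(seqs, consensus) >= min_support:
            return "circular", consensus
    if graph is not None:
        sub = graph.subgraph(cluster)
        max_deg = max(dict(sub.degree()).values())
        if max_deg >= 0.7 * (len(cluster) - 1):
            return "star", None
    return "linear/other", None


def estimate_monomer(cluster: list[str], reads: dict[str, str],
                     topology: str, cycle_consensus: str | None = None) -> tuple[int | None, str | None]:
    """(monomer_length, consensus) for a circular or star cluster."""
    if topology not in ("circular", "star"):
        raise ValueError("monomer defined only for circular/star clusters")
    if topology == "circular" and cycle_consensus:
        return len(cycle_consensus), cycle_consensus
    seqs = _orient_reads([reads[r] for r in cluster])
    if topology == "circular":
        consensus = _dominant_cycle(seqs)
        if consensus is None:
            raise ValueError("no dominant cycle")
        return len(consensus), consensus
    # star: period of the hub read's self-similarity
    hub = max(seqs, key=len)
    period = _autocorrelation_period(hub)
    if period is None:
        return None, None
    return period, hub[:period]


def genome_proportion(cluster: list[str], total_reads: int) -> float:
    """Cluster read count over all sampled reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return len(cluster) / total_reads


def discover_satellites(reads: list[tuple[str, str]], n_sample: int | None = None,
                        seed=0, min_similarity: float = MIN_SIMILARITY,
                        min_coverage: float = MIN_COVERAGE) -> list[ReadCluster]:
    """End-to-end satellite discovery on a read set.

    Returns every non-singleton cluster with topology, monomer estimate
    (circular/star only) and genome proportion, largest first.
    """
    if n_sample is not None and n_sample < len(reads):
        reads = sample_reads(reads, n_sample, seed)
    total = len(reads)
    seqs = dict(reads)
    graph = build_similarity_graph(reads, min_similarity, min_coverage)
    out = []
    for members in cluster_graph(graph):
        topology, consensus = classify_topology(members, seqs, graph)
        cluster = ReadCluster(member_read_ids=members, topology=topology,
                              genome_proportion=genome_proportion(members, total))
        if topology in ("circular", "star"):
            cluster.monomer_length, cluster.consensus = estimate_monomer(
                members, seqs, topology, consensus)
        out.append(cluster)
    return out
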
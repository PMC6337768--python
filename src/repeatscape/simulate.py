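"""Synthetic genomes with planted repeats and a machine-readable truth table.

The generator emulates the statistical structure the annotation pipeline
assumes: LTR retrotransposons inserted as [TSD][5'LTR][internal][3'LTR][TSD]
whose two LTRs were identical at insertion and have since diverged under a
Kimura two-parameter substitution process at rate ``r`` per site per year;
terminal-inverted-repeat (TIR/MITE) elements; tandem satellite arrays of
mutated monomer copies; and uniformly sampled shotgun reads.  Every planted
feature is recorded in a truth table so recovery can be scored exactly.

Mutations are substitutions only by default (an optional indel rate
exercises gap handling in the dating aligner); transitions are drawn
``ts_tv_ratio`` times as often as each transversion class, so the expected
pairwise K2P distance between the two LTRs of an element of age T is 2rT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import references
from .alignment import revcomp
from .references import ReferenceLibrary, DOMAIN_ORDER, back_translate, default_library

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# index order A=0 C=1 G=2 T=3; transitions are A<->G, C<->T
_TS_MAP = np.array([2, 3, 0, 1])
_TV1_MAP = np.array([1, 0, 1, 0])
_TV2_MAP = np.array([3, 2, 3, 2])

LTR_CLASS = "LTR-RE"
TIR_CLASS = "TIR"
SATELLITE_CLASS = "satellite-array"
LIBRARY_CLASS = "library-copy"

TRUTH_COLUMNS = [
    "element_id", "element_class", "contig", "start", "end",
    "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end", "tsd",
    "planted_age", "superfamily", "lineage", "has_pbs", "has_ppt",
    "domain_order", "monomer_length",
]


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Defaults are the pipeline's standard test conditions: a 2-Mb genome,
    50 LTR retroelements with 300-1500 bp LTRs inserted 0-3 Myr ago at a
    substitution rate of 1.3e-8 /site/yr, moderately AT-rich background
    (GC 0.36, typical of plant intergenic sequence).
    """

    genome_length: int = 2_000_000
    gc_content: float = 0.36
    n_ltr_elements: int = 50
    ltr_length_range: tuple[int, int] = (300, 1500)
    internal_length_range: tuple[int, int] = (2500, 7000)
    age_range: tuple[float, float] = (0.0, 3.0e6)
    substitution_rate: float = 1.3e-8
    ts_tv_ratio: float = 2.0
    indel_rate: float = 0.0  # per-site per-branch; off by default
    n_decoy_elements: int = 0  # feature-free LTR-REs (filter test cases)
    n_tir_elements: int = 0
    satellite_specs: tuple[tuple[int, int, float], ...] = ()
    n_library_copies: int = 0  # mutated copies of bundled nucleotide repeats
    read_length: int = 301
    n_reads: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        lo, hi = self.age_range
        if lo < 0 or hi > 2.0e7 or lo > hi:
            raise ValueError("age_range must lie within [0, 2e7]")
        lo, hi = self.ltr_length_range
        if lo <= 0 or lo >= hi:
            raise ValueError("invalid ltr_length_range")
        for monomer, copies, div in self.satellite_specs:
            if copies < 2:
                raise ValueError("satellite arrays need >= 2 copies")
            if monomer <= 0:
                raise ValueError("monomer_length must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one planted element."""

    element_id: str
    element_class: str
    contig: str
    start: int
    end: int
    ltr5_start: int = -1
    ltr5_end: int = -1
    ltr3_start: int = -1
    ltr3_end: int = -1
    tsd: str = ""
    planted_age: float = 0.0
    superfamily: str = "unknown"
    lineage: str = "unknown"
    has_pbs: bool = False
    has_ppt: bool = False
    domain_order: str = ""
    monomer_length: int = 0

    def __post_init__(self):
        if self.planted_age < 0:
            raise ValueError("planted_age must be >= 0")
        if self.tsd and not 4 <= len(self.tsd) <= 8 and self.element_class == LTR_CLASS:
            raise ValueError("LTR-RE TSD length must be in [4, 8]")
        if self.ltr5_start >= 0:
            if not (self.start <= self.ltr5_start < self.ltr5_end
                    <= self.ltr3_start < self.ltr3_end <= self.end):
                raise ValueError("LTR intervals must nest within [start, end)")


# --- elementary operations -------------------------------------------------


def generate_background(length: int, gc: float, seed) -> str:
    """I.i.d. nucleotide sequence of exact ``length`` with expected GC ``gc``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = as_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list(BASES))[idx])


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _k2p_category_probs(distance: float, ts_tv_ratio: float) -> tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) after one branch.

    ``distance`` is the expected number of substitutions per site on the
    branch; transition rate alpha and per-class transversion rate beta
    satisfy alpha + 2 beta = rate and alpha/beta = ts_tv_ratio.
    """
    if distance == 0:
        return 1.0, 0.0, 0.0
    kappa = ts_tv_ratio
    beta_t = distance / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    p_tv_each = 0.25 - 0.25 * np.exp(-4.0 * beta_t)
    return 1.0 - p_ts - 2.0 * p_tv_each, float(p_ts), float(p_tv_each)


def evolve_sequence(seq: str, distance: float, ts_tv_ratio: float, seed,
                    indel_rate: float = 0.0) -> str:
    """Evolve ``seq`` along one branch of expected length ``distance`` subs/site."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    rng = as_rng(seed)
    arr = np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    p_same, p_ts, p_tv = _k2p_category_probs(distance, ts_tv_ratio)
    u = rng.random(arr.size)
    out = arr.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = u >= p_same + p_ts + p_tv
    out[ts_mask] = _TS_MAP[arr[ts_mask]]
    out[tv1_mask] = _TV1_MAP[arr[tv1_mask]]
    out[tv2_mask] = _TV2_MAP[arr[tv2_mask]]
    result = "".join(BASES[i] for i in out)
    if indel_rate > 0:
        result = _apply_indels(result, indel_rate, rng)
    return result


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Sprinkle short (1-3 bp) insertions/deletions at ``rate`` per site."""
    n = rng.poisson(rate * len(seq))
    chars = list(seq)
    for _ in range(n):
        pos = int(rng.integers(len(chars)))
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            del chars[pos : pos + size]
        else:
            ins = "".join(BASES[rng.integers(4)] for _ in range(size))
            chars[pos:pos] = list(ins)
    return "".join(chars)


def evolve_ltr_pair(ancestral_ltr: str, age: float, r: float, ts_tv_ratio: float,
                    seed, indel_rate: float = 0.0) -> tuple[str, str]:
    """Two independently evolved copies of an ancestral LTR.

    Each copy accumulates an expected ``r * age`` substitutions per site,
    so the expected pairwise K2P distance between the copies is 2 r T.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    rng = as_rng(seed)
    d = r * age
    ltr5 = evolve_sequence(ancestral_ltr, d, ts_tv_ratio, rng, indel_rate)
    ltr3 = evolve_sequence(ancestral_ltr, d, ts_tv_ratio, rng, indel_rate)
    return ltr5, ltr3


def _force_termini(ltr: str) -> str:
    """LTRs begin TG and end CA (the detector requires these termini)."""
    return "TG" + ltr[2:-2] + "CA"


def _random_tsd(rng: np.random.Generator, length: int | None = None) -> str:
    n = int(rng.integers(4, 9)) if length is None else length
    return "".join(BASES[rng.integers(4)] for _ in range(n))


def build_ltr_element(rng: np.random.Generator, refs: ReferenceLibrary, *,
                      ltr_length: int, internal_length: int, age: float,
                      superfamily: str, lineage: str, r: float = 1.3e-8,
                      ts_tv_ratio: float = 2.0, has_pbs: bool = True,
                      has_ppt: bool = True, domain_order: tuple[str, ...] | None = None,
                      tsd: str | None = None, gc: float = 0.36,
                      indel_rate: float = 0.0) -> dict:
    """Assemble the sequence parts of one LTR retroelement.

    Returns a dict with keys tsd, ltr5, internal, ltr3 plus the feature
    metadata needed to fill a TruthRecord.
    """
    if domain_order is None:
        domain_order = DOMAIN_ORDER[superfamily] if superfamily in DOMAIN_ORDER else ()
    tsd = _random_tsd(rng) if tsd is None else tsd
    ancestral = _force_termini(generate_background(ltr_length, gc, rng))
    ltr5, ltr3 = evolve_ltr_pair(ancestral, age, r, ts_tv_ratio, rng, indel_rate)
    ltr5, ltr3 = _force_termini(ltr5), _force_termini(ltr3)

    parts: list[str] = []
    parts.append(generate_background(int(rng.integers(1, 5)), gc, rng))
    if has_pbs:
        trna_id = sorted(refs.trna)[int(rng.integers(len(refs.trna)))]
        pbs_len = int(rng.integers(15, 19))
        parts.append(revcomp(refs.trna[trna_id][-pbs_len:]))
    parts.append(generate_background(int(rng.integers(30, 80)), gc, rng))
    for domain in domain_order:
        pep = refs.rt_for(superfamily, lineage) if (
            domain == "RT" and (superfamily, lineage) in refs.rt_lineage
        ) else refs.domain_consensus[domain]
        parts.append(back_translate(pep))
        parts.append(generate_background(30, gc, rng))
    assembled = sum(len(p) for p in parts)
    tail_features = 40  # room for spacer + PPT + end pad
    if assembled + tail_features < internal_length:
        parts.append(generate_background(internal_length - assembled - tail_features, gc, rng))
    if has_ppt:
        parts.append(generate_background(int(rng.integers(10, 25)), gc, rng))
        ppt_len = int(rng.integers(12, 26))
        parts.append("".join("AG"[rng.integers(2)] for _ in range(ppt_len)))
        parts.append(generate_background(int(rng.integers(1, 5)), gc, rng))
    else:
        # feature switched off: suppress chance purine tracts near the
        # 3' boundary so the decoy is genuinely PPT-free (every third
        # base pyrimidine caps any 10-mer window below the 0.85 floor)
        tail = []
        for i in range(60):
            if i % 3 == 0:
                tail.append("CT"[rng.integers(2)])
            else:
                tail.append(BASES[rng.integers(4)])
        parts.append("".join(tail))
    internal = evolve_sequence("".join(parts), r * age, ts_tv_ratio, rng, indel_rate)
    return {
        "tsd": tsd, "ltr5": ltr5, "ltr3": ltr3, "internal": internal,
        "age": age, "superfamily": superfamily, "lineage": lineage,
        "has_pbs": has_pbs, "has_ppt": has_ppt, "domain_order": domain_order,
    }


def plant_ltr_element(genome: str, position: int, element: dict, *,
                      contig: str = "chr1", element_id: str = "LTRRE_1") -> tuple[str, TruthRecord]:
    """Insert [TSD][5'LTR][internal][3'LTR][TSD] at ``position``.

    ``element`` comes from :func:`build_ltr_element`.  Coordinates in the
    returned TruthRecord are 0-based half-open on the post-insertion
    genome; start/end delimit the element proper (TSD copies flank it).
    """
    tsd, ltr5, ltr3, internal = element["tsd"], element["ltr5"], element["ltr3"], element["internal"]
    insert = tsd + ltr5 + internal + ltr3 + tsd
    if position < 0 or position > len(genome):
        raise ValueError("position out of range")
    genome_out = genome[:position] + insert + genome[position:]
    start = position + len(tsd)
    ltr5_start = start
    ltr5_end = ltr5_start + len(ltr5)
    ltr3_start = ltr5_end + len(internal)
    ltr3_end = ltr3_start + len(ltr3)
    truth = TruthRecord(
        element_id=element_id, element_class=LTR_CLASS, contig=contig,
        start=start, end=ltr3_end,
        ltr5_start=ltr5_start, ltr5_end=ltr5_end,
        ltr3_start=ltr3_start, ltr3_end=ltr3_end,
        tsd=tsd, planted_age=element["age"],
        superfamily=element["superfamily"], lineage=element["lineage"],
        has_pbs=element["has_pbs"], has_ppt=element["has_ppt"],
        domain_order=",".join(element["domain_order"]),
    )
    return genome_out, truth


def plant_satellite_array(genome: str, position: int, monomer_length: int,
                          copies: int, divergence: float, seed, *,
                          ts_tv_ratio: float = 2.0, gc: float = 0.36,
                          contig: str = "chr1", element_id: str = "SAT_1",
                          occupied: list[tuple[int, int]] | None = None) -> tuple[str, TruthRecord]:
    """Insert a tandem array of independently mutated monomer copies."""
    if copies < 2:
        raise ValueError("copies must be >= 2")
    if occupied:
        for s, e in occupied:
            if s <= position < e:
                raise ValueError(f"position {position} overlaps planted element [{s},{e})")
    rng = as_rng(seed)
    monomer = generate_background(monomer_length, gc, rng)
    array = "".join(
        evolve_sequence(monomer, divergence, ts_tv_ratio, rng) for _ in range(copies)
    )
    if position < 0 or position > len(genome):
        raise ValueError("position out of range")
    genome_out = genome[:position] + array + genome[position:]
    truth = TruthRecord(
        element_id=element_id, element_class=SATELLITE_CLASS, contig=contig,
        start=position, end=position + len(array), monomer_length=monomer_length,
    )
    return genome_out, truth


def build_tir_element(rng: np.random.Generator, *, tir_length: int = 25,
                      total_length: int = 300, tsd: str = "TA",
                      gc: float = 0.36) -> dict:
    """A MITE-like element: TSD + TIR + internal + revcomp(TIR) + TSD."""
    internal_len = max(total_length - 2 * tir_length, 10)
    tir = generate_background(tir_length, gc, rng)
    internal = generate_background(internal_len, gc, rng)
    return {"tsd": tsd, "tir": tir, "internal": internal}


def plant_tir_element(genome: str, position: int, element: dict, *,
                      contig: str = "chr1", element_id: str = "TIR_1") -> tuple[str, TruthRecord]:
    tsd, tir, internal = element["tsd"], element["tir"], element["internal"]
    insert = tsd + tir + internal + revcomp(tir) + tsd
    if position < 0 or position > len(genome):
        raise ValueError("position out of range")
    genome_out = genome[:position] + insert + genome[position:]
    start = position + len(tsd)
    end = start + len(tir) * 2 + len(internal)
    truth = TruthRecord(
        element_id=element_id, element_class=TIR_CLASS, contig=contig,
        start=start, end=end, tsd=tsd,
    )
    return genome_out, truth


def simulate_reads(genome: str, n_reads: int, read_length: int, seed) -> list[tuple[str, str]]:
    """Uniform shotgun reads from both strands as (read_id, sequence).

    Read ids encode origin (start position and strand) for debugging;
    downstream code must not rely on them.
    """
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = as_rng(seed)
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads = []
    for i, (s, rev) in enumerate(zip(starts, strands)):
        seq = genome[int(s) : int(s) + read_length]
        if rev:
            seq = revcomp(seq)
        reads.append((f"read_{i}|{int(s)}|{'-' if rev else '+'}", seq))
    return reads


# --- whole-genome assembly -------------------------------------------------


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    contigs: dict[str, str]
    truth: pd.DataFrame
    reads: list[tuple[str, str]] = field(default_factory=list)

    @property
    def genome(self) -> str:
        return self.contigs["chr1"]


def _choose_positions(rng: np.random.Generator, n: int, length: int,
                      margin: int = 1000, min_gap: int = 400) -> list[int]:
    for _ in range(200):
        pos = np.sort(rng.integers(margin, length - margin, size=n))
        if n <= 1 or np.all(np.diff(pos) >= min_gap):
            return [int(p) for p in pos]
    raise RuntimeError("could not place elements without overlap; genome too small")


def simulate_genome(config: SimulationConfig,
                    refs: ReferenceLibrary | None = None) -> SimulatedGenome:
    """Generate the full synthetic genome described by ``config``.

    Elements are planted left to right at background positions at least
    400 bp apart, so truth intervals never overlap and the final genome
    length is the background length plus the sum of inserted sequence.
    """
    refs = refs or default_library()
    rng = as_rng(config.seed)
    lineage_cycle = sorted(refs.rt_lineage)  # (superfamily, lineage), deterministic
    genome = generate_background(config.genome_length, config.gc_content, rng)

    plans: list[tuple[str, dict]] = []
    for i in range(config.n_ltr_elements):
        superfamily, lineage = lineage_cycle[i % len(lineage_cycle)]
        age = float(rng.uniform(*config.age_range))
        plans.append(("ltr", {
            "ltr_length": int(rng.integers(config.ltr_length_range[0],
                                           config.ltr_length_range[1] + 1)),
            "internal_length": int(rng.integers(config.internal_length_range[0],
                                                config.internal_length_range[1] + 1)),
            "age": age, "superfamily": superfamily, "lineage": lineage,
            "has_pbs": True, "has_ppt": True,
        }))
    for _ in range(config.n_decoy_elements):
        age = float(rng.uniform(*config.age_range))
        plans.append(("ltr", {
            "ltr_length": int(rng.integers(config.ltr_length_range[0],
                                           config.ltr_length_range[1] + 1)),
            "internal_length": int(rng.integers(config.internal_length_range[0],
                                                config.internal_length_range[1] + 1)),
            "age": age, "superfamily": "unknown", "lineage": "unknown",
            "has_pbs": False, "has_ppt": False, "domain_order": (),
        }))
    for _ in range(config.n_tir_elements):
        plans.append(("tir", {
            "tir_length": int(rng.integers(20, 31)),
            "total_length": int(rng.integers(200, 601)),
        }))
    for monomer, copies, div in config.satellite_specs:
        plans.append(("sat", {"monomer_length": monomer, "copies": copies,
                              "divergence": div}))
    for i in range(config.n_library_copies):
        name, label, seq = refs.repeat_nt[i % len(refs.repeat_nt)]
        plans.append(("lib", {"name": name, "label": label, "seq": seq}))

    rng.shuffle(plans)  # interleave element types along the genome
    positions = _choose_positions(rng, len(plans), config.genome_length) if plans else []

    records: list[TruthRecord] = []
    offset = 0
    counters = {"ltr": 0, "tir": 0, "sat": 0, "lib": 0}
    for pos_bg, (kind, spec) in zip(positions, plans):
        pos = pos_bg + offset
        counters[kind] += 1
        before = len(genome)
        if kind == "ltr":
            element = build_ltr_element(
                rng, refs, r=config.substitution_rate,
                ts_tv_ratio=config.ts_tv_ratio, gc=config.gc_content,
                indel_rate=config.indel_rate, **spec)
            genome, truth = plant_ltr_element(
                genome, pos, element, element_id=f"LTRRE_{counters['ltr']:04d}")
        elif kind == "tir":
            element = build_tir_element(rng, gc=config.gc_content, **spec)
            genome, truth = plant_tir_element(
                genome, pos, element, element_id=f"TIR_{counters['tir']:04d}")
        elif kind == "sat":
            genome, truth = plant_satellite_array(
                genome, pos, seed=rng, ts_tv_ratio=config.ts_tv_ratio,
                gc=config.gc_content, element_id=f"SAT_{counters['sat']:04d}", **spec)
        else:  # library copy, mutated ~5%
            copy = evolve_sequence(spec["seq"], 0.05, config.ts_tv_ratio, rng)
            genome = genome[:pos] + copy + genome[pos:]
            truth = TruthRecord(
                element_id=f"LIB_{counters['lib']:04d}", element_class=LIBRARY_CLASS,
                contig="chr1", start=pos, end=pos + len(copy),
                lineage=spec["label"])
        offset += len(genome) - before
        records.append(truth)

    truth_df = pd.DataFrame([asdict(r) for r in records], columns=TRUTH_COLUMNS)
    sim = SimulatedGenome(config=config, contigs={"chr1": genome}, truth=truth_df)
    if config.n_reads > 0:
        sim.reads = simulate_reads(genome, config.n_reads, config.read_length, rng)
    return sim
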
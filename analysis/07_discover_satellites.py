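#!/usr/bin/env python
"""Satellite DNA discovery from the simulated read set.

Builds the read-similarity graph (90% identity over >=55% of the
shorter read), takes connected components, classifies cluster topology,
and estimates monomer length/consensus and genome proportion for
circular/star clusters.  Writes satellites.tsv, satellite_consensus.fasta
and a position-frequency matrix per satellite.
"""

from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from repeatscape import io as rio
from repeatscape.satellites import discover_satellites

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "satellites"


def position_frequency_matrix(reads: list[str], consensus: str) -> pd.DataFrame:
    """Per-monomer-position base counts from reads aligned to the
    tandem-repeated consensus."""
    m = len(consensus)
    target = consensus * (int(np.ceil(max(map(len, reads)) / m)) + 2)
    counts = np.zeros((m, 4), dtype=int)
    base_index = {b: i for i, b in enumerate("ACGT")}
    for seq in reads:
        res = edlib.align(seq, target, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        tpos = res["locations"][0][0]
        qpos = 0
        for token in _cigar_tokens(res["cigar"]):
            n, op = token
            if op in ("=", "X", "M"):
                for k in range(n):
                    base = seq[qpos + k]
                    if base in base_index:
                        counts[(tpos + k) % m, base_index[base]] += 1
                qpos += n
                tpos += n
            elif op == "I":
                qpos += n
            elif op == "D":
                tpos += n
    return pd.DataFrame(counts, columns=list("ACGT"))


def _cigar_tokens(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    reads = rio.read_fastq(DATA / "reads.fastq")
    truth = rio.read_tsv(DATA / "satellite_truth.tsv")

    clusters = discover_satellites(reads)
    rows = [{"cluster": i + 1, "n_reads": c.size, "topology": c.topology,
             "monomer_length": c.monomer_length or "",
             "genome_proportion_pct": round(100 * c.genome_proportion, 3)}
            for i, c in enumerate(clusters)]
    rio.write_tsv(pd.DataFrame(rows), OUT / "satellites.tsv")
    rio.write_fasta([(f"cluster{i + 1}_monomer_{c.monomer_length}bp", c.consensus)
                     for i, c in enumerate(clusters) if c.consensus],
                    OUT / "satellite_consensus.fasta")

    seqs = dict(reads)
    for i, cluster in enumerate(clusters):
        if cluster.topology in ("circular", "star") and cluster.consensus:
            pfm = position_frequency_matrix(
                [seqs[r] for r in cluster.member_read_ids], cluster.consensus)
            rio.write_tsv(pfm, OUT / f"cluster{i + 1}_pfm.tsv")

    satellite = [c for c in clusters if c.topology in ("circular", "star")]
    print(f"{len(clusters)} clusters; {len(satellite)} satellite candidates:")
    for c in satellite:
        planted = truth[(truth.monomer_length - (c.monomer_length or 0)).abs() <= 2]
        note = ""
        if len(planted):
            row = planted.iloc[0]
            note = f" (planted {row.monomer_length} bp)"
        print(f"  {c.topology:>8}: monomer {c.monomer_length} bp{note}, "
              f"{c.size} reads, {100 * c.genome_proportion:.2f}% of genome")


if __name__ == "__main__":
    main()
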
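#!/usr/bin/env python
"""Generate the standard synthetic study inputs.

Two data sets, written under results/data/:

* an annotation genome: 2 Mb with 50 LTR retroelements (ages 0-3 Myr,
  LTRs 300-1500 bp), 10 TIR/MITE elements, and 8 labelled library-copy
  insertions, plus its ground-truth table;
* a satellite read set: 0.6x coverage (301-bp reads) of a 3-Mb genome
  carrying 52/325/365-bp monomer tandem arrays at 1.6-1.9% each.
"""

from pathlib import Path

from repeatscape import io as rio
from repeatscape.references import default_library
from repeatscape.simulate import SimulationConfig, simulate_genome

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 101


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    annotation = SimulationConfig(
        genome_length=2_000_000, n_ltr_elements=50, ltr_length_range=(300, 1500),
        age_range=(0.0, 3.0e6), n_tir_elements=10, n_library_copies=8, seed=SEED)
    sim = simulate_genome(annotation)
    rio.write_fasta(sim.contigs, OUT / "genome.fasta")
    rio.write_tsv(sim.truth, OUT / "truth.tsv")
    print(f"annotation genome: {len(sim.genome):,} bp, "
          f"{len(sim.truth)} planted elements")

    refs = default_library()
    rio.write_fasta([(f"{n}#{lbl}", s) for n, lbl, s in refs.repeat_nt],
                    OUT / "repeat_library.fasta")

    satellite = SimulationConfig(
        genome_length=3_000_000, n_ltr_elements=0,
        satellite_specs=((52, 1154, 0.02), (325, 178, 0.02), (365, 140, 0.02)),
        n_reads=5980, read_length=301, seed=SEED)
    sat_sim = simulate_genome(satellite)
    rio.write_fastq(sat_sim.reads, OUT / "reads.fastq")
    rio.write_tsv(sat_sim.truth, OUT / "satellite_truth.tsv")
    arrays = ", ".join(f"{r.monomer_length} bp x {(r.end - r.start) // r.monomer_length}"
                       for _, r in sat_sim.truth.iterrows())
    print(f"satellite read set: {len(sat_sim.reads)} reads over "
          f"{len(sat_sim.genome):,} bp (arrays: {arrays})")


if __name__ == "__main__":
    main()
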
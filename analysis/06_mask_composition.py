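#!/usr/bin/env python
"""Sequential repeat masking and the genome composition report.

Pass 1 masks with the signature-derived element library (this
pipeline's own detections, labelled by superfamily, plus TIR/MITE
detections); pass 2 with the bundled labelled nucleotide repeat
library.  Later passes see only unmasked sequence, so the combined
intervals are disjoint.  Writes masked.bed, masked.fasta and
composition.tsv, and compares class-level composition to planted truth.
"""

from pathlib import Path

from repeatscape import io as rio
from repeatscape.annotate import annotate_element, detect_tir_elements, filter_full_length
from repeatscape.classify import classify_element
from repeatscape.detect import detect_genome
from repeatscape.masking import composition_report, sequential_mask, soft_mask
from repeatscape.references import default_library

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "masking"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    contigs = rio.read_fasta(DATA / "genome.fasta")
    truth = rio.read_tsv(DATA / "truth.tsv")
    refs = default_library()
    genome = contigs["chr1"]

    candidates = detect_genome(contigs)
    annotated = filter_full_length(
        [annotate_element(genome, c, refs) for c in candidates])
    labels = [classify_element(e, refs) for e in annotated]
    signature = [(f"el{i}", f"LTR/{lab.superfamily}",
                  genome[e.candidate.start : e.candidate.end])
                 for i, (e, lab) in enumerate(zip(annotated, labels))]
    signature += [(f"tir{i}", "DNA/TIR", genome[t.start : t.end])
                  for i, t in enumerate(detect_tir_elements(genome, refs=refs))]

    intervals = sequential_mask(genome, [("signature", signature),
                                         ("library1", refs.repeat_nt)])
    rio.write_bed([(iv.contig, iv.start, iv.end, iv.label) for iv in intervals],
                  OUT / "masked.bed")
    rio.write_fasta({"chr1": soft_mask(genome, intervals)}, OUT / "masked.fasta")
    report = composition_report(intervals, len(genome))
    rio.write_tsv(report, OUT / "composition.tsv")

    planted = {}
    for _, row in truth.iterrows():
        cls = {"LTR-RE": "LTR", "TIR": "DNA",
               "library-copy": str(row.lineage).split("/")[0]}.get(row.element_class)
        if cls:
            planted[cls] = planted.get(cls, 0) + (row.end - row.start)
    total = report[report.label == "total"].iloc[0]
    print(f"masked {int(total.total_bp):,} bp ({total.pct_genome:.2f}% of genome)")
    for _, row in report.iterrows():
        if row.label.endswith("(subtotal)"):
            planted_pct = 100 * planted.get(row["class"], 0) / len(genome)
            print(f"  {row['class']:>7}: masked {row.pct_genome:5.2f}% "
                  f"vs planted {planted_pct:5.2f}%")


if __name__ == "__main__":
    main()
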
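#!/usr/bin/env python
"""Superfamily/lineage classification and the RT phylogeny.

Classifies retained elements by domain order (INT-RT = Copia, RT-INT =
Gypsy) with lineage assignment from the best-identity RT reference,
de-duplicates RT peptides, and builds the neighbor-joining tree of the
representatives.  Writes classification.tsv, lineage_counts.tsv and
rt_tree.nwk.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from repeatscape import io as rio
from repeatscape.annotate import annotate_element, filter_full_length
from repeatscape.classify import classify_element
from repeatscape.detect import detect_genome
from repeatscape.phylo import build_nj_tree, dedup_representatives, rt_distance_matrix
from repeatscape.references import default_library

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "classification"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    contigs = rio.read_fasta(DATA / "genome.fasta")
    refs = default_library()

    candidates = detect_genome(contigs)
    annotated = filter_full_length(
        [annotate_element(contigs[c.contig], c, refs) for c in candidates])
    labels = [classify_element(e, refs) for e in annotated]

    rows = [{"contig": e.candidate.contig, "start": e.candidate.start,
             "end": e.candidate.end, "superfamily": lab.superfamily,
             "lineage": lab.lineage, "evidence": lab.evidence}
            for e, lab in zip(annotated, labels)]
    rio.write_tsv(pd.DataFrame(rows), OUT / "classification.tsv")

    counts = Counter((lab.superfamily, lab.lineage) for lab in labels)
    rio.write_tsv(pd.DataFrame(
        [{"superfamily": sf, "lineage": lin, "n": n}
         for (sf, lin), n in sorted(counts.items())]), OUT / "lineage_counts.tsv")

    rt_peps = []
    for i, (element, label) in enumerate(zip(annotated, labels)):
        rt = next((d for d in element.domains if d.domain == "RT" and d.peptide), None)
        if rt is not None:
            rt_peps.append((f"{label.superfamily}_{label.lineage.replace('/', '-')}_{i}",
                            rt.peptide))
    reps = dedup_representatives(rt_peps, identity_threshold=0.98)
    if len(reps) >= 3:
        tree = build_nj_tree(rt_distance_matrix(reps), [n for n, _ in reps])
        (OUT / "rt_tree.nwk").write_text(tree.newick + "\n")
        print(f"{len(rt_peps)} RT peptides -> {len(reps)} representatives; "
              f"tree written to rt_tree.nwk")
    by_sf = Counter(lab.superfamily for lab in labels)
    print(f"classification: {dict(by_sf)}; "
          f"{sum(1 for lab in labels if lab.lineage != 'unknown')} lineage-assigned")


if __name__ == "__main__":
    main()
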
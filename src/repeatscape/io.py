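"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversions
happen only here, at the format boundary: GFF3 is written 1-based
inclusive, BED 0-based half-open, FASTA wrapped at 60 columns.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WIDTH = 60


def read_fasta(path) -> dict[str, str]:
    """Contig name -> sequence (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[tuple[str, str]], path, quality: int = 40) -> None:
    with open(path, "w") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{chr(33 + quality) * len(seq)}\n")


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: list[tuple[str, int, int, str]], path) -> None:
    """(contig, start, end, name) records, 0-based half-open."""
    with open(path, "w") as handle:
        for contig, start, end, name in sorted(intervals):
            if start < 0 or end <= start:
                raise ValueError(f"invalid BED interval {contig}:{start}-{end}")
            handle.write(f"{contig}\t{start}\t{end}\t{name}\n")


def write_gff3(features: list[dict], path) -> None:
    """Write GFF3 (1-based inclusive) from 0-based half-open features.

    Each feature dict needs contig, source, type, start, end (0-based
    half-open) and optionally score, strand, attributes (dict).
    """
    lines = ["##gff-version 3"]
    for feat in sorted(features, key=lambda f: (f["contig"], f["start"], f["end"])):
        start, end = feat["start"], feat["end"]
        if start < 0 or end <= start:
            raise ValueError(f"invalid feature interval {start}-{end}")
        attrs = feat.get("attributes", {})
        attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
        score = feat.get("score", ".")
        lines.append("\t".join([
            feat["contig"], feat.get("source", "repeatscape"), feat["type"],
            str(start + 1), str(end),  # 1-based inclusive
            str(score), feat.get("strand", "+"), ".", attr_str,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[dict]:
    """Inverse of :func:`write_gff3` (coordinates back to 0-based half-open)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        attrs = {}
        if cols[8] != ".":
            for item in cols[8].split(";"):
                if "=" in item:
                    key, value = item.split("=", 1)
                    attrs[key] = value
        out.append({
            "contig": cols[0], "source": cols[1], "type": cols[2],
            "start": int(cols[3]) - 1, "end": int(cols[4]),
            "score": cols[5], "strand": cols[6], "attributes": attrs,
        })
    return out


def candidates_to_gff3(elements, tsd_features: bool = True) -> list[dict]:
    """GFF3 feature dicts for detected/annotated LTR candidates."""
    feats = []
    for i, element in enumerate(elements):
        cand = getattr(element, "candidate", element)
        eid = f"ltrre{i + 1:05d}"
        feats.append({"contig": cand.contig, "type": "LTR_retrotransposon",
                      "start": cand.start, "end": cand.end, "strand": cand.strand,
                      "attributes": {"ID": eid,
                                     "ltr_similarity": f"{cand.ltr_similarity:.4f}"}})
        for name, (s, e) in (("ltr5", cand.ltr5), ("ltr3", cand.ltr3)):
            feats.append({"contig": cand.contig, "type": "long_terminal_repeat",
                          "start": s, "end": e, "strand": cand.strand,
                          "attributes": {"Parent": eid, "Name": name}})
        if tsd_features and cand.tsd:
            feats.append({"contig": cand.contig, "type": "target_site_duplication",
                          "start": cand.start - len(cand.tsd), "end": cand.start,
                          "attributes": {"Parent": eid, "Name": cand.tsd}})
        pbs = getattr(element, "pbs", None)
        if pbs is not None:
            start = cand.ltr5[1] + pbs.offset_from_5ltr
            feats.append({"contig": cand.contig, "type": "primer_binding_site",
                          "start": start, "end": start + pbs.length,
                          "attributes": {"Parent": eid, "trna": pbs.trna_id}})
        ppt = getattr(element, "ppt", None)
        if ppt is not None:
            end = cand.ltr3[0] - ppt.offset_from_3ltr
            feats.append({"contig": cand.contig, "type": "RR_tract",
                          "start": end - ppt.length, "end": end,
                          "attributes": {"Parent": eid,
                                         "purine_fraction": f"{ppt.purine_fraction:.2f}"}})
        for dom in getattr(element, "domains", []) or []:
            feats.append({"contig": cand.contig, "type": "polypeptide_domain",
                          "start": cand.start + dom.pep_interval[0],
                          "end": cand.start + dom.pep_interval[1],
                          "attributes": {"Parent": eid, "Name": dom.domain,
                                         "bits": f"{dom.score:.1f}"}})
    return feats


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
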
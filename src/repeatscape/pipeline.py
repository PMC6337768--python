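"""One reproducible run tying all annotation stages together.

Stage order: detect -> annotate -> filter -> classify -> date -> TIR
search -> sequential masking -> composition report, plus satellite
discovery when reads are supplied.  Every stage's outputs are written
under the run directory in standard formats, and a manifest records the
configuration, the seeds, input checksums and output paths, so
re-running an identical manifest reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .annotate import annotate_element, detect_tir_elements, filter_full_length, flag_intact
from .classify import classify_element
from .dating import DEFAULT_RATE, age_summary, date_elements
from .detect import DetectorConfig, detect_genome
from .masking import composition_report, sequential_mask, soft_mask
from .references import default_library
from .satellites import discover_satellites

__version__ = "0.1.0"

log = logging.getLogger("repeatscape")


@dataclass
class PipelineConfig:
    genome_fasta: str
    out_dir: str
    reads_fastq: str | None = None
    seed: int = 0
    substitution_rate: float = DEFAULT_RATE
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    extra_libraries: list[str] = field(default_factory=list)  # FASTA paths for masking passes 2+


@dataclass
class RunManifest:
    version: str
    config: dict
    seeds: dict
    input_checksums: dict
    outputs: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _read_labelled_library(path: str) -> list[tuple[str, str, str]]:
    """FASTA with ``name#class/superfamily`` (or plain) headers."""
    out = []
    for name, seq in rio.read_fasta(path).items():
        if "#" in name:
            base, label = name.split("#", 1)
        else:
            base, label = name, "unknown"
        out.append((base, label, seq))
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = default_library()
    outputs: dict[str, str] = {}
    checksums: dict[str, str] = {}

    def out(name: str) -> Path:
        path = out_dir / name
        outputs[name] = str(path)
        return path

    stage = "load"
    try:
        genome_path = Path(config.genome_fasta)
        if not genome_path.exists():
            raise FileNotFoundError(f"genome FASTA not found: {genome_path}")
        contigs = rio.read_fasta(genome_path)
        checksums["genome"] = rio.sha256_file(genome_path)

        stage = "detect"
        log.info("detecting LTR candidates on %d contig(s)", len(contigs))
        candidates = detect_genome(contigs, config.detector)

        stage = "annotate"
        annotated = [annotate_element(contigs[c.contig], c, refs) for c in candidates]

        stage = "filter"
        retained = filter_full_length(annotated)
        log.info("%d/%d candidates retained by the full-length filter",
                 len(retained), len(annotated))

        stage = "classify"
        labels = [classify_element(e, refs) for e in retained]
        class_rows = []
        for element, label in zip(retained, labels):
            cand = element.candidate
            class_rows.append({
                "contig": cand.contig, "start": cand.start, "end": cand.end,
                "ltr_similarity": round(cand.ltr_similarity, 4), "tsd": cand.tsd,
                "has_pbs": element.pbs is not None, "has_ppt": element.ppt is not None,
                "domains": ",".join(sorted(element.domain_labels())),
                "intact": flag_intact(element),
                "superfamily": label.superfamily, "lineage": label.lineage,
                "evidence": label.evidence,
            })
        rio.write_tsv(pd.DataFrame(class_rows), out("elements.tsv"))
        rio.write_gff3(rio.candidates_to_gff3(retained), out("elements.gff3"))
        rio.write_fasta([(f"ltrre{i + 1:05d}",
                          contigs[e.candidate.contig][e.candidate.start:e.candidate.end])
                         for i, e in enumerate(retained)], out("elements.fasta"))

        stage = "date"
        dating = date_elements(contigs, retained, r=config.substitution_rate, labels=labels)
        rio.write_tsv(dating, out("insertion_ages.tsv"))
        if not dating.empty:
            rio.write_tsv(age_summary(dating), out("age_summary.tsv"))

        stage = "tir"
        tirs = []
        for name, seq in contigs.items():
            tirs.extend(detect_tir_elements(seq, refs=refs, contig_name=name))

        stage = "mask"
        signature_library = []
        for i, (element, label) in enumerate(zip(retained, labels)):
            cand = element.candidate
            seq = contigs[cand.contig][cand.start : cand.end]
            signature_library.append((f"ltrre{i + 1:05d}", f"LTR/{label.superfamily}", seq))
        for i, tir in enumerate(tirs):
            seq = contigs[tir.contig][tir.start : tir.end]
            signature_library.append((f"tir{i + 1:05d}", "DNA/TIR", seq))
        passes = [("signature", signature_library)]
        for n, lib_path in enumerate(config.extra_libraries, start=1):
            passes.append((f"library{n}", _read_labelled_library(lib_path)))
        intervals = []
        reports = []
        for name, seq in contigs.items():
            ivs = sequential_mask(seq, passes, contig=name)
            intervals.extend(ivs)
            reports.append((name, seq, ivs))
        rio.write_bed([(iv.contig, iv.start, iv.end, iv.label) for iv in intervals],
                      out("masked.bed"))
        rio.write_fasta({name: soft_mask(seq, [iv for iv in intervals if iv.contig == name])
                         for name, seq in contigs.items()}, out("masked.fasta"))

        stage = "report"
        genome_length = sum(len(s) for s in contigs.values())
        report = composition_report(intervals, genome_length)
        rio.write_tsv(report, out("composition.tsv"))

        if config.reads_fastq:
            stage = "satellites"
            reads = rio.read_fastq(config.reads_fastq)
            checksums["reads"] = rio.sha256_file(config.reads_fastq)
            clusters = discover_satellites(reads, seed=config.seed)
            sat_rows = [{
                "cluster": i + 1, "n_reads": c.size, "topology": c.topology,
                "monomer_length": c.monomer_length if c.monomer_length else "",
                "genome_proportion_pct": round(100 * c.genome_proportion, 4),
            } for i, c in enumerate(clusters)]
            rio.write_tsv(pd.DataFrame(sat_rows), out("satellites.tsv"))
            rio.write_fasta([(f"cluster{i + 1}_monomer", c.consensus)
                             for i, c in enumerate(clusters) if c.consensus],
                            out("satellite_consensus.fasta"))
    except Exception as err:  # noqa: BLE001 - re-raise with the failing stage named
        raise StageError(stage, err) from err

    manifest = RunManifest(
        version=__version__,
        config={
            "genome_fasta": config.genome_fasta, "out_dir": config.out_dir,
            "reads_fastq": config.reads_fastq, "seed": config.seed,
            "substitution_rate": config.substitution_rate,
            "detector": dataclasses.asdict(config.detector),
            "extra_libraries": list(config.extra_libraries),
        },
        seeds={"global": config.seed, "satellites": config.seed},
        input_checksums=checksums,
        outputs=outputs,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
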
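"""End-to-end orchestration of the sRNA analysis stages.

Stages communicate only through files in a run directory, so any stage can
be re-run from the cached outputs of its predecessors:

    simulate -> process -> annotate -> mirna-de -> novel -> tasirna ->
    natsirna -> network -> report

All randomness flows from one top-level seed; a manifest records the seed
and SHA-256 checksums of every output, so two runs with the same seed can
be compared file by file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import abundance_stats, annotation, natsirna, novel_mirna, read_processing, tasirna
from .io import read_fasta, read_gff3
from .natsirna import Interval, NATPair
from .read_processing import SRNALibrary
from .synthetic_data import (
    CONDITIONS,
    SimulationConfig,
    build_reference,
    default_config,
    simulate_library,
    write_library,
    write_reference,
)
from .tasirna import TasLocus

log = logging.getLogger("srnakit")

DEFAULT_CONTROL = "leaf_WT"
DEFAULT_TREATMENTS = ("leaf_OE7", "leaf_OE21")
NOVEL_SCREEN_MIN_COUNT = 5  # skip singleton background tags in the hairpin screen


@dataclass
class PipelineConfig:
    """Thresholds and layout of one pipeline run."""

    seed: int = 0
    control: str = DEFAULT_CONTROL
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    conditions: tuple[str, ...] = CONDITIONS
    simulation: SimulationConfig = field(default_factory=lambda: default_config())
    log2_cutoff: float = 1.0
    p_cutoff: float = 0.05
    tasirna_read_filter: int = 10
    novel_report_count: int = 100

    def validate(self) -> None:
        if self.log2_cutoff <= 0 or self.p_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        for c in (self.control, *self.treatments):
            if c not in self.conditions:
                raise ValueError(f"library {c!r} not among simulated conditions")


def _stage_seed(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages


def stage_simulate(rundir: Path, config: PipelineConfig) -> None:
    ref = build_reference(config.simulation, _stage_seed(config.seed, "reference"))
    write_reference(ref, rundir / "reference")
    for cond in config.conditions:
        reads, truth = simulate_library(
            ref, config.simulation, cond, _stage_seed(config.seed, f"library:{cond}")
        )
        write_library(reads, truth, rundir / "libraries", cond)
        log.info("simulate: %s -> %d reads", cond, len(reads))


def _load_libraries(rundir: Path) -> list[SRNALibrary]:
    stats = pd.read_csv(rundir / "process" / "library_stats.tsv", sep="\t")
    return [
        SRNALibrary(
            library_id=r["library_id"],
            tissue=r["tissue"],
            genotype=r["genotype"],
            raw_read_count=int(r["raw_reads"]),
            clean_read_count=int(r["clean_reads"]),
        )
        for _, r in stats.iterrows()
    ]


def _load_tags(rundir: Path) -> dict[str, read_processing.SmallRNATag]:
    table = pd.read_csv(rundir / "process" / "tags.tsv", sep="\t", index_col="sequence")
    tags = {}
    for seq, row in table.iterrows():
        counts = {lib: int(n) for lib, n in row.items() if n > 0}
        tags[str(seq)] = read_processing.SmallRNATag(sequence=str(seq), counts=counts)
    return tags


def stage_process(rundir: Path, config: PipelineConfig) -> None:
    libdir = rundir / "libraries"
    if not libdir.is_dir():
        raise StageError("process", f"no simulated libraries under {libdir}")
    outdir = rundir / "process"
    outdir.mkdir(parents=True, exist_ok=True)
    libraries, tag_sets = [], []
    for cond in config.conditions:
        fastq = libdir / f"{cond}.fastq"
        if not fastq.exists():
            raise StageError("process", f"missing library {cond} ({fastq})")
        tissue, genotype = cond.split("_", 1)
        lib = SRNALibrary(library_id=cond, tissue=tissue, genotype=genotype)
        tags = read_processing.process_fastq(fastq, lib, config.simulation.adapter3)
        total = sum(t.total for t in tags.values())
        if total != lib.clean_read_count:
            raise StageError("process", f"conservation violated in {cond}")
        log.info(
            "process: %s raw=%d clean=%d unique=%d",
            cond, lib.raw_read_count, lib.clean_read_count, len(tags),
        )
        libraries.append(lib)
        tag_sets.append(tags)
        read_processing.write_collapsed_fasta(tags, outdir / f"{cond}.collapsed.fa")
        read_processing.length_distribution(tags, cond).to_csv(
            outdir / f"{cond}.lengths.tsv", sep="\t"
        )
    merged = read_processing.merge_tag_sets(tag_sets)
    table = pd.DataFrame(
        {
            "sequence": list(merged),
            **{
                cond: [merged[s].counts.get(cond, 0) for s in merged]
                for cond in config.conditions
            },
        }
    ).sort_values("sequence")
    table.to_csv(outdir / "tags.tsv", sep="\t", index=False)
    read_processing.library_stats(libraries).to_csv(
        outdir / "library_stats.tsv", sep="\t", index=False
    )


def stage_annotate(rundir: Path, config: PipelineConfig) -> None:
    genome = read_fasta(rundir / "reference" / "genome.fa")["minigenome"]
    features = read_gff3(rundir / "reference" / "features.gff3")
    tags = _load_tags(rundir)
    libraries = _load_libraries(rundir)
    assignments = annotation.annotate_tags(tags, genome, features)
    outdir = rundir / "annotate"
    outdir.mkdir(parents=True, exist_ok=True)
    annotation.assignments_table(assignments).to_csv(
        outdir / "assignments.tsv", sep="\t", index=False
    )
    summary = annotation.summarize_classes(assignments, tags, libraries)
    summary.to_csv(outdir / "class_summary.tsv", sep="\t")
    for lib in libraries:
        if summary[f"{lib.library_id}_total"].sum() != lib.clean_read_count:
            raise StageError("annotate", f"partition violated in {lib.library_id}")
    log.info("annotate: %d tags in %d categories", len(tags), (summary.sum(axis=1) > 0).sum())


def _clean_total(libraries: list[SRNALibrary], cond: str) -> int:
    for lib in libraries:
        if lib.library_id == cond:
            return lib.clean_read_count
    raise StageError("mirna-de", f"unknown library {cond}")


def stage_mirna_de(rundir: Path, config: PipelineConfig) -> None:
    mature = read_fasta(rundir / "reference" / "mirna_mature.fa")
    tags = _load_tags(rundir)
    libraries = _load_libraries(rundir)
    outdir = rundir / "mirna_de"
    outdir.mkdir(parents=True, exist_ok=True)
    counts = pd.DataFrame(
        {
            cond: {
                mid: tags[seq].counts.get(cond, 0) if seq in tags else 0
                for mid, seq in mature.items()
            }
            for cond in config.conditions
        }
    )
    counts.to_csv(outdir / "mirna_counts.tsv", sep="\t")
    n1 = _clean_total(libraries, config.control)
    for treatment in config.treatments:
        n2 = _clean_total(libraries, treatment)
        table = abundance_stats.de_table(counts, config.control, treatment, n1, n2)
        table.to_csv(outdir / f"de_{config.control}_vs_{treatment}.tsv", sep="\t", index=False)
        log.info(
            "mirna-de %s: %d up, %d down",
            treatment, (table["call"] == "up").sum(), (table["call"] == "down").sum(),
        )


def stage_novel(rundir: Path, config: PipelineConfig) -> None:
    genome = read_fasta(rundir / "reference" / "genome.fa")["minigenome"]
    tags = _load_tags(rundir)
    assignments = pd.read_csv(rundir / "annotate" / "assignments.tsv", sep="\t")
    unannotated = [
        t
        for t in assignments[assignments["category"] == "unannotated"]["tag"]
        if tags[t].total >= NOVEL_SCREEN_MIN_COUNT
    ]
    candidates = novel_mirna.screen_tags(tags, unannotated, genome)
    outdir = rundir / "novel"
    outdir.mkdir(parents=True, exist_ok=True)
    for tissue in ("leaf", "root"):
        tissue_cands = []
        for c in candidates:
            n = sum(
                v for lib, v in tags[c.tag].counts.items() if lib.startswith(tissue)
            )
            if c.accepted and n > 0:
                c2 = novel_mirna.HairpinCandidate(**{**c.__dict__})
                c2.total_count = n
                tissue_cands.append(c2)
        reported = novel_mirna.name_candidates(
            tissue_cands, tissue, config.novel_report_count
        )
        novel_mirna.candidates_table(tissue_cands).to_csv(
            outdir / f"{tissue}_candidates.tsv", sep="\t", index=False
        )
        novel_mirna.candidates_table(reported).to_csv(
            outdir / f"{tissue}_reported.tsv", sep="\t", index=False
        )
        log.info("novel (%s): %d accepted, %d reported", tissue, len(tissue_cands), len(reported))


def _load_tas(rundir: Path) -> list[TasLocus]:
    cdna = read_fasta(rundir / "reference" / "tas_cdna.fa")
    sites = pd.read_csv(rundir / "reference" / "tas_cleavage.tsv", sep="\t")
    return [
        TasLocus(r["locus_id"], cdna[r["locus_id"]], int(r["cleavage_position"]))
        for _, r in sites.iterrows()
    ]


def stage_tasirna(rundir: Path, config: PipelineConfig) -> None:
    loci = _load_tas(rundir)
    tags = _load_tags(rundir)
    libraries = _load_libraries(rundir)
    outdir = rundir / "tasirna"
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = []
    for lib in libraries:
        mapped = tasirna.map_21nt(tags, loci, lib.library_id)
        for locus in loci:
            p = tasirna.phase_registers(mapped[locus.locus_id], locus)
            profiles.append((lib.library_id, p))
    table = tasirna.profile_table([p for _, p in profiles])
    table.insert(0, "library_id", [lib for lib, _ in profiles])
    table.to_csv(outdir / "phase_profiles.tsv", sep="\t", index=False)
    n1 = _clean_total(libraries, config.control)
    for treatment in config.treatments:
        n2 = _clean_total(libraries, treatment)
        de = tasirna.tasirna_de(
            tags, loci, config.control, treatment, n1, n2, config.tasirna_read_filter
        )
        de.to_csv(outdir / f"de_{config.control}_vs_{treatment}.tsv", sep="\t", index=False)
        log.info("tasirna %s: %d sequences tested", treatment, len(de))


def _combined_calls(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """One row per sequence; the call is up/down only when every comparison
    agrees, mirroring the altered-in-both-lines convention."""
    base = tables[0].copy()
    calls = [t.set_index("id")["call"] for t in tables]
    def agree(i):
        cs = {c.get(i, "equal") for c in calls}
        return cs.pop() if len(cs) == 1 else "equal"
    base["call"] = base["id"].map(agree)
    return base


def stage_network(rundir: Path, config: PipelineConfig) -> None:
    loci = _load_tas(rundir)
    tags = _load_tags(rundir)
    transcriptome = read_fasta(rundir / "reference" / "transcriptome.fa")
    if not transcriptome:
        raise StageError("network", "missing transcriptome")
    families = pd.read_csv(
        rundir / "reference" / "transcript_families.tsv", sep="\t"
    ).set_index("transcript_id")["family"].to_dict()
    mature = read_fasta(rundir / "reference" / "mirna_mature.fa")
    initiator_id = sorted(mature)[0] if "miR173" not in mature else "miR173"
    de_tables = [
        pd.read_csv(rundir / "tasirna" / f"de_{config.control}_vs_{t}.tsv", sep="\t")
        for t in config.treatments
    ]
    combined = _combined_calls(de_tables)
    graph = tasirna.build_network(
        combined, tags, loci, mature[initiator_id], initiator_id, transcriptome, families
    )
    outdir = rundir / "network"
    outdir.mkdir(parents=True, exist_ok=True)
    tasirna.write_sif(graph, outdir / "network.sif")
    tasirna.write_graphml(graph, outdir / "network.graphml")
    log.info("network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges())


def _load_nat_pairs(rundir: Path) -> list[NATPair]:
    table = pd.read_csv(rundir / "reference" / "nat_pairs.tsv", sep="\t")
    pairs = []
    for _, r in table.iterrows():
        ol_b = None
        if str(r["ol_b_start"]) not in ("", "nan"):
            ol_b = Interval(int(float(r["ol_b_start"])) - 1, int(float(r["ol_b_end"])), "+")
        pairs.append(
            NATPair(
                pair_id=r["pair_id"],
                pair_type=r["type"],
                gene_a=r["gene_a"],
                wl_a=Interval(int(r["a_start"]) - 1, int(r["a_end"]), r["a_strand"]),
                gene_b=r["gene_b"],
                wl_b=Interval(int(r["b_start"]) - 1, int(r["b_end"]), r["b_strand"]),
                ol=Interval(int(r["ol_start"]) - 1, int(r["ol_end"]), "+"),
                ol_b=ol_b,
            )
        )
    return pairs


def stage_natsirna(rundir: Path, config: PipelineConfig) -> None:
    genome = read_fasta(rundir / "reference" / "genome.fa")["minigenome"]
    pairs = _load_nat_pairs(rundir)
    tags = _load_tags(rundir)
    libraries = _load_libraries(rundir)
    outdir = rundir / "natsirna"
    outdir.mkdir(parents=True, exist_ok=True)
    counts = natsirna.count_all_regions(
        tags, pairs, genome, [lib.library_id for lib in libraries]
    )
    counts.to_csv(outdir / "region_counts.tsv", sep="\t", index=False)
    n1 = _clean_total(libraries, config.control)
    des = []
    for treatment in config.treatments:
        n2 = _clean_total(libraries, treatment)
        de = natsirna.natsirna_de(counts, config.control, treatment, n1, n2)
        de.to_csv(outdir / f"de_{config.control}_vs_{treatment}.tsv", sep="\t", index=False)
        des.append(de)
    if len(des) >= 2:
        natsirna.altered_in_both(des[0], des[1]).to_csv(
            outdir / "altered_in_both.tsv", sep="\t", index=False
        )
    log.info("natsirna: %d pairs counted", counts["pair_id"].nunique())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_report(rundir: Path, config: PipelineConfig) -> None:
    libraries = _load_libraries(rundir)
    outputs = sorted(
        p for p in rundir.rglob("*")
        if p.is_file() and p.suffix in (".tsv", ".fa", ".fastq", ".gff3", ".sif", ".graphml")
    )
    manifest = {
        "srnakit_version": __version__,
        "seed": config.seed,
        "control": config.control,
        "treatments": list(config.treatments),
        "files": {str(p.relative_to(rundir)): _sha256(p) for p in outputs},
    }
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    lines = ["# sRNA pipeline report", ""]
    lines.append("| library | raw | clean | % clean |")
    lines.append("|---|---|---|---|")
    for lib in libraries:
        pct = 100.0 * lib.clean_read_count / lib.raw_read_count
        lines.append(
            f"| {lib.library_id} | {lib.raw_read_count} | {lib.clean_read_count} | {pct:.1f} |"
        )
    for treatment in config.treatments:
        de = pd.read_csv(
            rundir / "mirna_de" / f"de_{config.control}_vs_{treatment}.tsv", sep="\t"
        )
        lines.append(
            f"\nmiRNA DE {config.control} vs {treatment}: "
            f"{(de['call'] == 'up').sum()} up, {(de['call'] == 'down').sum()} down, "
            f"{(de['call'] == 'equal').sum()} equal"
        )
    (rundir / "report.md").write_text("\n".join(lines) + "\n")


STAGES = {
    "simulate": stage_simulate,
    "process": stage_process,
    "annotate": stage_annotate,
    "mirna-de": stage_mirna_de,
    "novel": stage_novel,
    "tasirna": stage_tasirna,
    "natsirna": stage_natsirna,
    "network": stage_network,
    "report": stage_report,
}


def run_pipeline(rundir: str | Path, config: PipelineConfig | None = None) -> Path:
    """Execute every stage in order; any failure aborts with the stage name."""
    config = config or PipelineConfig()
    config.validate()
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES.items():
        try:
            fn(rundir, config)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise StageError(name, str(exc)) from exc
    return rundir
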
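"""tasiRNA phase-register analysis and the initiator-miRNA network.

Trans-acting siRNAs are diced in 21-nt steps from the end of a TAS
transcript defined by initiator-miRNA-guided cleavage, so the start
positions of genuine tasiRNAs fall into a single residue class mod 21
relative to the cleavage site.  This module maps 21-nt tags to TAS cDNAs
(sense strand, perfect match, all positions kept), accumulates the 21-bin
phase-register histogram per locus (register 0 = a read starting exactly at
the cleavage site), tests per-sequence abundance between libraries with the
tag-count statistic, and assembles the initiator-miRNA -> TAS -> tasiRNA ->
PPR/TPR-target network as a typed graph exported in SIF and GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import abundance_stats
from .read_processing import SmallRNATag
from .target_prediction import scan_targets

PHASE = 21
READ_FILTER = 10


@dataclass(frozen=True)
class TasLocus:
    """A TAS gene: cDNA sequence plus the 1-based position on the cDNA of
    the initiator-miRNA-guided cleavage."""

    locus_id: str
    cdna: str
    cleavage_position: int

    def __post_init__(self) -> None:
        if not (1 <= self.cleavage_position <= len(self.cdna)):
            raise ValueError("cleavage_position must lie inside the cDNA")


@dataclass
class PhaseProfile:
    """21-bin register histogram of perfectly mapped 21-nt reads."""

    locus_id: str
    bins: np.ndarray  # shape (21,), counts per register
    total: int
    positions: dict[int, int]  # 1-based start -> count

    @property
    def in_register_fraction(self) -> float:
        return float(self.bins[0]) / self.total if self.total else 0.0


def map_21nt(
    tags: Mapping[str, SmallRNATag],
    loci: Iterable[TasLocus],
    library_id: str | None = None,
) -> dict[str, dict[int, dict[str, int]]]:
    """Exact sense-strand occurrences of 21-nt tags on each TAS cDNA.

    Returns {locus_id: {1-based start: {tag: count}}}; every occurrence of a
    multi-site tag is kept.  Only length-21 tags are considered.
    """
    out: dict[str, dict[int, dict[str, int]]] = {}
    for locus in loci:
        cdna = locus.cdna.upper()
        hits: dict[int, dict[str, int]] = {}
        for seq, tag in tags.items():
            if len(seq) != PHASE:
                continue
            n = tag.total if library_id is None else tag.counts.get(library_id, 0)
            if n == 0:
                continue
            start = cdna.find(seq)
            while start >= 0:
                hits.setdefault(start + 1, {})[seq] = n
                start = cdna.find(seq, start + 1)
        out[locus.locus_id] = hits
    return out


def phase_registers(
    positions: Mapping[int, Mapping[str, int] | int], locus: TasLocus
) -> PhaseProfile:
    """Accumulate mapped counts into the 21 phase registers of a locus.

    ``register(pos) = (pos - cleavage_position) mod 21``; a read starting
    exactly at the cleavage site is register 0.  Position values may be
    plain counts or per-tag count maps.
    """
    bins = np.zeros(PHASE, dtype=int)
    flat: dict[int, int] = {}
    for pos, val in positions.items():
        n = val if isinstance(val, int) else sum(val.values())
        flat[pos] = flat.get(pos, 0) + n
        bins[(pos - locus.cleavage_position) % PHASE] += n
    return PhaseProfile(
        locus_id=locus.locus_id, bins=bins, total=int(bins.sum()), positions=flat
    )


def tasirna_de(
    tags: Mapping[str, SmallRNATag],
    loci: Iterable[TasLocus],
    control: str,
    treatment: str,
    n1: int,
    n2: int,
    read_filter: int = READ_FILTER,
) -> pd.DataFrame:
    """Differential abundance of individual TAS-mapped 21-nt sequences.

    Only sequences whose count exceeds ``read_filter`` reads in at least one
    of the two compared libraries are tested (strict inequality).  Returns
    the standard DE table plus a ``loci`` column listing the source loci.
    """
    loci = list(loci)
    mapped = map_21nt(tags, loci)
    seq_loci: dict[str, set[str]] = {}
    for locus_id, hits in mapped.items():
        for pos_tags in hits.values():
            for seq in pos_tags:
                seq_loci.setdefault(seq, set()).add(locus_id)
    rows = {}
    for seq in sorted(seq_loci):
        x = tags[seq].counts.get(control, 0)
        y = tags[seq].counts.get(treatment, 0)
        if max(x, y) <= read_filter:
            continue
        rows[seq] = (x, y)
    counts = pd.DataFrame(
        {control: {s: xy[0] for s, xy in rows.items()},
         treatment: {s: xy[1] for s, xy in rows.items()}},
        dtype=int,
    )
    table = abundance_stats.de_table(counts, control, treatment, n1, n2)
    table["loci"] = table["id"].map(lambda s: ",".join(sorted(seq_loci[s])))
    return table


def build_network(
    de_results: pd.DataFrame,
    tags: Mapping[str, SmallRNATag],
    loci: Iterable[TasLocus],
    initiator_mirna: str,
    initiator_id: str,
    transcriptome: Mapping[str, str],
    transcript_families: Mapping[str, str] | None = None,
) -> nx.MultiDiGraph:
    """Typed graph of the initiator-miRNA / TAS / tasiRNA / target system.

    Nodes: sRNA (with the DE call as attribute), TAS_gene, MIR_gene, and
    PPR_target / TPR_target transcripts.  Edges: ``generated_from`` (sRNA ->
    TAS locus it perfectly maps to), ``targets`` (sRNA -> transcript with a
    passing duplex), ``initiates`` (initiator miRNA -> its MIR gene and each
    TAS locus it cleaves).
    """
    if not transcriptome:
        raise ValueError("transcriptome is required to draw targets edges")
    loci = list(loci)
    families = transcript_families or {}
    g = nx.MultiDiGraph()
    mir_gene = f"MIR_{initiator_id}"
    g.add_node(initiator_id, node_type="sRNA", call="initiator")
    g.add_node(mir_gene, node_type="MIR_gene")
    g.add_edge(initiator_id, mir_gene, edge_type="initiates")
    for locus in loci:
        g.add_node(locus.locus_id, node_type="TAS_gene")
        g.add_edge(initiator_id, locus.locus_id, edge_type="initiates")
    calls = dict(zip(de_results["id"], de_results["call"]))
    for _, row in de_results.iterrows():
        seq = row["id"]
        g.add_node(seq, node_type="sRNA", call=calls[seq])
        for locus_id in str(row["loci"]).split(","):
            g.add_edge(seq, locus_id, edge_type="generated_from")
        for site in scan_targets(seq, transcriptome, mirna_id=seq):
            fam = families.get(site.transcript_id, "PPR")
            g.add_node(site.transcript_id, node_type=f"{fam}_target")
            g.add_edge(
                seq,
                site.transcript_id,
                edge_type="targets",
                start=site.start,
                end=site.end,
            )
    return g


def write_sif(graph: nx.MultiDiGraph, path: str | Path) -> None:
    """Cytoscape SIF export: ``source <edge_type> target`` per line."""
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[2]["edge_type"], e[1])):
            fh.write(f"{u}\t{data['edge_type']}\t{v}\n")


def write_graphml(graph: nx.MultiDiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def profile_table(profiles: Iterable[PhaseProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"locus_id": p.locus_id, "total": p.total}
        row.update({f"register_{i}": int(p.bins[i]) for i in range(PHASE)})
        rows.append(row)
    return pd.DataFrame(rows)
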
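"""Exact-match tag mapping and single-category annotation.

Unique tags are mapped to the mini-genome on both strands with no mismatches
(every occurrence is kept), then each tag receives exactly one annotation
category by a fixed priority rule over the classes of the features its hits
fall in:

    GenBank ncRNA (rRNA/tRNA/snRNA/snoRNA/scRNA) > Rfam > known miRNA >
    repeat > exon > intron > siRNA

with exon and intron hits split into sense/antisense relative to the
annotated transcript strand.  Tags with no hit to any feature are
"unannotated".  Because each tag lands in exactly one category, the
per-category totals partition the clean reads of every library.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .io import Feature
from .read_processing import SRNALibrary, SmallRNATag

GENBANK_CLASSES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA", "scRNA"})

#: annotation categories in priority order (highest first)
CATEGORIES = (
    "GenBank",
    "Rfam",
    "known_miRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "siRNA",
    "unannotated",
)
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class MappingHit:
    """One exact occurrence of a tag on the genome.

    ``start`` is 0-based on the forward strand; for strand "-" the tag's
    reverse complement matches the forward genome at that position.
    ``feature_id``/``class_label`` identify a feature fully containing the
    hit, or are None for a bare genomic hit.
    """

    tag: str
    strand: str
    start: int
    feature_id: str | None = None
    class_label: str | None = None
    feature_strand: str | None = None


@dataclass
class AnnotationAssignment:
    tag: str
    category: str
    hits: tuple[MappingHit, ...] = ()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class GenomeIndex:
    """Hash index of all genome substrings in a set of lengths, both strands.

    Desk-scale replacement for a short-read aligner: exact matches only, all
    positions kept.
    """

    def __init__(self, genome: str, lengths: Iterable[int]):
        if not genome:
            raise ValueError("empty reference")
        self.genome = genome.upper()
        self._index: dict[int, dict[str, list[int]]] = {}
        for L in sorted(set(lengths)):
            table: dict[str, list[int]] = defaultdict(list)
            for i in range(len(self.genome) - L + 1):
                table[self.genome[i : i + L]].append(i)
            self._index[L] = table

    def find(self, tag: str) -> list[tuple[str, int]]:
        """All (strand, forward-coordinate start) exact occurrences."""
        L = len(tag)
        if L not in self._index:
            table: dict[str, list[int]] = defaultdict(list)
            for i in range(len(self.genome) - L + 1):
                table[self.genome[i : i + L]].append(i)
            self._index[L] = table
        table = self._index[L]
        hits = [("+", i) for i in table.get(tag, ())]
        rc = revcomp(tag)
        hits += [("-", i) for i in table.get(rc, ())]
        # palindromic tags match both strands at the same position; keep both
        return sorted(hits, key=lambda h: (h[1], h[0]))


def map_tags(
    tags: Iterable[str],
    genome: str | GenomeIndex,
    features: list[Feature] | None = None,
) -> list[MappingHit]:
    """Map tag sequences to the genome; annotate each occurrence with every
    feature that fully contains it (one MappingHit per tag/position/feature).
    Occurrences contained in no feature yield a bare hit."""
    tags = list(tags)
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(
        genome, {len(t) for t in tags}
    )
    features = features or []
    hits: list[MappingHit] = []
    for tag in tags:
        for strand, start in index.find(tag):
            end = start + len(tag)
            containing = [f for f in features if f.contains(start, end)]
            if not containing:
                hits.append(MappingHit(tag=tag, strand=strand, start=start))
                continue
            for f in sorted(containing, key=lambda f: f.feature_id):
                hits.append(
                    MappingHit(
                        tag=tag,
                        strand=strand,
                        start=start,
                        feature_id=f.feature_id,
                        class_label=f.class_label,
                        feature_strand=f.strand,
                    )
                )
    return hits


def _hit_category(hit: MappingHit) -> str:
    cls = hit.class_label
    if cls is None:
        return "unannotated"
    if cls in GENBANK_CLASSES:
        return "GenBank"
    if cls == "rfam":
        return "Rfam"
    if cls == "miRNA":
        return "known_miRNA"
    if cls in ("exon", "intron"):
        sense = hit.strand == hit.feature_strand
        return f"{cls}_{'sense' if sense else 'antisense'}"
    if cls in ("repeat", "siRNA"):
        return cls
    return "unannotated"


def classify_tag(tag: str, hits: Iterable[MappingHit]) -> AnnotationAssignment:
    """Assign the single highest-priority category among a tag's hits.

    Ties within a category resolve to the lexicographically smallest
    feature_id (determinism only; the category is unaffected).
    """
    own = tuple(h for h in hits if h.tag == tag)
    if not own:
        return AnnotationAssignment(tag=tag, category="unannotated")
    best = min(
        own, key=lambda h: (_PRIORITY[_hit_category(h)], h.feature_id or "~", h.start)
    )
    return AnnotationAssignment(tag=tag, category=_hit_category(best), hits=own)


def annotate_tags(
    tags: Mapping[str, SmallRNATag],
    genome: str | GenomeIndex,
    features: list[Feature],
) -> dict[str, AnnotationAssignment]:
    """Map and classify a whole collapsed tag set."""
    hits = map_tags(tags.keys(), genome, features)
    by_tag: dict[str, list[MappingHit]] = defaultdict(list)
    for h in hits:
        by_tag[h.tag].append(h)
    return {seq: classify_tag(seq, by_tag.get(seq, ())) for seq in tags}


def summarize_classes(
    assignments: Mapping[str, AnnotationAssignment],
    tags: Mapping[str, SmallRNATag],
    libraries: Iterable[SRNALibrary],
) -> pd.DataFrame:
    """Per-category unique-tag and total-read counts for each library.

    The category totals are a partition: per library they sum to the clean
    read count, and unique counts sum to the number of tags with reads in
    that library.
    """
    libs = list(libraries)
    rows = []
    for cat in CATEGORIES:
        row: dict[str, object] = {"category": cat}
        for lib in libs:
            unique = total = 0
            for seq, a in assignments.items():
                if a.category != cat:
                    continue
                n = tags[seq].counts.get(lib.library_id, 0)
                if n:
                    unique += 1
                    total += n
            row[f"{lib.library_id}_unique"] = unique
            row[f"{lib.library_id}_total"] = total
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def assignments_table(
    assignments: Mapping[str, AnnotationAssignment]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"tag": seq, "category": a.category, "n_hits": len(a.hits)}
            for seq, a in sorted(assignments.items())
        ]
    )
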
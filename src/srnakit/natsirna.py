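"""siRNA quantification over natural antisense transcript (NAT) gene pairs.

A NAT pair is two genes producing complementary transcripts: *cis* pairs
overlap on opposite strands of one locus, *trans* pairs pair complementary
segments of two loci.  Reads are counted over the overlap region (OL) and
the whole-gene regions (WL) of each pair: a read counts in a region iff its
exact genomic match is fully contained in the region's interval, every
mapping position counts, and each hit carries the orientation of the genome
strand its sequence matches (+ forward, - reverse complement).  Per-pair OL
totals are then tested between libraries with the tag-count statistic, and
pairs significant in both treatment libraries against the control are
flagged as altered in both lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from . import abundance_stats
from .annotation import GenomeIndex
from .read_processing import SmallRNATag


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval on a named strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed interval [{self.start}, {self.end})")

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass(frozen=True)
class NATPair:
    """A cis or trans NAT gene pair with OL and WL counting windows.

    For cis pairs ``ol`` is the genomic overlap, contained in both WL
    intervals, and the genes sit on opposite strands.  For trans pairs
    ``ol`` and ``ol_b`` are the paired complementary segments (one per
    gene) and their counts are pooled.
    """

    pair_id: str
    pair_type: str
    gene_a: str
    wl_a: Interval
    gene_b: str
    wl_b: Interval
    ol: Interval
    ol_b: Interval | None = None

    def __post_init__(self) -> None:
        if self.pair_type not in ("cis", "trans"):
            raise ValueError("pair_type must be cis or trans")
        if self.pair_type == "cis":
            if self.wl_a.strand == self.wl_b.strand:
                raise ValueError("cis pair genes must be on opposite strands")
            for wl in (self.wl_a, self.wl_b):
                if not wl.contains(self.ol.start, self.ol.end):
                    raise ValueError("cis OL must be contained in both WL intervals")

    def region(self, name: str) -> list[Interval]:
        if name == "OL":
            return [self.ol] + ([self.ol_b] if self.ol_b else [])
        if name == "WL_a":
            return [self.wl_a]
        if name == "WL_b":
            return [self.wl_b]
        raise ValueError(f"unknown region {name!r}")


@dataclass
class NATRegionCount:
    pair_id: str
    region: str
    library_id: str
    plus: int = 0
    minus: int = 0

    @property
    def total(self) -> int:
        return self.plus + self.minus


REGIONS = ("OL", "WL_a", "WL_b")


def count_region(
    tags: Mapping[str, SmallRNATag],
    pair: NATPair,
    region: str,
    genome: str | GenomeIndex,
    library_id: str,
) -> NATRegionCount:
    """Count reads of one library whose exact genomic hits fall fully inside
    the region; + and - orientations are tallied separately and a palindromic
    tag matching both strands at one locus counts once per orientation."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(
        genome, {len(t) for t in tags}
    )
    intervals = pair.region(region)
    out = NATRegionCount(pair_id=pair.pair_id, region=region, library_id=library_id)
    for seq, tag in tags.items():
        n = tag.counts.get(library_id, 0)
        if n == 0:
            continue
        for strand, start in index.find(seq):
            if any(iv.contains(start, start + len(seq)) for iv in intervals):
                if strand == "+":
                    out.plus += n
                else:
                    out.minus += n
    return out


def count_all_regions(
    tags: Mapping[str, SmallRNATag],
    pairs: Iterable[NATPair],
    genome: str | GenomeIndex,
    library_ids: Iterable[str],
) -> pd.DataFrame:
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(
        genome, {len(t) for t in tags}
    )
    rows = []
    for pair in pairs:
        for region in REGIONS:
            for lib in library_ids:
                c = count_region(tags, pair, region, index, lib)
                rows.append(
                    {
                        "pair_id": c.pair_id,
                        "region": c.region,
                        "library_id": c.library_id,
                        "plus": c.plus,
                        "minus": c.minus,
                        "total": c.total,
                    }
                )
    return pd.DataFrame(rows)


def natsirna_de(
    region_counts: pd.DataFrame,
    control: str,
    treatment: str,
    n1: int,
    n2: int,
) -> pd.DataFrame:
    """Test per-pair OL totals (orientations pooled) between two libraries."""
    ol = region_counts[region_counts["region"] == "OL"]
    table = ol.pivot_table(index="pair_id", columns="library_id", values="total", fill_value=0)
    for lib in (control, treatment):
        if lib not in table.columns:
            table[lib] = 0
    return abundance_stats.de_table(table.astype(int), control, treatment, n1, n2)


def altered_in_both(
    de_t1: pd.DataFrame, de_t2: pd.DataFrame
) -> pd.DataFrame:
    """Pairs called non-equal in the same direction against the control in
    both treatment libraries."""
    a = de_t1.set_index("id")["call"]
    b = de_t2.set_index("id")["call"]
    both = a.index.intersection(b.index)
    keep = [i for i in both if a[i] != "equal" and a[i] == b[i]]
    return pd.DataFrame({"pair_id": keep, "call": [a[i] for i in keep]})
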
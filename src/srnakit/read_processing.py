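"""Raw FASTQ to clean, collapsed unique small-RNA tags.

Processing follows the standard sRNA-seq preprocessing chain: locate the 3'
adapter in each read and keep the insert upstream of it, drop reads with no
adapter (their insert end is undefined), drop inserts outside 18-30 nt or
containing ambiguous bases, then collapse identical inserts into unique tags
with per-library counts.  The total of retained reads is the library's
clean-read count, which downstream serves as the normalization denominator
(N1/N2) of the differential statistic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

MIN_LEN = 18
MAX_LEN = 30
ADAPTER_SEED = 8


@dataclass
class SmallRNATag:
    """A unique 18-30 nt sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SRNALibrary:
    """One sequencing library and its read-accounting totals."""

    library_id: str
    tissue: str = "leaf"
    genotype: str = "WT"
    raw_read_count: int = 0
    clean_read_count: int = 0


def trim_adapter(read: str, adapter3: str) -> str | None:
    """Return the insert upstream of the left-most exact match of the 3'
    adapter's first ``ADAPTER_SEED`` nucleotides, or None when the seed is
    absent (the read is discarded)."""
    if len(adapter3) < ADAPTER_SEED:
        raise ValueError(f"3' adapter must be at least {ADAPTER_SEED} nt")
    pos = read.find(adapter3[:ADAPTER_SEED])
    if pos < 0:
        return None
    return read[:pos]


def _valid_insert(insert: str) -> bool:
    if not (MIN_LEN <= len(insert) <= MAX_LEN):
        return False
    return all(base in "ACGT" for base in insert)


def clean_and_collapse(
    inserts: Iterable[str], library: SRNALibrary
) -> dict[str, SmallRNATag]:
    """Length-filter, drop ambiguous bases, and collapse identical inserts.

    Updates ``library.clean_read_count`` to the number of retained reads and
    returns the tag set keyed by sequence.  Conservation: the sum of tag
    counts equals the clean-read count.
    """
    counter = Counter(s.upper() for s in inserts)
    tags: dict[str, SmallRNATag] = {}
    clean = 0
    for seq, n in sorted(counter.items()):
        if not _valid_insert(seq):
            continue
        tags[seq] = SmallRNATag(sequence=seq, counts={library.library_id: n})
        clean += n
    library.clean_read_count = clean
    return tags


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    for record in SeqIO.parse(str(path), "fastq"):
        yield str(record.seq).upper()


def process_fastq(
    path: str | Path, library: SRNALibrary, adapter3: str
) -> dict[str, SmallRNATag]:
    """Full per-library preprocessing: trim, filter, collapse."""
    raw = 0
    inserts = []
    for seq in iter_fastq_sequences(path):
        raw += 1
        insert = trim_adapter(seq, adapter3)
        if insert is not None:
            inserts.append(insert)
    library.raw_read_count = raw
    return clean_and_collapse(inserts, library)


def merge_tag_sets(tag_sets: Iterable[dict[str, SmallRNATag]]) -> dict[str, SmallRNATag]:
    """Union per-library tag sets into one set with merged count maps."""
    merged: dict[str, SmallRNATag] = {}
    for tags in tag_sets:
        for seq, tag in tags.items():
            if seq not in merged:
                merged[seq] = SmallRNATag(sequence=seq, counts=dict(tag.counts))
            else:
                for lib, n in tag.counts.items():
                    merged[seq].counts[lib] = merged[seq].counts.get(lib, 0) + n
    return merged


def length_distribution(
    tags: dict[str, SmallRNATag], library_id: str | None = None
) -> pd.DataFrame:
    """Histogram over 18..30 nt, by unique tags and by total reads.

    When ``library_id`` is given only that library's counts enter the total
    column (a tag still counts as unique if it has reads in that library).
    """
    unique = {L: 0 for L in range(MIN_LEN, MAX_LEN + 1)}
    total = {L: 0 for L in range(MIN_LEN, MAX_LEN + 1)}
    for tag in tags.values():
        n = tag.total if library_id is None else tag.counts.get(library_id, 0)
        if n == 0:
            continue
        unique[len(tag)] += 1
        total[len(tag)] += n
    return pd.DataFrame(
        {"length": list(unique), "unique": list(unique.values()), "total": list(total.values())}
    ).set_index("length")


def write_collapsed_fasta(tags: dict[str, SmallRNATag], path: str | Path) -> None:
    """Collapsed tags as FASTA with headers ``tag_<i>_x<count>``, ordered by
    descending total count then sequence."""
    ordered = sorted(tags.values(), key=lambda t: (-t.total, t.sequence))
    with open(path, "w") as fh:
        for i, tag in enumerate(ordered, start=1):
            fh.write(f">tag_{i}_x{tag.total}\n{tag.sequence}\n")


def library_stats(libraries: Iterable[SRNALibrary]) -> pd.DataFrame:
    rows = [
        {
            "library_id": lib.library_id,
            "tissue": lib.tissue,
            "genotype": lib.genotype,
            "raw_reads": lib.raw_read_count,
            "clean_reads": lib.clean_read_count,
            "pct_clean": 100.0 * lib.clean_read_count / lib.raw_read_count
            if lib.raw_read_count
            else 0.0,
        }
        for lib in libraries
    ]
    return pd.DataFrame(rows)
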
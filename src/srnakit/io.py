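"""File interchange: FASTA via Biopython, GFF3 feature tables, TSV helpers.

Internal coordinates are 0-based half-open everywhere; GFF3 output follows
the GFF3 convention of 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Feature:
    """A genome feature with a small-RNA annotation class label.

    ``start``/``end`` are 0-based half-open on the forward genome strand.
    ``class_label`` is one of rRNA/tRNA/snRNA/snoRNA/scRNA/rfam/miRNA/
    repeat/exon/intron/siRNA.
    """

    feature_id: str
    class_label: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(features: list[Feature], path: str | Path, seqid: str = "minigenome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id};class={f.class_label}"
            fh.write(
                f"{seqid}\tsrnakit\t{f.class_label}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            features.append(
                Feature(
                    feature_id=attrs.get("ID", cols[2]),
                    class_label=attrs.get("class", cols[2]),
                    strand=cols[6],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                )
            )
    return features
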
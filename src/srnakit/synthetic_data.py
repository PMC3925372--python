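"""Miniature references and read libraries with the structure the analysis assumes.

The generator builds a desk-scale mini-genome (~50 kb) carrying one instance
of every feature class the annotation hierarchy knows (rRNA, tRNA, snRNA,
snoRNA, Rfam ncRNA, repeat, exon/intron gene models, a heterochromatic
siRNA locus), a set of miRNA hairpin precursors, TAS-like loci with a
defined initiator-cleavage site and a phased 21-nt siRNA train downstream
of it, cis- and trans-NAT gene pairs, and a small transcriptome of PPR/TPR
and other target mRNAs carrying planted complementary sites.

Simulated libraries emulate the empirical shape of plant sRNA-seq data:
18-30 nt inserts with length peaks at 21 nt (miRNA/tasiRNA) and 24 nt
(heterochromatic siRNA), an extra tRNA-derived 19-nt peak in root
libraries, per-condition abundance multipliers for designated miRNAs, TAS
loci and NAT regions, configurable phasing fidelity on TAS loci, and a
fraction of adapter-free decoy reads.  Reads are emitted as insert plus the
full 3' adapter at constant Q40, alongside a truth table recording every
read's source.  All randomness flows from an explicit integer seed;
identical seeds give byte-identical outputs.

The background sequence is patched so that neither the 3'-adapter's 8-nt
seed nor its reverse complement occurs in the genome or transcriptome,
keeping adapter trimming exact on noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import revcomp
from .io import Feature, write_fasta, write_gff3
from .natsirna import Interval, NATPair
from .tasirna import TasLocus

_BASES = np.array(list("ACGT"))

#: classic Illumina small-RNA adapters (any fixed string works; the 3' seed
#: must be at least 8 nt)
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"

#: 19-nt 5' fragment of a Gly-tRNA-like gene, the dominant root tRNA read
TRNA19 = "GCATTGGTGGTTCAGTGGT"

DEFAULT_LENGTH_WEIGHTS = {
    18: 0.02, 19: 0.03, 20: 0.06, 21: 0.30, 22: 0.07, 23: 0.08,
    24: 0.28, 25: 0.06, 26: 0.03, 27: 0.02, 28: 0.02, 29: 0.01, 30: 0.02,
}

CONDITIONS = tuple(
    f"{tissue}_{genotype}"
    for tissue in ("leaf", "root")
    for genotype in ("WT", "pap2", "OE7", "OE21")
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study-like conditions."""

    reads_per_library: int = 20_000
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    adapter5: str = ADAPTER5
    adapter3: str = ADAPTER3
    #: source-class mixture of a leaf library (root swaps the tRNA weight)
    class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "mirna": 0.20,
            "tasirna": 0.12,
            "sirna24": 0.26,
            "trna": 0.04,
            "genic": 0.16,
            "novel": 0.02,
            "nat": 0.12,
            "decoy": 0.08,
        }
    )
    #: tRNA-fragment class weight used in root libraries (19-nt peak)
    root_trna_weight: float = 0.25
    #: condition -> source id -> abundance multiplier
    multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    phasing_fidelity: float = 0.9
    noise_rate: float = 0.0
    seed: int = 0
    # reference shape
    n_mirnas: int = 8
    n_novel_mirnas: int = 2
    n_tas: int = 4
    mature_length: int = 21
    loop_length: int = 18
    tas_phases: int = 8
    genome_size: int = 50_000  # padded with background up to this length

    def validate(self) -> None:
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if len(self.adapter3) < 8:
            raise ValueError("3' adapter must be at least 8 nt")
        for w in list(self.length_weights.values()) + list(self.class_weights.values()):
            if w < 0:
                raise ValueError("weights must be nonnegative")
        if abs(sum(self.class_weights.values()) - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")
        if not 0.0 <= self.phasing_fidelity <= 1.0:
            raise ValueError("phasing_fidelity must be in [0, 1]")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        for cond, mults in self.multipliers.items():
            for key, m in mults.items():
                if m <= 0:
                    raise ValueError(f"multiplier {key}={m} in {cond} must be > 0")
        if self.loop_length < 15:
            raise ValueError("loop shorter than 15 nt cannot form a screened hairpin")


@dataclass
class MirnaRecord:
    mirna_id: str
    precursor: str
    mature: str
    arm: str
    star: str


@dataclass
class SyntheticReference:
    """Mini-genome plus every companion reference the pipeline consumes."""

    genome: str
    features: list[Feature]
    mirnas: list[MirnaRecord]
    novel_mirnas: list[MirnaRecord]
    tas_loci: list[TasLocus]
    tas_offsets: dict[str, int]  # locus_id -> 0-based genomic start of cDNA
    nat_pairs: list[NATPair]
    transcriptome: dict[str, str]
    families: dict[str, str]  # transcript_id -> PPR / TPR / other
    trna_fragment: str = TRNA19


def default_multipliers() -> dict[str, dict[str, float]]:
    """Study-like abundance shifts: in OE leaf the initiator miR173 and a
    designated miRNA rise, the TAS1-like loci rise with them, one miRNA and
    the TAS4-like locus fall, and one cis-NAT OL region is strongly up."""
    up4 = {"miR158": 4.0, "miR172": 4.0}
    oe_leaf = {
        **up4,
        "miR173": 3.0,
        "miR391": 0.25,
        "TAS1A": 2.5,
        "TAS1B": 2.5,
        "TAS4": 0.2,
        "natpair_cis1_OL": 10.0,
    }
    oe_root = {"miR158": 4.0, "miR391": 0.25}
    out: dict[str, dict[str, float]] = {c: {} for c in CONDITIONS}
    for g in ("OE7", "OE21"):
        out[f"leaf_{g}"] = dict(oe_leaf)
        out[f"root_{g}"] = dict(oe_root)
    return out


def default_config(seed: int = 0) -> SimulationConfig:
    cfg = SimulationConfig(seed=seed, multipliers=default_multipliers())
    cfg.validate()
    return cfg


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _patch_forbidden(seq: str, forbidden: tuple[str, ...], rng: np.random.Generator) -> str:
    """Substitute one base inside every occurrence of a forbidden word until
    none remain (keeps adapter seeds out of reference sequence)."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        joined = "".join(s)
        for word in forbidden:
            pos = joined.find(word)
            if pos >= 0:
                mid = pos + len(word) // 2
                old = s[mid]
                s[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
                changed = True
    return "".join(s)


def _clean_random_seq(rng: np.random.Generator, n: int, forbidden: tuple[str, ...]) -> str:
    return _patch_forbidden(_random_seq(rng, n), forbidden, rng)


def build_reference(config: SimulationConfig, seed: int) -> SyntheticReference:
    """Deterministically assemble the mini-genome and companion references."""
    config.validate()
    if config.mature_length + 8 > 2 * config.mature_length:
        raise ValueError("contradictory hairpin geometry")
    rng = np.random.default_rng(seed)
    seed8 = config.adapter3[:8]
    forbidden = (seed8, revcomp(seed8))

    def rand(n: int) -> str:
        return _clean_random_seq(rng, n, forbidden)

    parts: list[str] = []
    features: list[Feature] = []
    cursor = 0

    def emit(seq: str, feature_id: str | None, class_label: str | None, strand: str = "+") -> int:
        nonlocal cursor
        start = cursor
        parts.append(seq)
        cursor += len(seq)
        if feature_id is not None:
            features.append(Feature(feature_id, class_label, strand, start, start + len(seq)))
        return start

    def spacer(n: int = 400) -> None:
        emit(rand(n), None, None)

    # GenBank-style structural ncRNAs
    spacer()
    emit(rand(1200), "rRNA_1", "rRNA")
    spacer()
    emit(TRNA19 + rand(55), "tRNA_Gly_1", "tRNA")
    spacer()
    emit(rand(160), "snoRNA_1", "snoRNA")
    spacer()
    emit(rand(140), "snRNA_1", "snRNA")
    spacer()
    emit(rand(120), "rfam_nc_1", "rfam")
    spacer()
    emit(rand(800), "repeat_1", "repeat")
    spacer()
    emit(rand(600), "sirna_locus_1", "siRNA")
    spacer()
    # protein-coding gene model: exon / intron / exon
    emit(rand(220), "gene1_exon1", "exon")
    emit(rand(150), "gene1_intron1", "intron")
    emit(rand(220), "gene1_exon2", "exon")

    # miRNA precursors: ungapped hairpin = mature + loop + perfect star
    mirna_names = ["miR173", "miR158", "miR172", "miR391", "miR396", "miR397", "miR842", "miR846"]
    mirnas: list[MirnaRecord] = []
    for i in range(config.n_mirnas):
        name = mirna_names[i] if i < len(mirna_names) else f"miR_nov{i:02d}"
        mature = rand(config.mature_length)
        loop = rand(config.loop_length)
        star = revcomp(mature)
        arm = "5p" if i % 2 == 0 else "3p"
        precursor = mature + loop + star if arm == "5p" else star + loop + mature
        spacer(250)
        emit(precursor, f"{name}_precursor", "miRNA")
        mirnas.append(MirnaRecord(name, precursor, mature, arm, star))

    # hairpins with no annotation: sources of "novel" miRNA candidates
    novel_mirnas: list[MirnaRecord] = []
    for i in range(config.n_novel_mirnas):
        name = f"novel{i + 1:02d}"
        mature = rand(config.mature_length)
        loop = rand(config.loop_length)
        star = revcomp(mature)
        arm = "5p" if i % 2 == 0 else "3p"
        precursor = mature + loop + star if arm == "5p" else star + loop + mature
        spacer(250)
        emit(precursor, None, None)
        novel_mirnas.append(MirnaRecord(name, precursor, mature, arm, star))

    # TAS-like loci: prefix ending at the initiator cleavage site, then a
    # phased train of 21-nt tasiRNAs, then a tail.  The 21 nt upstream of the
    # cleavage site are the perfect complement of the initiator miRNA.
    initiator = mirnas[0]
    tas_names = ["TAS1A", "TAS1B", "TAS2", "TAS4", "TAS3A"]
    tas_loci: list[TasLocus] = []
    tas_offsets: dict[str, int] = {}
    phase = config.mature_length
    for i in range(config.n_tas):
        name = tas_names[i] if i < len(tas_names) else f"TASX{i}"
        prefix = rand(60) + revcomp(initiator.mature)
        train = rand(phase * config.tas_phases)
        cdna = prefix + train + rand(40)
        spacer(250)
        start = emit(cdna, f"{name}_locus", "siRNA")
        tas_loci.append(TasLocus(name, cdna, len(prefix) + 1))
        tas_offsets[name] = start

    # cis-NAT pair: overlapping genes on opposite strands
    spacer()
    nat_start = emit(rand(1000), None, None)
    wl_a = Interval(nat_start, nat_start + 600, "+")
    wl_b = Interval(nat_start + 400, nat_start + 1000, "-")
    ol = Interval(nat_start + 400, nat_start + 600, "+")
    features.append(Feature("natA_1", "exon", "+", wl_a.start, wl_a.end))
    features.append(Feature("natB_1", "exon", "-", wl_b.start, wl_b.end))
    cis_pair = NATPair("natpair_cis1", "cis", "natA_1", wl_a, "natB_1", wl_b, ol)

    # trans-NAT pair: complementary segments on two distant genes
    spacer()
    seg = rand(180)
    c_start = emit(rand(120) + seg + rand(120), None, None)
    spacer()
    d_start = emit(rand(100) + revcomp(seg) + rand(140), None, None)
    wl_c = Interval(c_start, c_start + 420, "+")
    wl_d = Interval(d_start, d_start + 420, "+")
    ol_c = Interval(c_start + 120, c_start + 300, "+")
    ol_d = Interval(d_start + 100, d_start + 280, "+")
    features.append(Feature("natC_1", "exon", "+", wl_c.start, wl_c.end))
    features.append(Feature("natD_1", "exon", "+", wl_d.start, wl_d.end))
    trans_pair = NATPair(
        "natpair_trans1", "trans", "natC_1", wl_c, "natD_1", wl_d, ol_c, ol_b=ol_d
    )
    spacer()
    if cursor < config.genome_size:
        emit(rand(config.genome_size - cursor), None, None)

    genome = "".join(parts)

    # transcriptome: PPR/TPR mRNAs with planted perfect-complement sites of
    # the first phased tasiRNA of each TAS locus, plus target mRNAs of the
    # designated miRNAs
    transcriptome: dict[str, str] = {}
    families: dict[str, str] = {}
    for i, locus in enumerate(tas_loci):
        tasi = locus.cdna[locus.cleavage_position - 1 : locus.cleavage_position - 1 + phase]
        fam = "PPR" if i % 2 == 0 else "TPR"
        tid = f"{fam}_t{i + 1:02d}"
        transcriptome[tid] = rand(180) + revcomp(tasi) + rand(180)
        families[tid] = fam
    for j, rec in enumerate(mirnas[:4]):
        tid = f"target_{rec.mirna_id}"
        transcriptome[tid] = rand(150) + revcomp(rec.mature) + rand(150)
        families[tid] = "other"

    ref = SyntheticReference(
        genome=genome,
        features=features,
        mirnas=mirnas,
        novel_mirnas=novel_mirnas,
        tas_loci=tas_loci,
        tas_offsets=tas_offsets,
        nat_pairs=[cis_pair, trans_pair],
        transcriptome=transcriptome,
        families=families,
    )
    _check_reference(ref)
    return ref


def _check_reference(ref: SyntheticReference) -> None:
    for rec in ref.mirnas + ref.novel_mirnas:
        if rec.mature not in rec.precursor:
            raise AssertionError("mature not in precursor")
        if rec.precursor not in ref.genome:
            raise AssertionError("precursor not locatable in genome")
    for locus in ref.tas_loci:
        if locus.cdna not in ref.genome:
            raise AssertionError("TAS cDNA not locatable in genome")
    for pair in ref.nat_pairs:
        if pair.pair_type == "cis":
            for wl in (pair.wl_a, pair.wl_b):
                assert wl.contains(pair.ol.start, pair.ol.end)


# ---------------------------------------------------------------------------
# library simulation


def _sources(
    ref: SyntheticReference, config: SimulationConfig, condition: str
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Flat list of (class, source_id) with absolute expected weights; the
    base weights sum to 1 before multipliers are applied."""
    tissue = condition.split("_")[0]
    weights = dict(config.class_weights)
    if tissue == "root":
        weights["trna"] = config.root_trna_weight
        rest = sum(v for k, v in weights.items() if k != "trna")
        scale = (1.0 - weights["trna"]) / rest
        for k in weights:
            if k != "trna":
                weights[k] *= scale
    mult = config.multipliers.get(condition, {})
    sources: list[tuple[str, str]] = []
    w: list[float] = []

    def add(cls: str, members: list[str]) -> None:
        for m in members:
            sources.append((cls, m))
            w.append(weights[cls] / len(members) * mult.get(m, 1.0))

    add("mirna", [r.mirna_id for r in ref.mirnas])
    add("novel", [r.mirna_id for r in ref.novel_mirnas])
    add("tasirna", [t.locus_id for t in ref.tas_loci])
    add("sirna24", ["sirna_locus_1", "repeat_1"])
    add("trna", ["tRNA_Gly_1"])
    add("genic", ["background"])
    nat_regions = []
    for pair in ref.nat_pairs:
        nat_regions += [f"{pair.pair_id}_OL", f"{pair.pair_id}_WLonly"]
    add("nat", nat_regions)
    add("decoy", ["decoy"])
    return sources, np.asarray(w)


def _feature_map(ref: SyntheticReference) -> dict[str, Feature]:
    return {f.feature_id: f for f in ref.features}


def _sample_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    lengths = np.array(sorted(config.length_weights))
    p = np.array([config.length_weights[L] for L in lengths], dtype=float)
    return int(rng.choice(lengths, p=p / p.sum()))


def _window_read(rng: np.random.Generator, seq: str, length: int, stranded: bool = False) -> tuple[str, str]:
    start = int(rng.integers(0, len(seq) - length + 1))
    insert = seq[start : start + length]
    if stranded or rng.random() < 0.5:
        return insert, "+"
    return revcomp(insert), "-"


def simulate_library(
    ref: SyntheticReference,
    config: SimulationConfig,
    condition: str,
    seed: int,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate one library for a condition label like ``leaf_OE7``.

    Returns (reads, truth): ``reads`` is a list of (read_id, read sequence
    including the full 3' adapter for non-decoy reads); ``truth`` records
    each read's source class and id, intended insert length, whether it
    carries the adapter, and for TAS reads whether it is in phase register 0.
    Deterministic for a fixed seed.
    """
    if condition not in CONDITIONS and condition not in config.multipliers:
        raise ValueError(f"unknown condition label {condition!r}")
    config.validate()
    rng = np.random.default_rng(seed)
    sources, w = _sources(ref, config, condition)
    n_reads = int(round(config.reads_per_library * w.sum()))
    counts = rng.multinomial(n_reads, w / w.sum())
    fmap = _feature_map(ref)
    tas_by_id = {t.locus_id: t for t in ref.tas_loci}
    mir_by_id = {r.mirna_id: r for r in ref.mirnas + ref.novel_mirnas}
    nat_by_id = {p.pair_id: p for p in ref.nat_pairs}

    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    idx = 0
    phase = config.mature_length
    for (cls, source_id), n in zip(sources, counts):
        for _ in range(int(n)):
            in_register = ""
            has_adapter = True
            if cls in ("mirna", "novel"):
                insert = mir_by_id[source_id].mature
            elif cls == "tasirna":
                locus = tas_by_id[source_id]
                c0 = locus.cleavage_position - 1
                region_len = phase * config.tas_phases
                if rng.random() < config.phasing_fidelity:
                    k = int(rng.integers(0, config.tas_phases))
                    start = c0 + phase * k
                    in_register = "1"
                else:
                    off = int(rng.integers(1, phase))
                    k = int(rng.integers(0, config.tas_phases - 1))
                    start = c0 + phase * k + off
                    in_register = "0"
                insert = locus.cdna[start : start + phase]
            elif cls == "sirna24":
                f = fmap[source_id]
                insert, _ = _window_read(rng, ref.genome[f.start : f.end], 24)
            elif cls == "trna":
                insert = ref.trna_fragment
            elif cls == "genic":
                length = _sample_length(rng, config)
                insert, _ = _window_read(rng, ref.genome, length)
            elif cls == "nat":
                pair_id, region = source_id.rsplit("_", 1)
                pair = nat_by_id[pair_id]
                if region == "OL":
                    ivs = pair.region("OL")
                else:  # WL but outside OL, so OL <= WL stays strict
                    ivs = [Interval(pair.wl_a.start, pair.ol.start, "+")]
                iv = ivs[int(rng.integers(0, len(ivs)))]
                length = min(_sample_length(rng, config), iv.end - iv.start)
                insert, _ = _window_read(rng, ref.genome[iv.start : iv.end], length)
            else:  # decoy: no adapter -> discarded by trimming
                insert = _clean_random_seq(
                    rng, 30 + int(rng.integers(0, 10)),
                    (config.adapter3[:8], revcomp(config.adapter3[:8])),
                )
                has_adapter = False
            if config.noise_rate > 0 and rng.random() < config.noise_rate:
                pos = int(rng.integers(0, len(insert)))
                alt = str(rng.choice([b for b in "ACGT" if b != insert[pos]]))
                insert = insert[:pos] + alt + insert[pos + 1 :]
            read = insert + config.adapter3 if has_adapter else insert
            read_id = f"{condition}_{idx:06d}"
            idx += 1
            reads.append((read_id, read))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "source_class": cls,
                    "source_id": source_id,
                    "intended_length": len(insert),
                    "has_adapter": int(has_adapter),
                    "in_register": in_register,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def write_library(
    reads: list[tuple[str, str]],
    truth: pd.DataFrame,
    outdir: str | Path,
    condition: str,
) -> tuple[Path, Path]:
    """Write a simulated library as FASTQ (constant Q40) + truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastq = outdir / f"{condition}.fastq"
    with open(fastq, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    truth_path = outdir / f"{condition}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return fastq, truth_path


def write_reference(ref: SyntheticReference, outdir: str | Path) -> None:
    """Write the reference bundle: genome FASTA, features GFF3, miRNA
    precursor/mature FASTA, TAS cDNA FASTA + cleavage TSV, NAT pair TSV,
    transcriptome FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta({"minigenome": ref.genome}, outdir / "genome.fa")
    write_gff3(ref.features, outdir / "features.gff3")
    write_fasta(
        {f"{r.mirna_id}_precursor": r.precursor for r in ref.mirnas},
        outdir / "mirna_precursors.fa",
    )
    write_fasta({r.mirna_id: r.mature for r in ref.mirnas}, outdir / "mirna_mature.fa")
    write_fasta({t.locus_id: t.cdna for t in ref.tas_loci}, outdir / "tas_cdna.fa")
    pd.DataFrame(
        [
            {"locus_id": t.locus_id, "cleavage_position": t.cleavage_position}
            for t in ref.tas_loci
        ]
    ).to_csv(outdir / "tas_cleavage.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "type": p.pair_type,
                "gene_a": p.gene_a,
                "a_start": p.wl_a.start + 1,
                "a_end": p.wl_a.end,
                "a_strand": p.wl_a.strand,
                "gene_b": p.gene_b,
                "b_start": p.wl_b.start + 1,
                "b_end": p.wl_b.end,
                "b_strand": p.wl_b.strand,
                "ol_start": p.ol.start + 1,
                "ol_end": p.ol.end,
                "ol_b_start": p.ol_b.start + 1 if p.ol_b else "",
                "ol_b_end": p.ol_b.end if p.ol_b else "",
            }
            for p in ref.nat_pairs
        ]
    ).to_csv(outdir / "nat_pairs.tsv", sep="\t", index=False)
    write_fasta(ref.transcriptome, outdir / "transcriptome.fa")
    pd.DataFrame(
        [{"transcript_id": t, "family": fam} for t, fam in ref.families.items()]
    ).to_csv(outdir / "transcript_families.tsv", sep="\t", index=False)
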
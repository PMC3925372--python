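"""Hairpin-precursor screen for novel miRNA candidates.

Unannotated tags are tested for miRNA-like origin by extracting the genomic
sequence flanking each mapping position and searching it for a stem-loop
fold that carries the tag on one arm.  The fold engine is a deliberately
simple ungapped arm-pairing search, not a thermodynamic folder: for a
hairpin whose stem is ungapped, a base at window position i pairs with the
base at position c - i for a single pairing constant c, so scanning c scans
all candidate ungapped stems.  A candidate is accepted when

    * the mature tag lies wholly on one arm,
    * at least ``min_paired`` of its positions pair with the star arm
      (Watson-Crick or G:U),
    * the loop between the arms is at least ``min_loop`` nt, and
    * the stem energy (same per-pair stand-in scores as target prediction)
      is at or below ``max_energy``.

Accepted candidates are named ``<tissue>_miRNA%04d_<arm>`` in order of
descending read count, and a reported subset keeps those with summed counts
above ``report_min_count`` reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .annotation import GenomeIndex, MappingHit, revcomp
from .read_processing import SmallRNATag
from .target_prediction import PAIR_ENERGIES, pair_state

DEFAULT_WINDOW = 250
MIN_LOOP = 15
MAX_ENERGY = -30.0
UNPAIRED_ALLOWANCE = 4  # a 21-nt mature must pair at >= 17 positions
REPORT_MIN_COUNT = 100


@dataclass
class FlankWindow:
    """Genomic window on the hit strand containing the mature tag."""

    sequence: str
    mature_offset: int
    chrom_start: int  # forward-genome start of the window, 0-based
    strand: str


@dataclass
class HairpinCandidate:
    tag: str
    window: FlankWindow
    arm: str = ""
    star: str = ""
    stem_pairs: int = 0
    energy: float = 0.0
    loop_length: int = 0
    status: str = "rejected(no_valid_fold)"
    name: str = ""
    total_count: int = 0

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def extract_flank(
    genome: str, hit: MappingHit, window: int = DEFAULT_WINDOW
) -> FlankWindow:
    """Window of ``window`` nt centred on the tag, on the hit strand,
    truncated at contig ends."""
    L = len(hit.tag)
    if hit.start < 0 or hit.start + L > len(genome):
        raise ValueError("hit lies outside the contig")
    pad = (window - L) // 2
    lo = max(0, hit.start - pad)
    hi = min(len(genome), hit.start + L + pad)
    seq = genome[lo:hi]
    offset = hit.start - lo
    if hit.strand == "-":
        seq = revcomp(seq)
        offset = len(seq) - (offset + L)
    return FlankWindow(sequence=seq, mature_offset=offset, chrom_start=lo, strand=hit.strand)


def _pairs(a: str, b: str) -> bool:
    return pair_state(a, b) != "mismatch"


def _stem_energy(window: str, c: int, energies: Mapping[str, float]) -> tuple[float, int]:
    """Energy and pair count of the full ungapped stem along constant c."""
    energy = 0.0
    pairs = 0
    lo = max(0, c - len(window) + 1)
    for i in range(lo, (c + 1) // 2):
        a, b = window[i], window[c - i]
        state = pair_state(a, b)
        if state == "mismatch":
            continue
        pairs += 1
        if state == "GU":
            energy += energies["GU"]
        else:
            energy += energies["GC"] if a in "GC" else energies["AU"]
    return energy, pairs


def hairpin_screen(
    window: FlankWindow | str,
    mature: str,
    min_loop: int = MIN_LOOP,
    max_energy: float = MAX_ENERGY,
    unpaired_allowance: int = UNPAIRED_ALLOWANCE,
    pair_energies: Mapping[str, float] = PAIR_ENERGIES,
) -> HairpinCandidate:
    """Search the window for the best ungapped stem-loop placing the mature
    tag on one arm; returns an accepted or rejected(reason) candidate."""
    if isinstance(window, str):
        off = window.find(mature)
        window = FlankWindow(sequence=window, mature_offset=off, chrom_start=0, strand="+")
    seq = window.sequence.upper()
    m, L = window.mature_offset, len(mature)
    cand = HairpinCandidate(tag=mature, window=window)
    if m < 0 or seq[m : m + L] != mature:
        cand.status = "rejected(mature_not_in_window)"
        return cand
    min_paired = L - unpaired_allowance
    best = None  # (paired, -|energy|) maximized
    for c in range(2 * len(seq) - 2):
        star_lo, star_hi = c - (m + L - 1), c - m  # inclusive star interval
        if star_lo < 0 or star_hi >= len(seq):
            continue
        if star_lo > m + L - 1:  # star downstream -> mature on 5' arm
            arm, loop = "5p", star_lo - (m + L - 1) - 1
        elif star_hi < m:  # star upstream -> mature on 3' arm
            arm, loop = "3p", m - star_hi - 1
        else:
            continue  # arms overlap: not a hairpin
        paired = sum(1 for i in range(m, m + L) if _pairs(seq[i], seq[c - i]))
        if best is None or paired > best[0]:
            energy, stem_pairs = _stem_energy(seq, c, pair_energies)
            best = (paired, c, arm, loop, energy, stem_pairs, star_lo, star_hi)
    if best is None:
        return cand
    paired, c, arm, loop, energy, stem_pairs, star_lo, star_hi = best
    cand.arm = arm
    cand.star = revcomp(seq[star_lo : star_hi + 1])
    cand.stem_pairs = stem_pairs
    cand.energy = energy
    cand.loop_length = loop
    if paired < min_paired:
        cand.status = "rejected(insufficient_stem)"
    elif loop < min_loop:
        cand.status = "rejected(loop_too_short)"
    elif energy > max_energy:
        cand.status = "rejected(energy_above_threshold)"
    else:
        cand.status = "accepted"
    return cand


def screen_tags(
    tags: Mapping[str, SmallRNATag],
    unannotated: Iterable[str],
    genome: str,
    window: int = DEFAULT_WINDOW,
    **screen_kwargs,
) -> list[HairpinCandidate]:
    """Screen every mapping position of every unannotated tag (multi-locus
    tags yield one candidate per locus)."""
    unannotated = sorted(set(unannotated))
    index = GenomeIndex(genome, {len(t) for t in unannotated})
    candidates = []
    for seq in unannotated:
        for strand, start in index.find(seq):
            hit = MappingHit(tag=seq, strand=strand, start=start)
            flank = extract_flank(genome, hit, window)
            cand = hairpin_screen(flank, seq, **screen_kwargs)
            cand.total_count = tags[seq].total if seq in tags else 0
            candidates.append(cand)
    return candidates


def name_candidates(
    candidates: Iterable[HairpinCandidate],
    tissue: str,
    report_min_count: int = REPORT_MIN_COUNT,
) -> list[HairpinCandidate]:
    """Name accepted candidates ``<tissue>_miRNA%04d_<arm>`` by descending
    summed count then sequence; returns the reported subset (counts strictly
    above ``report_min_count``).  All accepted candidates get a name."""
    accepted = sorted(
        (c for c in candidates if c.accepted),
        key=lambda c: (-c.total_count, c.tag),
    )
    numbered: dict[str, int] = {}
    for c in accepted:
        if c.tag not in numbered:
            numbered[c.tag] = len(numbered) + 1
        c.name = f"{tissue}_miRNA{numbered[c.tag]:04d}_{c.arm}"
    return [c for c in accepted if c.total_count > report_min_count]


def candidates_table(candidates: Iterable[HairpinCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": c.name,
                "tag": c.tag,
                "arm": c.arm,
                "status": c.status,
                "stem_pairs": c.stem_pairs,
                "energy": c.energy,
                "loop": c.loop_length,
                "total_count": c.total_count,
                "strand": c.window.strand,
                "window_start": c.window.chrom_start + 1,
            }
            for c in candidates
        ]
    )
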
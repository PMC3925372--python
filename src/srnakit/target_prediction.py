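"""Plant miRNA target prediction over ungapped duplexes.

A candidate site is an ungapped antiparallel duplex between a miRNA (5'->3')
and a window of transcript sequence of the same length.  Position i counted
from the miRNA 5' end pairs with position L-i+1 of the site.  Each position
is scored match (Watson-Crick), GU (G:U wobble) or mismatch, and the duplex
is accepted only if all six of the classical plant-miRNA rules hold
(Allen et al. 2005 / Schwab et al. 2005 lineage):

    1. at most 4 mismatches overall (GU wobbles do not count);
    2. no adjacent mismatches within positions 2-12;
    3. no run of three or more consecutive mismatches anywhere;
    4. no mismatch at positions 10-11 (the cleavage site);
    5. weighted 5'-region score over positions 1-12 (mismatch = 1,
       GU = 0.5) at most 2.5;
    6. duplex energy at least 75% of the energy of the same miRNA paired
       to its perfect complement.

The energy function is a per-pair stand-in (GC -3, AU -2, GU -1,
mismatch 0) rather than a nearest-neighbour thermodynamic model; rule 6
is a ratio, which limits sensitivity to the absolute energy scale.  It is
pluggable via the ``pair_energies`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .annotation import revcomp

#: Watson-Crick pairs over the DNA alphabet (T stands in for U)
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}

PAIR_ENERGIES = {"GC": -3.0, "AU": -2.0, "GU": -1.0, "mismatch": 0.0}

MAX_MISMATCHES = 4
FIVE_PRIME_CAP = 2.5
ENERGY_RATIO_MIN = 0.75


def pair_state(mirna_base: str, site_base: str) -> str:
    """State of one duplex position: the miRNA base against the site base
    it faces (site read antiparallel)."""
    pair = (mirna_base, site_base)
    if pair in _WC:
        return "match"
    if pair in _GU:
        return "GU"
    return "mismatch"


@dataclass
class DuplexAlignment:
    """Ungapped miRNA:site duplex with per-position states.

    ``states[i]`` is the state at miRNA position i+1 (1-based from the
    miRNA 5' end).  ``five_prime_score`` weighs positions 1-12 with
    mismatch = 1 and GU = 0.5.
    """

    mirna: str
    site: str
    states: tuple[str, ...]
    total_mismatches: int
    gu_positions: tuple[int, ...]
    five_prime_score: float
    duplex_energy: float
    perfect_energy: float

    @property
    def energy_ratio(self) -> float:
        return self.duplex_energy / self.perfect_energy


def _perfect_energy(mirna: str, energies: Mapping[str, float]) -> float:
    return sum(
        energies["GC"] if b in "GC" else energies["AU"] for b in mirna
    )


def align_duplex(
    mirna: str,
    site: str,
    pair_energies: Mapping[str, float] = PAIR_ENERGIES,
) -> DuplexAlignment:
    """Score the ungapped antiparallel duplex of a miRNA against a
    same-length target site (both given 5'->3')."""
    mirna = mirna.upper().replace("U", "T")
    site = site.upper().replace("U", "T")
    if len(mirna) != len(site):
        raise ValueError("site length must equal miRNA length (ungapped duplex)")
    L = len(mirna)
    states = tuple(pair_state(mirna[i], site[L - 1 - i]) for i in range(L))
    mismatches = sum(s == "mismatch" for s in states)
    gu = tuple(i + 1 for i, s in enumerate(states) if s == "GU")
    five_prime = sum(
        1.0 if s == "mismatch" else 0.5 if s == "GU" else 0.0
        for s in states[:12]
    )
    energy = sum(
        pair_energies["mismatch"]
        if s == "mismatch"
        else pair_energies["GU"]
        if s == "GU"
        else pair_energies["GC"]
        if mirna[i] in "GC"
        else pair_energies["AU"]
        for i, s in enumerate(states)
    )
    return DuplexAlignment(
        mirna=mirna,
        site=site,
        states=states,
        total_mismatches=mismatches,
        gu_positions=gu,
        five_prime_score=five_prime,
        duplex_energy=energy,
        perfect_energy=_perfect_energy(mirna, pair_energies),
    )


def _max_mismatch_run(states: Iterable[str]) -> int:
    best = run = 0
    for s in states:
        run = run + 1 if s == "mismatch" else 0
        best = max(best, run)
    return best


def passes_criteria(aln: DuplexAlignment) -> tuple[bool, list[int]]:
    """Evaluate all six rules; returns (passed, violated rule ids)."""
    violated = []
    if aln.total_mismatches > MAX_MISMATCHES:
        violated.append(1)
    window = aln.states[1:12]  # positions 2..12
    if any(a == b == "mismatch" for a, b in zip(window, window[1:])):
        violated.append(2)
    if _max_mismatch_run(aln.states) >= 3:
        violated.append(3)
    if "mismatch" in aln.states[9:11]:  # positions 10-11
        violated.append(4)
    if aln.five_prime_score > FIVE_PRIME_CAP:
        violated.append(5)
    if aln.energy_ratio < ENERGY_RATIO_MIN:
        violated.append(6)
    return (not violated, violated)


@dataclass(frozen=True)
class TargetSite:
    """A transcript window whose duplex with the miRNA passes all rules.
    Coordinates are 1-based inclusive on the transcript."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    alignment: DuplexAlignment


def scan_targets(
    mirna: str,
    transcriptome: Mapping[str, str],
    mirna_id: str = "miRNA",
    pair_energies: Mapping[str, float] = PAIR_ENERGIES,
) -> list[TargetSite]:
    """Slide the miRNA over every same-length window of every transcript and
    keep the windows passing all six rules.

    The miRNA binds the transcript antiparallel, so the aligned site is the
    transcript window itself read 5'->3'.
    """
    L = len(mirna)
    out: list[TargetSite] = []
    for tid in sorted(transcriptome):
        seq = transcriptome[tid].upper().replace("U", "T")
        for i in range(len(seq) - L + 1):
            aln = align_duplex(mirna, seq[i : i + L], pair_energies)
            ok, _ = passes_criteria(aln)
            if ok:
                out.append(
                    TargetSite(
                        mirna_id=mirna_id,
                        transcript_id=tid,
                        start=i + 1,
                        end=i + L,
                        alignment=aln,
                    )
                )
    return out


def perfect_site(mirna: str) -> str:
    """The transcript site a fully complementary duplex would occupy."""
    return revcomp(mirna.upper().replace("U", "T"))


def sites_table(sites: Iterable[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "mismatches": s.alignment.total_mismatches,
                "gu": len(s.alignment.gu_positions),
                "five_prime_score": s.alignment.five_prime_score,
                "energy_ratio": s.alignment.energy_ratio,
            }
            for s in sites
        ]
    )
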
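"""Six-rule miRNA/target duplex filter."""

import numpy as np
import pytest

from srnakit import target_prediction as tp
from srnakit.annotation import revcomp


def mutate_site(mirna: str, positions: dict[int, str]) -> str:
    """Build a target site that is the perfect complement of the miRNA
    except at the given 1-based miRNA positions, where the site base facing
    that position is replaced."""
    L = len(mirna)
    site = list(revcomp(mirna))
    for pos, base in positions.items():
        site[L - pos] = base
    return "".join(site)


def non_pairing_base(mirna_base: str) -> str:
    """A site base that neither pairs Watson-Crick nor wobbles with the
    given miRNA base."""
    for b in "ACGT":
        if tp.pair_state(mirna_base, b) == "mismatch":
            return b
    raise AssertionError


MIRNA = "TGATTGAGCCGCGCCAATATC"  # arbitrary 21-mer, mixed composition


class TestAlignDuplex:
    def test_perfect_complement_all_match(self):
        aln = tp.align_duplex(MIRNA, revcomp(MIRNA))
        assert set(aln.states) == {"match"}
        assert aln.total_mismatches == 0 and aln.gu_positions == ()
        assert aln.five_prime_score == 0.0
        assert aln.energy_ratio == pytest.approx(1.0)

    def test_single_gu_at_position_3(self):
        # miRNA position 3 is A in MIRNA; use a miRNA with G at position 3
        mirna = "TGGTTGAGCCGCGCCAATATC"
        site = mutate_site(mirna, {3: "T"})  # G:T wobble
        aln = tp.align_duplex(mirna, site)
        assert aln.gu_positions == (3,)
        assert aln.total_mismatches == 0
        assert aln.five_prime_score == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tp.align_duplex(MIRNA, "ACGT")

    def test_agreement_with_per_position_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            mirna = "".join(rng.choice(list("ACGT"), size=21))
            site = "".join(rng.choice(list("ACGT"), size=21))
            aln = tp.align_duplex(mirna, site)
            L = len(mirna)
            for i in range(L):
                a, b = mirna[i], site[L - 1 - i]
                pair = a + b
                if pair in ("AT", "TA", "GC", "CG"):
                    expected = "match"
                elif pair in ("GT", "TG"):
                    expected = "GU"
                else:
                    expected = "mismatch"
                assert aln.states[i] == expected

    def test_rna_input_accepted(self):
        aln = tp.align_duplex("UGAUUGAGCCGCGCCAAUAUC", revcomp(MIRNA))
        assert set(aln.states) == {"match"}


class TestDuplexEnergy:
    def test_all_gc_perfect_duplex(self):
        mirna = "GC" * 10 + "G"
        aln = tp.align_duplex(mirna, revcomp(mirna))
        assert aln.duplex_energy == -63.0
        assert aln.perfect_energy == -63.0

    def test_hand_computed_four_mismatch_duplex(self):
        # perfect energy of MIRNA: 11 GC (-3) + 10 AU (-2) = -53
        site = mutate_site(
            MIRNA,
            {p: non_pairing_base(MIRNA[p - 1]) for p in (1, 5, 15, 21)},
        )
        aln = tp.align_duplex(MIRNA, site)
        assert aln.perfect_energy == -53.0
        lost = sum(3.0 if MIRNA[p - 1] in "GC" else 2.0 for p in (1, 5, 15, 21))
        assert aln.duplex_energy == pytest.approx(-53.0 + lost)

    def test_mismatches_never_lower_energy(self):
        site = mutate_site(MIRNA, {7: non_pairing_base(MIRNA[6])})
        aln = tp.align_duplex(MIRNA, site)
        assert aln.duplex_energy >= aln.perfect_energy


class TestCriteria:
    def test_perfect_duplex_passes_all(self):
        aln = tp.align_duplex(MIRNA, revcomp(MIRNA))
        ok, violated = tp.passes_criteria(aln)
        assert ok and violated == []

    def test_position_10_mismatch_fails_rule_4(self):
        site = mutate_site(MIRNA, {10: non_pairing_base(MIRNA[9])})
        ok, violated = tp.passes_criteria(tp.align_duplex(MIRNA, site))
        assert not ok and 4 in violated

    def test_five_scattered_mismatches_fail_rule_1(self):
        positions = {p: non_pairing_base(MIRNA[p - 1]) for p in (13, 15, 17, 19, 21)}
        ok, violated = tp.passes_criteria(tp.align_duplex(MIRNA, mutate_site(MIRNA, positions)))
        assert not ok and 1 in violated

    def test_adjacent_mismatches_in_seed_fail_rule_2(self):
        positions = {p: non_pairing_base(MIRNA[p - 1]) for p in (5, 6)}
        ok, violated = tp.passes_criteria(tp.align_duplex(MIRNA, mutate_site(MIRNA, positions)))
        assert 2 in violated

    def test_run_of_three_fails_rule_3(self):
        positions = {p: non_pairing_base(MIRNA[p - 1]) for p in (15, 16, 17)}
        ok, violated = tp.passes_criteria(tp.align_duplex(MIRNA, mutate_site(MIRNA, positions)))
        assert 3 in violated

    def test_gu_wobbles_count_half_toward_rule_5(self):
        # six G:U wobbles in positions 1-12 = 3.0 > 2.5, with zero mismatches
        mirna = "G" * 21
        site = list(revcomp(mirna))  # all C
        for pos in (1, 2, 3, 4, 5, 6):
            site[21 - pos] = "T"
        aln = tp.align_duplex(mirna, "".join(site))
        assert aln.total_mismatches == 0
        assert aln.five_prime_score == 3.0
        ok, violated = tp.passes_criteria(aln)
        assert 5 in violated
        # five wobbles = 2.5 sits exactly on the cap and passes
        site[21 - 6] = "C"
        aln = tp.align_duplex(mirna, "".join(site))
        assert aln.five_prime_score == 2.5
        assert tp.passes_criteria(aln)[0]

    def test_rule_4_failure_is_independent_of_energy(self):
        site = mutate_site(MIRNA, {10: non_pairing_base(MIRNA[9])})
        aln = tp.align_duplex(MIRNA, site)
        assert aln.energy_ratio >= 0.75  # energy fine, rule 4 still fails
        assert not tp.passes_criteria(aln)[0]


class TestScanTargets:
    def test_embedded_perfect_site_found(self):
        transcript = "A" * 50 + revcomp(MIRNA) + "C" * 50
        sites = tp.scan_targets(MIRNA, {"t1": transcript})
        exact = [s for s in sites if s.alignment.total_mismatches == 0]
        assert len(exact) == 1
        assert (exact[0].start, exact[0].end) == (51, 71)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        transcriptome = {
            f"t{i}": "".join(rng.choice(list("ACGT"), size=2000)) for i in range(5)
        }
        transcriptome["t_pos"] = "AC" * 40 + revcomp(MIRNA) + "GT" * 40
        found = {
            (s.transcript_id, s.start) for s in tp.scan_targets(MIRNA, transcriptome)
        }
        brute = set()
        for tid, seq in transcriptome.items():
            for i in range(len(seq) - 21 + 1):
                if tp.passes_criteria(tp.align_duplex(MIRNA, seq[i : i + 21]))[0]:
                    brute.add((tid, i + 1))
        assert found == brute

    def test_planted_tasirna_sites_recovered(self, reference):
        for locus in reference.tas_loci:
            tasi = locus.cdna[
                locus.cleavage_position - 1 : locus.cleavage_position + 20
            ]
            sites = tp.scan_targets(tasi, reference.transcriptome)
            assert any(
                s.alignment.total_mismatches == 0 for s in sites
            ), f"planted site of {locus.locus_id} missed"
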
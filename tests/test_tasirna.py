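"""Phase-register analysis and the initiator-miRNA network."""

import numpy as np
import pytest
from scipy.stats import chisquare

from srnakit import tasirna as ts
from srnakit.read_processing import SmallRNATag


def make_locus(seed: int = 7, n_phases: int = 8, prefix_len: int = 60) -> ts.TasLocus:
    rng = np.random.default_rng(seed)
    cdna = "".join(rng.choice(list("ACGT"), size=prefix_len + 21 * n_phases + 40))
    return ts.TasLocus("TASx", cdna, prefix_len + 1)


def phased_tag(locus: ts.TasLocus, k: int) -> str:
    start = locus.cleavage_position - 1 + 21 * k
    return locus.cdna[start : start + 21]


class TestMap21:
    def test_planted_read_recovered(self):
        locus = make_locus()
        seq = phased_tag(locus, 2)
        tags = {seq: SmallRNATag(seq, {"L": 9})}
        mapped = ts.map_21nt(tags, [locus], "L")
        assert mapped["TASx"] == {locus.cleavage_position + 42: {seq: 9}}

    def test_22nt_tag_excluded(self):
        locus = make_locus()
        seq = locus.cdna[10:32]  # 22-nt exact substring
        tags = {seq: SmallRNATag(seq, {"L": 5})}
        assert ts.map_21nt(tags, [locus], "L")["TASx"] == {}

    def test_antisense_tag_excluded(self):
        from srnakit.annotation import revcomp

        locus = make_locus()
        seq = revcomp(phased_tag(locus, 1))
        tags = {seq: SmallRNATag(seq, {"L": 5})}
        assert ts.map_21nt(tags, [locus], "L")["TASx"] == {}

    def test_equivalence_with_naive_scan(self):
        locus = make_locus(seed=13)
        probes = [phased_tag(locus, 0), locus.cdna[5:26], "A" * 21]
        tags = {s: SmallRNATag(s, {"L": 1}) for s in probes}
        mapped = ts.map_21nt(tags, [locus], "L")["TASx"]
        brute: dict[int, set[str]] = {}
        for s in probes:
            for i in range(len(locus.cdna) - 20):
                if locus.cdna[i : i + 21] == s:
                    brute.setdefault(i + 1, set()).add(s)
        assert {pos: set(d) for pos, d in mapped.items()} == brute


class TestPhaseRegisters:
    def test_multiples_of_21_in_register_zero(self):
        locus = make_locus()
        c = locus.cleavage_position
        profile = ts.phase_registers({c: 3, c + 21: 2, c + 42: 5}, locus)
        assert profile.bins[0] == 10 and profile.bins[1:].sum() == 0
        assert profile.total == 10

    def test_register_invariant_to_21_shift(self):
        locus = make_locus()
        pos = {locus.cleavage_position + 4: 7, locus.cleavage_position + 9: 2}
        shifted = {p + 21: n for p, n in pos.items()}
        a = ts.phase_registers(pos, locus)
        b = ts.phase_registers(shifted, locus)
        assert (a.bins == b.bins).all()

    def test_bins_conserve_mapped_total(self):
        locus = make_locus()
        rng = np.random.default_rng(5)
        pos = {int(p): int(n) for p, n in zip(rng.integers(1, 200, 50), rng.integers(1, 9, 50))}
        profile = ts.phase_registers(pos, locus)
        assert profile.bins.sum() == profile.total == sum(pos.values())

    def test_uniform_positions_give_flat_profile(self):
        locus = make_locus(prefix_len=84)
        rng = np.random.default_rng(99)
        positions = {}
        for p in rng.integers(1, len(locus.cdna) - 20, size=1000):
            positions[int(p)] = positions.get(int(p), 0) + 1
        profile = ts.phase_registers(positions, locus)
        assert chisquare(profile.bins).pvalue > 0.01
        assert profile.bins.max() <= 2 * 1000 / 21


class TestTasirnaDE:
    def test_read_filter_is_strict(self):
        locus = make_locus()
        seq = phased_tag(locus, 0)
        tags = {seq: SmallRNATag(seq, {"ctl": 10, "trt": 10})}
        de = ts.tasirna_de(tags, [locus], "ctl", "trt", 1000, 1000)
        assert len(de) == 0

    def test_spiked_sequence_called_up(self):
        locus = make_locus()
        seq = phased_tag(locus, 3)
        tags = {seq: SmallRNATag(seq, {"ctl": 50, "trt": 200})}
        de = ts.tasirna_de(tags, [locus], "ctl", "trt", 10_000, 10_000)
        assert list(de["call"]) == ["up"]
        assert de.loc[0, "loci"] == "TASx"

    def test_call_agrees_with_statistic_module(self):
        from srnakit import abundance_stats as ab

        locus = make_locus()
        seq = phased_tag(locus, 1)
        tags = {seq: SmallRNATag(seq, {"ctl": 37, "trt": 18})}
        de = ts.tasirna_de(tags, [locus], "ctl", "trt", 5000, 6000)
        ref = ab.classify_de(37, 18, 5000, 6000)
        assert de.loc[0, "call"] == ref.call
        assert de.loc[0, "p"] == pytest.approx(ref.p_two_tailed)


class TestNetwork:
    def _de_frame(self, seq, loci_str, call="up"):
        import pandas as pd

        return pd.DataFrame(
            [{"id": seq, "x": 10, "y": 80, "call": call, "loci": loci_str}]
        )

    def test_edges_backed_by_evidence(self):
        from srnakit.annotation import revcomp

        locus_a = make_locus(seed=31)
        seq = phased_tag(locus_a, 0)
        # second locus sharing the same sRNA sequence
        cdna_b = locus_a.cdna[:60] + seq + locus_a.cdna[60 + 21 :]
        locus_b = ts.TasLocus("TASy", cdna_b, 61)
        transcriptome = {"PPR_x": "C" * 40 + revcomp(seq) + "G" * 40}
        tags = {seq: SmallRNATag(seq, {"ctl": 10, "trt": 80})}
        g = ts.build_network(
            self._de_frame(seq, "TASx,TASy"),
            tags,
            [locus_a, locus_b],
            "TTTTTTTTTTGGGGGGGGGGG",
            "miR173",
            transcriptome,
            {"PPR_x": "PPR"},
        )
        edge_types = sorted(d["edge_type"] for _, _, d in g.edges(data=True))
        # 3 initiates (MIR gene + 2 loci) + 2 generated_from + >=1 targets
        assert edge_types.count("initiates") == 3
        assert edge_types.count("generated_from") == 2
        assert edge_types.count("targets") >= 1
        assert g.nodes[seq]["call"] == "up"
        assert g.nodes["PPR_x"]["node_type"] == "PPR_target"

    def test_no_passing_duplex_no_targets_edges(self):
        locus = make_locus(seed=37)
        seq = phased_tag(locus, 0)
        tags = {seq: SmallRNATag(seq, {"ctl": 10, "trt": 80})}
        g = ts.build_network(
            self._de_frame(seq, "TASx"),
            tags,
            [locus],
            "TTTTTTTTTTGGGGGGGGGGG",
            "miR173",
            {"t1": "A" * 120},
        )
        assert not any(d["edge_type"] == "targets" for _, _, d in g.edges(data=True))

    def test_missing_transcriptome_rejected(self):
        locus = make_locus()
        with pytest.raises(ValueError):
            ts.build_network(
                self._de_frame("A" * 21, "TASx"), {}, [locus], "A" * 21, "m", {}
            )

    def test_sif_round_trip(self, tmp_path):
        locus = make_locus(seed=41)
        seq = phased_tag(locus, 0)
        tags = {seq: SmallRNATag(seq, {"ctl": 10, "trt": 80})}
        g = ts.build_network(
            self._de_frame(seq, "TASx"), tags, [locus],
            "TTTTTTTTTTGGGGGGGGGGG", "miR173", {"t1": "A" * 120},
        )
        sif = tmp_path / "net.sif"
        ts.write_sif(g, sif)
        lines = [l.split("\t") for l in sif.read_text().splitlines()]
        assert len(lines) == g.number_of_edges()
        for u, rel, v in lines:
            assert g.has_edge(u, v)
        ts.write_graphml(g, tmp_path / "net.graphml")
        import networkx as nx

        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_edges() == g.number_of_edges()
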
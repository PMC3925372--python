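"""Reference construction and library simulation invariants."""

import numpy as np
import pytest
from scipy.stats import binomtest

from srnakit import synthetic_data as sd
from srnakit.annotation import revcomp
from srnakit.read_processing import SRNALibrary, clean_and_collapse, length_distribution, trim_adapter


class TestBuildReference:
    def test_deterministic_for_fixed_seed(self, sim_config):
        a = sd.build_reference(sim_config, seed=123)
        b = sd.build_reference(sim_config, seed=123)
        assert a.genome == b.genome
        assert a.features == b.features
        assert [r.precursor for r in a.mirnas] == [r.precursor for r in b.mirnas]

    def test_different_seeds_differ(self, sim_config):
        assert sd.build_reference(sim_config, 1).genome != sd.build_reference(sim_config, 2).genome

    def test_mature_within_precursor_and_genome(self, reference):
        for rec in reference.mirnas + reference.novel_mirnas:
            assert rec.mature in rec.precursor
            assert rec.precursor in reference.genome
            assert rec.star == revcomp(rec.mature)

    def test_tas_loci_locatable_with_cleavage_inside(self, sim_config, reference):
        assert len(reference.tas_loci) == sim_config.n_tas
        for locus in reference.tas_loci:
            assert locus.cdna in reference.genome
            assert 1 <= locus.cleavage_position <= len(locus.cdna)
            start = reference.tas_offsets[locus.locus_id]
            assert reference.genome[start : start + len(locus.cdna)] == locus.cdna

    def test_cis_ol_contained_in_both_wl(self, reference):
        cis = [p for p in reference.nat_pairs if p.pair_type == "cis"]
        assert cis
        for pair in cis:
            assert pair.wl_a.contains(pair.ol.start, pair.ol.end)
            assert pair.wl_b.contains(pair.ol.start, pair.ol.end)
            assert pair.wl_a.strand != pair.wl_b.strand

    def test_adapter_seed_absent_from_genome(self, sim_config, reference):
        seed8 = sim_config.adapter3[:8]
        assert seed8 not in reference.genome
        assert revcomp(seed8) not in reference.genome

    def test_contradictory_config_rejected(self):
        cfg = sd.default_config()
        cfg.loop_length = 8
        with pytest.raises(ValueError):
            sd.build_reference(cfg, 1)

    def test_bad_weights_rejected(self):
        cfg = sd.default_config()
        cfg.class_weights["mirna"] = 0.5
        with pytest.raises(ValueError):
            cfg.validate()


class TestSimulateLibrary:
    def test_deterministic_for_fixed_seed(self, reference, sim_config):
        a, ta = sd.simulate_library(reference, sim_config, "leaf_WT", seed=9)
        b, tb = sd.simulate_library(reference, sim_config, "leaf_WT", seed=9)
        assert a == b
        assert ta.equals(tb)

    def test_unknown_condition_rejected(self, reference, sim_config):
        with pytest.raises(ValueError):
            sd.simulate_library(reference, sim_config, "stem_WT", seed=1)

    def test_truth_table_conserves_reads(self, reference, sim_config):
        reads, truth = sd.simulate_library(reference, sim_config, "leaf_WT", seed=2)
        assert len(reads) == len(truth)
        assert truth.groupby("source_id").size().sum() == len(reads)

    def test_noise_free_inserts_are_reference_substrings(self, reference, sim_config):
        reads, truth = sd.simulate_library(reference, sim_config, "leaf_WT", seed=3)
        adapter = sim_config.adapter3
        with_adapter = truth[truth["has_adapter"] == 1]
        read_by_id = dict(reads)
        for read_id in with_adapter["read_id"].sample(200, random_state=0):
            insert = read_by_id[read_id][: -len(adapter)]
            assert insert in reference.genome or revcomp(insert) in reference.genome

    def test_reads_carry_full_adapter(self, reference, sim_config):
        reads, truth = sd.simulate_library(reference, sim_config, "leaf_WT", seed=4)
        read_by_id = dict(reads)
        for _, row in truth.head(300).iterrows():
            seq = read_by_id[row["read_id"]]
            if row["has_adapter"]:
                assert seq.endswith(sim_config.adapter3)
            else:
                assert sim_config.adapter3[:8] not in seq

    def test_discarded_fraction_equals_decoy_fraction(self, reference, sim_config):
        reads, truth = sd.simulate_library(reference, sim_config, "leaf_WT", seed=8)
        discarded = sum(
            1 for _, seq in reads if trim_adapter(seq, sim_config.adapter3) is None
        )
        assert discarded == int((truth["has_adapter"] == 0).sum())

    def test_spike_ratio_within_binomial_error_of_4(self, reference, sim_config):
        _, wt = sd.simulate_library(reference, sim_config, "leaf_WT", seed=21)
        _, oe = sd.simulate_library(reference, sim_config, "leaf_OE7", seed=22)
        for mirna in ("miR158", "miR172"):  # 4x multipliers in OE leaf
            x = int((wt["source_id"] == mirna).sum())
            y = int((oe["source_id"] == mirna).sum())
            # under a 4x spike, y | (x+y) ~ Binomial(x+y, 4/5)
            assert binomtest(y, x + y, 4 / 5).pvalue > 1e-3

    def test_phasing_fidelity_one_places_all_reads_in_register(self, reference, sim_config):
        import dataclasses

        cfg = dataclasses.replace(sim_config, phasing_fidelity=1.0)
        reads, truth = sd.simulate_library(reference, cfg, "leaf_WT", seed=30)
        tas = truth[truth["source_class"] == "tasirna"]
        assert len(tas) > 100
        assert (tas["in_register"] == "1").all()
        read_by_id = dict(reads)
        loci = {t.locus_id: t for t in reference.tas_loci}
        for _, row in tas.head(100).iterrows():
            insert = read_by_id[row["read_id"]][: -len(cfg.adapter3)]
            locus = loci[row["source_id"]]
            pos = locus.cdna.find(insert)
            assert pos >= 0
            assert (pos + 1 - locus.cleavage_position) % 21 == 0

    def test_noise_rate_mutates_inserts(self, reference, sim_config):
        import dataclasses

        cfg = dataclasses.replace(sim_config, noise_rate=0.5, reads_per_library=2000)
        reads, truth = sd.simulate_library(reference, cfg, "leaf_WT", seed=31)
        read_by_id = dict(reads)
        mirna_rows = truth[truth["source_class"] == "mirna"]
        matures = {r.mirna_id: r.mature for r in reference.mirnas}
        mutated = sum(
            read_by_id[row["read_id"]][: -len(cfg.adapter3)] != matures[row["source_id"]]
            for _, row in mirna_rows.iterrows()
        )
        assert 0.3 < mutated / len(mirna_rows) < 0.7


class TestLengthStructure:
    def _hist(self, reference, sim_config, condition, seed):
        reads, _ = sd.simulate_library(reference, sim_config, condition, seed=seed)
        lib = SRNALibrary(condition)
        inserts = [
            t for _, r in reads if (t := trim_adapter(r, sim_config.adapter3)) is not None
        ]
        tags = clean_and_collapse(inserts, lib)
        return length_distribution(tags)

    def test_leaf_modes_at_21_and_24(self, reference, sim_config):
        hist = self._hist(reference, sim_config, "leaf_WT", seed=40)
        top2 = set(hist["total"].nlargest(2).index)
        assert top2 == {21, 24}

    def test_root_has_additional_19nt_peak(self, reference, sim_config):
        hist = self._hist(reference, sim_config, "root_WT", seed=41)
        assert hist.loc[19, "total"] > hist.loc[18, "total"]
        assert hist.loc[19, "total"] > hist.loc[20, "total"]
        leaf = self._hist(reference, sim_config, "leaf_WT", seed=41)
        assert (
            hist.loc[19, "total"] / hist["total"].sum()
            > 3 * leaf.loc[19, "total"] / leaf["total"].sum()
        )


def test_write_reference_bundle(tmp_path, reference):
    sd.write_reference(reference, tmp_path)
    expected = [
        "genome.fa",
        "features.gff3",
        "mirna_precursors.fa",
        "mirna_mature.fa",
        "tas_cdna.fa",
        "tas_cleavage.tsv",
        "nat_pairs.tsv",
        "transcriptome.fa",
        "transcript_families.tsv",
    ]
    for name in expected:
        assert (tmp_path / name).stat().st_size > 0
    from srnakit.io import read_fasta, read_gff3

    genome = read_fasta(tmp_path / "genome.fa")["minigenome"]
    assert genome == reference.genome
    assert read_gff3(tmp_path / "features.gff3") == reference.features
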
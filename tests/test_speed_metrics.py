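"""Speed profiles, the RIT statistic and genome-wide slowdown summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codonramp import speed_metrics as sm
from codonramp.genetic_code import SENSE_CODONS

from conftest import make_gene, make_rrt

GCT_REPEAT = make_gene("ATG" + "GCT" * 60 + "TAA")  # 62 sense codons


class TestSpeedProfile:
    def test_per_codon_values_stop_omitted(self):
        rrt = make_rrt(1.0, ATG=0.7, GCT=1.1)
        gene = make_gene("ATGGCTTAA")
        assert sm.speed_profile(gene, rrt).tolist() == [0.7, 1.1]

    def test_profile_length_is_codon_count_minus_one(self, rrt_table):
        for n in (2, 10, 50):
            gene = make_gene("ATG" + "GAA" * n + "TAA")
            assert len(sm.speed_profile(gene, rrt_table)) == gene.n_codons - 1

    def test_internal_stop_error_names_position(self, rrt_table):
        gene = make_gene("ATGGCTTAGGCTTAA")
        with pytest.raises(ValueError, match="position 3"):
            sm.speed_profile(gene, rrt_table)


class TestRit:
    def test_identical_codon_multisets_give_zero(self, rrt_table):
        # numerator (positions 2..5) and denominator (6..9) both = one GAA+CCT pair each
        gene = make_gene("ATG" + "GAACCT" * 2 + "GAACCT" * 2 + "TAA")
        record = sm.rit(gene, rrt_table, window=5)
        assert record.rit == pytest.approx(0.0, abs=1e-12)

    def test_known_means_arithmetic(self):
        # numerator mean 1.2 (positions 2..3), denominator mean 1.0
        rrt = make_rrt(1.0, GAA=1.2, GAT=1.2)
        gene = make_gene("ATG" + "GAAGAT" + "GCT" * 10 + "TAA")
        record = sm.rit(gene, rrt, window=3)
        assert record.rit == pytest.approx(np.log2(1.2), abs=1e-12)
        assert (record.n_numerator, record.n_denominator) == (2, 10)

    def test_window_indexing_five_prime(self, rrt_table):
        gene = GCT_REPEAT
        record = sm.rit(gene, rrt_table, window=40)
        # numerator = positions 2..40 -> 39 codons; denominator = 41..N-1
        assert record.n_numerator == 39
        assert record.n_denominator == gene.n_sense - 40

    def test_window_indexing_three_prime(self, rrt_table):
        gene = GCT_REPEAT
        record = sm.rit(gene, rrt_table, window=40, end="three_prime")
        # numerator = last 40 sense codons; denominator = positions 2..N-41
        assert record.n_numerator == 40
        assert record.n_denominator == gene.n_sense - 41

    def test_three_prime_means_match_manual_slices(self):
        rrt = make_rrt(1.0, TGC=2.0)
        # last 6 sense codons are TGC -> 3' window of 6 is all slow
        gene = make_gene("ATG" + "GCT" * 20 + "TGC" * 6 + "TAA")
        record = sm.rit(gene, rrt, window=6, end="three_prime")
        assert record.rit == pytest.approx(np.log2(2.0 / 1.0))

    def test_too_short_gene_rejected(self, rrt_table):
        gene = make_gene("ATG" + "GCT" * 40 + "TAA")  # 41 sense codons
        with pytest.raises(ValueError, match="window"):
            sm.rit(gene, rrt_table, window=40)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, scale):
        rrt = make_rrt(1.0, GAA=1.3, CCT=0.8)
        gene = make_gene("ATG" + "GAACCTGCT" * 8 + "TAA")
        base = sm.rit(gene, rrt, window=10).rit
        scaled = sm.rit(gene, rrt.scaled(scale), window=10).rit
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_swapping_window_and_body_negates_rit(self, rrt_table):
        head, tail = "GAATGCCCT", "GCTGGTAAA"
        # numerator and denominator codon multisets are exchanged when the
        # window and body regions hold each other's codons
        gene_ab = make_gene("ATG" + head + tail + "TAA")
        gene_ba = make_gene("ATG" + tail + head + "TAA")
        rit_ab = sm.rit(gene_ab, rrt_table, window=4).rit
        rit_ba = sm.rit(gene_ba, rrt_table, window=4).rit
        assert rit_ab == pytest.approx(-rit_ba, abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.208, "SIT"), (-0.166, "FIT"), (0.0, "FIT")],  # tie breaks to FIT
    )
    def test_classification(self, value, expected):
        record = sm.RITRecord("g", 40, value, 39, 100)
        assert sm.classify_rit(record) == expected

    def test_sit_fraction(self):
        records = [sm.RITRecord(f"g{i}", 40, v, 39, 100)
                   for i, v in enumerate([0.2, -0.1, 0.1, 0.3])]
        assert sm.sit_fraction(records) == 0.75


class TestNeutralize:
    def test_empty_set_is_identity(self, rrt_table):
        assert sm.neutralize(rrt_table, set()).entries == rrt_table.entries

    def test_neutralized_codons_get_neutral_value(self, rrt_table):
        out = sm.neutralize(rrt_table, {"ATG"})
        assert out.lookup("ATG") == rrt_table.neutral_value == 1.0189

    def test_exactly_listed_codons_change(self, rrt_table):
        codons = {"ATG", "ATT", "TTG", "ATA"}
        out = sm.neutralize(rrt_table, codons)
        changed = {c for c in SENSE_CODONS
                   if out.entries[c] != rrt_table.entries[c]}
        assert changed == codons

    def test_input_table_not_modified(self, rrt_table):
        before = dict(rrt_table.entries)
        sm.neutralize(rrt_table, {"ATG", "TGC"})
        assert rrt_table.entries == before

    def test_stop_codon_rejected(self, rrt_table):
        with pytest.raises(ValueError, match="TAA"):
            sm.neutralize(rrt_table, {"TAA"})

    def test_neutralizing_at_existing_value_is_identity_downstream(self):
        rrt = make_rrt(1.0, GCT=1.0189)
        gene = make_gene("ATG" + "GCTGAA" * 30 + "TAA")
        out = sm.neutralize(rrt, {"GCT"})
        assert sm.rit(gene, out, window=20).rit == sm.rit(gene, rrt, window=20).rit


class TestGenomewideSlowdown:
    def test_null_case_constant_genes(self, rrt_table):
        genes = [make_gene("ATG" + codon * 50 + "TAA", gene_id=codon)
                 for codon in ("GCT", "GAA", "CCT")]
        summary = sm.genomewide_slowdown(genes, rrt_table, window=10)
        assert summary.mean_ratio_pct == pytest.approx(0.0, abs=1e-12)
        assert summary.p_value == 1.0

    def test_slow_window_detected_with_direction(self):
        rrt = make_rrt(1.0, TGC=1.5)
        genes = [make_gene("ATG" + "TGC" * 10 + "GCT" * 40 + "TAA",
                           gene_id=f"g{i}") for i in range(12)]
        summary = sm.genomewide_slowdown(genes, rrt, window=11)
        # window mean 1.5, body mean 1.0 -> +50%
        assert summary.mean_ratio_pct == pytest.approx(50.0, abs=1e-9)
        assert summary.p_value < 0.01
        assert summary.n_genes == 12

    def test_speed_scale_close_but_distinct(self):
        rrt = make_rrt(1.0, TGC=1.5, GCT=0.9)
        genes = [make_gene("ATG" + "TGCGCT" * 30 + "GCT" * 30 + "TAA",
                           gene_id=f"g{i}") for i in range(5)]
        rrt_scale = sm.genomewide_slowdown(genes, rrt, window=20, scale="rrt")
        speed_scale = sm.genomewide_slowdown(genes, rrt, window=20, scale="speed")
        assert rrt_scale.mean_ratio_pct > 0 and speed_scale.mean_ratio_pct > 0
        assert rrt_scale.mean_ratio_pct != speed_scale.mean_ratio_pct

    def test_short_genes_skipped(self, rrt_table):
        long = [make_gene("ATG" + "GCT" * 60 + "TAA", gene_id=f"L{i}")
                for i in range(3)]
        short = [make_gene("ATG" + "GCT" * 20 + "TAA", gene_id="S")]
        summary = sm.genomewide_slowdown(long + short, rrt_table, window=40)
        assert summary.n_genes == 3


class TestMetaprofile:
    def test_uniform_table_gives_flat_profile(self, uniform_rrt):
        genes = [make_gene("ATG" + "GCT" * n + "TAA", gene_id=f"g{n}")
                 for n in (20, 30, 40)]
        profile = sm.metaprofile(genes, uniform_rrt, max_pos=25)
        assert all(v == pytest.approx(1.0) for _, v, _ in profile)

    def test_gene_count_non_increasing_with_position(self, rrt_table):
        genes = [make_gene("ATG" + "GCT" * n + "TAA", gene_id=f"g{n}")
                 for n in (10, 20, 30, 40)]
        profile = sm.metaprofile(genes, rrt_table, max_pos=35)
        ns = [n for _, _, n in profile]
        assert ns == sorted(ns, reverse=True)
        assert profile[0][0] == 2  # starts after the initiator

    def test_smooth_width_one_is_identity(self, rrt_table):
        genes = [make_gene("ATG" + "GCTTGCGAA" * 10 + "TAA")]
        raw = sm.metaprofile(genes, rrt_table, max_pos=20, smooth=1)
        again = sm.metaprofile(genes, rrt_table, max_pos=20)
        assert raw == again

    def test_smoothing_averages_neighbours(self, rrt_table):
        genes = [make_gene("ATG" + "GCTTGCGAA" * 10 + "TAA")]
        raw = sm.metaprofile(genes, rrt_table, max_pos=20, smooth=1)
        smoothed = sm.metaprofile(genes, rrt_table, max_pos=20, smooth=3)
        # interior point = mean of the three raw neighbours
        mid = 5
        expected = np.mean([raw[mid - 1][1], raw[mid][1], raw[mid + 1][1]])
        assert smoothed[mid][1] == pytest.approx(expected)

    def test_even_smooth_rejected(self, rrt_table):
        with pytest.raises(ValueError):
            sm.metaprofile([GCT_REPEAT], rrt_table, max_pos=10, smooth=2)


def test_writers_produce_readable_tsv(tmp_path, rrt_table):
    records = sm.rit_table([GCT_REPEAT], rrt_table, window=40)
    path = tmp_path / "rit.tsv"
    sm.write_rit_records(records, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("gene_id") and len(lines) == 2
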
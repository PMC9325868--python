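"""Summary-statistics loading, validation and the trans-distance filter."""

import numpy as np
import pytest
from scipy import stats

from archie.summary_io import (
    EmptyMatrixError,
    SummaryError,
    filter_trans,
    intersect_expressed,
    load_summary,
    write_summary,
)

from conftest import make_summary


class TestLoadSummary:
    def test_key_based_placement_independent_of_row_order(self, summary_files):
        sm = load_summary(
            summary_files["summary"], summary_files["variant_meta"], summary_files["gene_meta"]
        )
        assert sm.variant_ids == ["rs1", "rs2"]
        assert sm.gene_ids == ["gA", "gB"]
        assert sm.Z.tolist() == [[2.0, 0.0], [1.0, -1.0]]
        assert sm.P[0, 0] == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-4)

    @pytest.mark.parametrize(
        "policy,expected_shape,expected_ids",
        [
            ("drop_gene", (2, 1), (["s1", "s2"], ["gA"])),
            ("drop_variant", (1, 2), (["s1"], ["gA", "gB"])),
        ],
    )
    def test_missing_policies(self, tmp_path, policy, expected_shape, expected_ids):
        (tmp_path / "s.tsv").write_text(
            "SNP\tSNPChr\tSNPPos\tGene\tGeneChr\tGenePos\tZscore\n"
            "s1\t1\t1000000\tgA\t2\t1000000\t2.0\n"
            "s1\t1\t1000000\tgB\t2\t2000000\t0.0\n"
            "s2\t1\t2000000\tgA\t2\t1000000\t-1.0\n"
        )
        (tmp_path / "v.tsv").write_text(
            "variant_id\tchromosome\tposition\tmaf\ttrait_label\n"
            "s1\t1\t1000000\t0.2\tt\ns2\t1\t2000000\t0.3\tt\n"
        )
        (tmp_path / "g.tsv").write_text("gene_id\tchromosome\ttss\ngA\t2\t1000000\ngB\t2\t2000000\n")
        sm = load_summary(tmp_path / "s.tsv", tmp_path / "v.tsv", tmp_path / "g.tsv", missing_policy=policy)
        assert sm.shape == expected_shape
        assert (sm.variant_ids, sm.gene_ids) == expected_ids

        with pytest.raises(SummaryError, match="missing_policy"):
            load_summary(tmp_path / "s.tsv", tmp_path / "v.tsv", tmp_path / "g.tsv", missing_policy="error")

    def test_duplicate_pair_reports_line(self, summary_files, tmp_path):
        text = summary_files["summary"].read_text()
        dup = tmp_path / "dup.tsv"
        dup.write_text(text + "rs1\t1\t1000000\tgA\t2\t8000000\t5.0\t0.1\n")
        with pytest.raises(SummaryError, match=r"duplicated.*line 6"):
            load_summary(dup, summary_files["variant_meta"], summary_files["gene_meta"])

    def test_unparseable_z_reports_line(self, summary_files, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "SNP\tSNPChr\tSNPPos\tGene\tGeneChr\tGenePos\tZscore\n"
            "rs1\t1\t1000000\tgA\t2\t8000000\tnot_a_number\n"
        )
        with pytest.raises(SummaryError, match="line 2"):
            load_summary(bad, summary_files["variant_meta"], summary_files["gene_meta"])

    def test_zp_consistency_warns_and_strict_raises(self, summary_files, tmp_path):
        # Z=1.96 goes with p=0.0500; a discordant p triggers the check
        bad = tmp_path / "zp.tsv"
        bad.write_text(
            "SNP\tSNPChr\tSNPPos\tGene\tGeneChr\tGenePos\tZscore\tPvalue\n"
            "rs1\t1\t1000000\tgA\t2\t8000000\t1.96\t0.5\n"
        )
        with pytest.warns(UserWarning, match="deviate"):
            load_summary(bad, summary_files["variant_meta"], summary_files["gene_meta"])
        with pytest.raises(SummaryError, match="deviate"):
            load_summary(bad, summary_files["variant_meta"], summary_files["gene_meta"], strict_zp=True)
        ok = tmp_path / "ok.tsv"
        ok.write_text(
            "SNP\tSNPChr\tSNPPos\tGene\tGeneChr\tGenePos\tZscore\tPvalue\n"
            "rs1\t1\t1000000\tgA\t2\t8000000\t1.96\t0.0500\n"
        )
        load_summary(ok, summary_files["variant_meta"], summary_files["gene_meta"], strict_zp=True)

    def test_round_trip_is_bit_exact(self, summary_files, tmp_path):
        sm = load_summary(
            summary_files["summary"], summary_files["variant_meta"], summary_files["gene_meta"]
        )
        out = tmp_path / "out.tsv"
        write_summary(sm, out)
        sm2 = load_summary(out, summary_files["variant_meta"], summary_files["gene_meta"])
        assert (sm.Z == sm2.Z).all()
        assert sm.variant_ids == sm2.variant_ids and sm.gene_ids == sm2.gene_ids


class TestFilterTrans:
    WINDOW = 5_000_000

    @staticmethod
    def brute_force_kept(summary, window):
        kept = []
        for j, grow in summary.genes.iterrows():
            ok = True
            for _, vrow in summary.variants.iterrows():
                same = str(vrow.chromosome).lstrip("chr") == str(grow.chromosome).lstrip("chr")
                if same and abs(int(vrow.position) - int(grow.tss)) < window:
                    ok = False
            if ok:
                kept.append(grow.gene_id)
        return kept

    def test_three_by_three_example_matches_exhaustive_enumeration(self):
        sm = make_summary(
            np.zeros((3, 3)),
            vchrom=["1", "1", "2"],
            vpos=[1_000_000, 2_000_000, 1_000_000],
            gchrom=["1", "1", "3"],
            gtss=[7_500_000, 3_000_000, 1_000_000],
        )
        expected = self.brute_force_kept(sm, self.WINDOW)
        out = filter_trans(sm, self.WINDOW)
        assert out.gene_ids == expected
        # the chr1 gene at 7.5 Mb is >= 5 Mb from both chr1 variants, so it survives
        assert set(expected) == {"g0", "g2"}

    def test_different_chromosome_kept_and_boundary_dropped(self):
        sm = make_summary(
            np.zeros((1, 2)),
            vchrom=["1"],
            vpos=[10_000_000],
            gchrom=["2", "1"],
            gtss=[1_000_000, 10_000_000 - 4_999_999],
        )
        out = filter_trans(sm)
        assert out.gene_ids == ["g0"]

    def test_exactly_five_megabases_is_trans(self):
        sm = make_summary(np.zeros((1, 1)), vchrom=["1"], vpos=[6_000_000], gchrom=["1"], gtss=[1_000_000])
        assert filter_trans(sm).gene_ids == ["g0"]

    def test_chromosome_label_normalization(self):
        sm = make_summary(np.zeros((1, 1)), vchrom=["chr1"], vpos=[1_000_000], gchrom=["1"], gtss=[2_000_000])
        with pytest.raises(EmptyMatrixError):
            filter_trans(sm)

    def test_idempotent_and_monotone_in_window(self, rng):
        sm = make_summary(
            rng.standard_normal((4, 12)),
            vchrom=["1", "1", "2", "3"],
            vpos=rng.integers(1, 50_000_000, 4).tolist(),
            gchrom=[str(c) for c in rng.integers(1, 4, 12)],
            gtss=rng.integers(1, 50_000_000, 12).tolist(),
        )
        once = filter_trans(sm, 2_000_000)
        twice = filter_trans(once, 2_000_000)
        assert once.gene_ids == twice.gene_ids
        sizes = []
        for w in [0, 1_000_000, 5_000_000, 20_000_000]:
            try:
                sizes.append(len(filter_trans(sm, w).gene_ids))
            except EmptyMatrixError:
                sizes.append(0)
        assert sizes == sorted(sizes, reverse=True)


class TestIntersectExpressed:
    def test_intersection_identity_and_empty(self):
        sm = make_summary(np.zeros((2, 3)))
        out = intersect_expressed(sm, {"g1", "g2", "g9"})
        assert out.gene_ids == ["g1", "g2"]
        assert intersect_expressed(sm, {"g0", "g1", "g2", "extra"}).gene_ids == sm.gene_ids
        with pytest.raises(EmptyMatrixError):
            intersect_expressed(sm, {"nope"})
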
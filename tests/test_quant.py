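"""Filtering, fractional counting and RPKM: examples, oracle, invariants."""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
import pysam
import pytest

from phaseq import quant, synth
from phaseq.quant import (
    AnnotationError, CDSFeature, DegenerateSampleError, GenomeAnnotation,
    Locus, ReadAlignmentGroup,
)


def make_group(read_id, *loci):
    return ReadAlignmentGroup(read_id, [Locus(*l) for l in loci])


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

class TestAnnotationIO:
    def test_reversed_rrna_interval_normalised(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n##sequence-region chr1 1 4000000\n"
            "chr1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=g1\n"
        )
        rrna = tmp_path / "r.tsv"
        rrna.write_text("replicon\tstart\tend\nchr1\t3580380\t3575211\n")
        ann = quant.read_annotation(gff, rrna)
        assert ann.rrna_intervals == [("chr1", 3575211, 3580380)]
        assert ann.rrna_intervals_raw == [("chr1", 3580380, 3575211)]

    def test_empty_rrna_file_gives_empty_exclusion_set(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n##sequence-region chr1 1 1000\n"
            "chr1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=g1\n"
        )
        rrna = tmp_path / "r.tsv"
        rrna.write_text("replicon\tstart\tend\n")
        ann = quant.read_annotation(gff, rrna)
        assert ann.rrna_intervals == []

    def test_cds_beyond_replicon_bounds_rejected(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n##sequence-region chr1 1 1000\n"
            "chr1\tsrc\tCDS\t100\t1400\t.\t+\t0\tID=g1\n"
        )
        rrna = tmp_path / "r.tsv"
        rrna.write_text("replicon\tstart\tend\n")
        with pytest.raises(AnnotationError):
            quant.read_annotation(gff, rrna)

    def test_unknown_replicon_rejected(self):
        with pytest.raises(AnnotationError):
            GenomeAnnotation([("chr1", 1000)],
                             [CDSFeature("g1", "chrX", 1, 100)], [])

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(AnnotationError):
            GenomeAnnotation(
                [("chr1", 1000)],
                [CDSFeature("g1", "chr1", 1, 100),
                 CDSFeature("g1", "chr1", 200, 300)], [])

    def test_synth_writers_round_trip(self, tmp_path):
        cfg = synth.SynthConfig(n_genes=10, seed=4)
        ann = synth.generate_annotation(cfg)
        synth.write_gff3(ann, tmp_path / "a.gff3")
        synth.write_rrna_tsv(ann, tmp_path / "r.tsv")
        back = quant.read_annotation(tmp_path / "a.gff3", tmp_path / "r.tsv")
        assert back.replicons == ann.replicons
        assert sorted(back.cds, key=lambda f: f.gene_id) == sorted(
            ann.cds, key=lambda f: f.gene_id)
        assert back.rrna_intervals == ann.rrna_intervals


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def write_sam(path, records, replicons=(("chr1", 10_000), ("chr2", 8_000))):
    """records: (qname, replicon, start_1based, nm, flag) or None ref (unmapped)."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": l} for n, l in replicons],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, rep, start, nm, flag in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.query_sequence = "A" * 36
            a.flag = flag
            if rep is None:
                a.flag |= 4
                a.reference_id = -1
            else:
                a.reference_id = header.get_tid(rep)
                a.reference_start = start - 1
                a.cigarstring = "36M"
                a.set_tag("NM", nm)
            out.write(a)


class TestGroupAlignments:
    def test_shared_qname_collates_to_one_group(self, tmp_path):
        p = tmp_path / "x.sam"
        write_sam(p, [
            ("r1", "chr1", 1001, 0, 0),
            ("r1", "chr1", 3001, 0, 256),
            ("r1", "chr2", 501, 1, 256),
            ("r2", "chr2", 601, 0, 0),
        ])
        groups = list(quant.group_alignments(p))
        assert [g.read_id for g in groups] == ["r1", "r2"]
        assert len(groups[0].loci) == 3
        assert groups[0].loci[0].end == 1001 + 35

    def test_unmapped_record_contributes_no_locus(self, tmp_path):
        p = tmp_path / "x.sam"
        write_sam(p, [("r1", None, 0, 0, 0), ("r2", "chr1", 1001, 0, 0)])
        groups = list(quant.group_alignments(p))
        assert [g.read_id for g in groups] == ["r2"]

    def test_group_content_independent_of_record_order(self, tmp_path):
        records = [
            (f"r{i}", "chr1", 1001 + 10 * i, i % 2, 0) for i in range(20)
        ] + [(f"r{i}", "chr2", 501 + 5 * i, 0, 256) for i in range(10)]
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(p1, records)
        write_sam(p2, shuffled)
        g1 = list(quant.group_alignments(p1))
        g2 = list(quant.group_alignments(p2))
        assert [(g.read_id, g.loci) for g in g1] == [(g.read_id, g.loci) for g in g2]

    def test_missing_sq_header_rejected(self, tmp_path):
        p = tmp_path / "x.sam"
        p.write_text("@HD\tVN:1.6\n")
        with pytest.raises(quant.SamHeaderError):
            list(quant.group_alignments(p))

    def test_missing_nm_tag_warns_and_counts_zero(self, tmp_path):
        p = tmp_path / "x.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
            "r1\t0\tchr1\t1001\t37\t36M\t*\t0\t0\t" + "A" * 36 + "\t" + "I" * 36 + "\n"
        )
        with pytest.warns(UserWarning, match="NM"):
            groups = list(quant.group_alignments(p))
        assert groups[0].loci[0].mismatches == 0


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

class TestFilterAlignments:
    def test_mismatched_single_locus_read_dropped(self, tiny_annotation):
        groups = [make_group("r1", ("chr1", 1001, 1036, 1))]
        retained, stats = quant.filter_alignments(groups, tiny_annotation)
        assert retained == []
        assert stats.n_reads_input == 1
        assert stats.n_reads_retained == 0
        assert stats.n_loci_dropped_mismatch == 1

    def test_rrna_read_dropped_and_tallied(self, tiny_annotation):
        groups = [make_group("r1", ("chr1", 5500, 5535, 0))]
        retained, stats = quant.filter_alignments(groups, tiny_annotation)
        assert retained == []
        assert stats.n_reads_rrna == 1
        assert stats.frac_rrna == 1.0

    def test_rrna_locus_dropped_but_genic_locus_survives(self, tiny_annotation):
        groups = [make_group("r1", ("chr1", 5500, 5535, 0),
                             ("chr1", 1100, 1135, 0))]
        retained, stats = quant.filter_alignments(groups, tiny_annotation)
        assert len(retained) == 1
        assert len(retained[0].loci) == 1
        assert retained[0].loci[0].start == 1100
        assert stats.n_reads_rrna == 0  # a genic locus survived

    def test_per_read_rrna_flag_drops_whole_read(self, tiny_annotation):
        groups = [make_group("r1", ("chr1", 5500, 5535, 0),
                             ("chr1", 1100, 1135, 0))]
        retained, stats = quant.filter_alignments(
            groups, tiny_annotation, drop_whole_read_on_rrna=True)
        assert retained == []
        assert stats.n_reads_rrna == 1

    def test_boundary_overlap_counts_as_rrna(self, tiny_annotation):
        # one-bp overlap at interval edge (5001) is enough
        groups = [make_group("r1", ("chr1", 4966, 5001, 0))]
        retained, stats = quant.filter_alignments(groups, tiny_annotation)
        assert retained == []
        assert stats.n_reads_rrna == 1


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

class TestCountReads:
    def test_two_locus_read_split_half_and_half(self, tiny_annotation):
        groups = [make_group("r1", ("chr1", 1100, 1135, 0),
                             ("chr1", 3100, 3135, 0))]
        counts, lib = quant.count_reads(groups, tiny_annotation)
        assert counts["geneA"] == pytest.approx(0.5)
        assert counts["geneB"] == pytest.approx(0.5)
        assert lib == pytest.approx(1.0)

    def test_unique_read_counts_one(self, tiny_annotation):
        groups = [make_group("r1", ("chr2", 600, 635, 0))]
        counts, lib = quant.count_reads(groups, tiny_annotation)
        assert counts["geneC"] == pytest.approx(1.0)

    def test_intergenic_locus_contributes_nothing(self, tiny_annotation):
        groups = [make_group("r1", ("chr1", 8000, 8035, 0))]
        counts, lib = quant.count_reads(groups, tiny_annotation)
        assert lib == 0.0

    def test_total_weight_conserved_for_all_genic_multihits(self, tiny_annotation):
        genic_starts = [("chr1", 1100), ("chr1", 1200), ("chr1", 3100),
                        ("chr2", 600)]
        groups = [
            make_group(f"r{i}", *[(rep, s, s + 35, 0) for rep, s in genic_starts])
            for i in range(10)
        ]
        counts, lib = quant.count_reads(groups, tiny_annotation)
        assert lib == pytest.approx(10.0, abs=1e-9)

    def test_matches_brute_force_oracle_on_random_reads(
            self, tiny_annotation, counting_oracle):
        rng = np.random.default_rng(42)
        positions = {"chr1": 10_000 - 36, "chr2": 8_000 - 36}
        groups = []
        for i in range(300):
            k = int(rng.integers(1, 4))
            loci = []
            for _ in range(k):
                rep = ["chr1", "chr2"][int(rng.integers(2))]
                start = int(rng.integers(1, positions[rep]))
                nm = int(rng.random() < 0.2)
                loci.append((rep, start, start + 35, nm))
            groups.append(make_group(f"r{i:03d}", *loci))
        retained, _ = quant.filter_alignments(groups, tiny_annotation)
        counts, lib = quant.count_reads(retained, tiny_annotation)
        expected, _ = counting_oracle(groups, tiny_annotation)
        pd.testing.assert_series_equal(
            counts, expected, check_names=False, atol=1e-9)


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

class TestComputeRpkm:
    def test_unit_case(self):
        rpkm = quant.compute_rpkm(
            pd.Series({"g": 10.0}), pd.Series({"g": 1000.0}), 1e6)
        assert rpkm["g"] == pytest.approx(10.0)

    def test_hand_arithmetic_two_genes(self):
        counts = pd.Series({"A": 75.0, "B": 25.0})
        lengths = pd.Series({"A": 1500.0, "B": 500.0})
        rpkm = quant.compute_rpkm(counts, lengths, 100.0)
        assert rpkm["A"] == pytest.approx(500_000.0)
        assert rpkm["B"] == pytest.approx(500_000.0)

    def test_scale_invariance(self):
        counts = pd.Series({"A": 75.0, "B": 25.0})
        lengths = pd.Series({"A": 1500.0, "B": 500.0})
        a = quant.compute_rpkm(counts, lengths, 100.0)
        b = quant.compute_rpkm(2 * counts, lengths, 200.0)
        pd.testing.assert_series_equal(a, b)

    def test_zero_library_rejected(self):
        with pytest.raises(DegenerateSampleError):
            quant.compute_rpkm(pd.Series({"g": 0.0}), pd.Series({"g": 100.0}), 0.0)

    def test_rpkm_length_identity(self, tiny_annotation):
        """All-genic input: sum over genes of RPKM * length_kb = 1e6."""
        counts = pd.DataFrame({"s1": [10.0, 5.0, 2.5], "s2": [1.0, 2.0, 3.0]},
                              index=["geneA", "geneB", "geneC"])
        design = pd.DataFrame(
            {"condition": ["F16", "F26"], "replicate": [1, 1]},
            index=["s1", "s2"])
        mat = quant.RPKMMatrix(counts, tiny_annotation.gene_lengths(), design)
        total = (mat.rpkm.mul(mat.gene_length / 1000.0, axis=0)).sum(axis=0)
        assert total.to_numpy() == pytest.approx([1e6, 1e6], rel=1e-12)


class TestEndToEnd:
    def test_recovery_rank_order_without_confounders(self, tmp_path):
        """No rRNA, no multimapping, no mismatches: RPKM rank order matches
        the programmed expression levels and relative RPKM tracks relative
        read density."""
        cfg = synth.SynthConfig(
            n_genes=8, reads_per_sample=4000, rrna_read_fraction=0.0,
            mismatch_fraction=0.0, multimap_fraction=0.0, n_rrn_regions=0,
            seed=8,
        )
        ann = synth.generate_annotation(cfg)
        prof = synth.default_profile(ann, cfg)
        sam = tmp_path / "s.sam"
        truth = synth.simulate_alignments(ann, prof, cfg, "F16", 1, sam)
        counts, stats = quant.quantify_sample(sam, ann)
        assert stats.n_reads_retained == cfg.reads_per_sample
        rpkm = quant.compute_rpkm(counts, ann.gene_lengths(), counts.sum())
        levels = prof.true_level["F16"]
        expressed = levels[levels > 0.5].index
        got = rpkm[expressed].rank()
        want = levels[expressed].rank()
        assert (got == want).all()
        # relative RPKM ~ relative true read density (reads per base)
        dens = truth.per_gene_counts[expressed] / ann.gene_lengths()[expressed]
        ratio_rpkm = rpkm[expressed] / rpkm[expressed].sum()
        ratio_dens = dens / dens.sum()
        assert ratio_rpkm.to_numpy() == pytest.approx(
            ratio_dens.to_numpy(), rel=0.05)
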
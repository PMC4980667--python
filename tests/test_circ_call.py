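import numpy as np
import pytest

from circmotif import circ_call as cc
from circmotif import synthetic_data as sd
from circmotif.errors import ChimericTableFormatError
from circmotif.models import Annotation, GeneModel, revcomp

from conftest import boundary_junction, make_record


class TestChimericTable:
    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("\t".join(cc.CHIMERIC_COLUMNS) + "\n")
        records, errors = cc.read_chimeric_table(path)
        assert records == [] and errors == []

    def test_one_based_to_half_open(self, tmp_path):
        path = tmp_path / "t.tsv"
        row = ["r1", "L1", "chr1", "101", "150", "+", "chr1", "1", "50", "+", "90", "80"]
        path.write_text("\t".join(cc.CHIMERIC_COLUMNS) + "\n" + "\t".join(row) + "\n")
        records, _ = cc.read_chimeric_table(path)
        assert (records[0].start_a, records[0].end_a) == (100, 150)
        assert (records[0].start_b, records[0].end_b) == (0, 50)

    def test_round_trip_lossless(self, simulated_records, tmp_path):
        records, _ = simulated_records
        path = tmp_path / "t.tsv"
        cc.write_chimeric_table(records, path)
        back, errors = cc.read_chimeric_table(path)
        assert errors == []
        assert back == list(records)

    def test_malformed_rows_collected_with_line_numbers(self, tmp_path):
        path = tmp_path / "t.tsv"
        good = ["r1", "L1", "chr1", "101", "150", "+", "chr1", "1", "50", "+", "90", "80"]
        bad = ["r2", "L1", "chr1", "xx", "150", "+", "chr1", "1", "50", "+", "90", "80"]
        path.write_text(
            "\t".join(cc.CHIMERIC_COLUMNS) + "\n"
            + "\t".join(good) + "\n"
            + "\t".join(bad) + "\n"
            + "\t".join(good[:5]) + "\n"
        )
        records, errors = cc.read_chimeric_table(path)
        assert len(records) == 1
        assert [line for line, _ in errors] == [3, 4]
        with pytest.raises(ChimericTableFormatError):
            cc.read_chimeric_table(path, strict=True)

    def test_missing_header_is_format_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tb\n")
        with pytest.raises(ChimericTableFormatError):
            cc.read_chimeric_table(path)


class TestExtractFromSam:
    def test_no_supplementary_gives_empty(self, tmp_path):
        path = tmp_path / "x.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t1\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tAS:i:50\n"
        )
        assert cc.extract_from_sam(path) == []

    def test_linear_score_margin(self, genome_annotation, tmp_path):
        genome, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        rec = make_record(gene, acc, don, chimeric_score=90, best_linear_score=80)
        path = tmp_path / "x.sam"
        sd.write_sam([rec], genome, path)
        (back,) = cc.extract_from_sam(path)
        assert back.chimeric_score - back.best_linear_score == 10

    def test_segment_order_matches_simulator_truth_on_1000_records(self, tmp_path):
        cfg = sd.SimConfig(seed=21, n_chrom=2, chrom_length=120_000, n_genes=25)
        genome = sd.make_genome(cfg)
        annotation, genome = sd.make_annotation(genome, cfg)
        spec = sd.make_truth_spec(
            annotation, cfg, 8, libraries=["A", "B"],
            counts=[{"A": 60, "B": 60}] * 8,
        )
        records, _ = sd.simulate_chimeric_records(
            genome, annotation, spec, cfg, decoys_per_class=10
        )
        assert len(records) >= 1000
        path = tmp_path / "x.sam"
        sd.write_sam(records, genome, path)
        back = {r.record_id: r for r in cc.extract_from_sam(path, genome, annotation)}
        assert len(back) == len(records)
        for r in records:
            b = back[r.record_id]
            assert (b.chrom_a, b.start_a, b.end_a, b.strand_a) == (
                r.chrom_a, r.start_a, r.end_a, r.strand_a,
            )
            assert (b.chrom_b, b.start_b, b.end_b, b.strand_b) == (
                r.chrom_b, r.start_b, r.end_b, r.strand_b,
            )
            assert (b.overhang_a, b.overhang_b) == (r.overhang_a, r.overhang_b)
            assert b.library_id == r.library_id

    def test_three_segment_read_skipped(self, genome_annotation, tmp_path):
        genome, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        rec = make_record(gene, acc, don)
        path = tmp_path / "x.sam"
        sd.write_sam([rec], genome, path)
        with open(path) as fh:
            lines = fh.readlines()
        # duplicate the supplementary line: the read now has 3 chimeric segments
        path.write_text("".join(lines) + lines[-2])
        assert cc.extract_from_sam(path) == []


class TestFilters:
    def test_overhang_boundary(self, genome_annotation):
        genome, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        params = cc.FilterParams()
        passing = make_record(gene, acc, don, overhang_a=12, overhang_b=40)
        failing = make_record(gene, acc, don, overhang_a=11, overhang_b=40)
        assert cc.criterion_flags(passing, genome, annotation, params)["c2"]
        flags = cc.criterion_flags(failing, genome, annotation, params)
        assert not flags["c2"]
        assert flags["c1"] and flags["c3"] and flags["c4"]

    def test_score_margin_boundary(self, genome_annotation):
        genome, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        params = cc.FilterParams()
        margin2 = make_record(gene, acc, don, chimeric_score=50, best_linear_score=48)
        margin3 = make_record(gene, acc, don, chimeric_score=50, best_linear_score=47)
        assert not cc.criterion_flags(margin2, genome, annotation, params)["c3"]
        assert cc.criterion_flags(margin3, genome, annotation, params)["c3"]

    def test_decoy_classes_rejected_with_designated_flag(
        self, genome_annotation, simulated_records
    ):
        genome, annotation = genome_annotation
        records, truth = simulated_records
        _accepted, flags = cc.apply_filters(records, genome, annotation)
        table = flags.set_index("record_id")
        for rid, crit in truth.decoy_records:
            row = table.loc[rid]
            assert not row["accepted"]
            assert not row[f"c{crit}"]
            for other in (1, 2, 3, 4):
                if other != crit:
                    assert row[f"c{other}"]

    def test_monotonicity_in_thresholds(self, genome_annotation, simulated_records):
        genome, annotation = genome_annotation
        records, _ = simulated_records

        def n_accepted(**kwargs):
            accepted, _ = cc.apply_filters(
                records, genome, annotation, cc.FilterParams(**kwargs)
            )
            return len(accepted)

        base = n_accepted()
        assert n_accepted(min_overhang=20) <= base
        assert n_accepted(score_margin=10) <= base
        assert n_accepted(min_overhang=20, score_margin=10) <= min(
            n_accepted(min_overhang=20), n_accepted(score_margin=10)
        )

    def test_out_of_bounds_junction_rejected(self, genome_annotation):
        genome, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        rec = make_record(gene, acc, don)
        tiny = {gene.chrom: genome[gene.chrom][: acc + 1]}
        flags = cc.criterion_flags(rec, tiny, annotation, cc.FilterParams())
        assert not flags["in_bounds"] and not flags["accepted"]


class TestCanonicalOrAnnotated:
    def test_simulated_boundary_is_both(self, genome_annotation):
        genome, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        j = cc.BackspliceJunction(gene.chrom, gene.strand, acc, don)
        ok, label = cc.canonical_or_annotated(j, genome, annotation)
        assert ok and label == "both"

    def test_shifted_junction_fails(self, genome_annotation):
        genome, annotation = genome_annotation
        for gene in annotation.genes:
            gene_, acc, don = gene, gene.exons[0][0], gene.exons[-1][1]
            seq = genome[gene.chrom]
            left = seq[acc - 1 : acc + 1]
            want = "AG" if gene.strand == "+" else "AC"
            if left != want:  # +1 shift must not be accidentally canonical
                j = cc.BackspliceJunction(gene.chrom, gene.strand, acc + 1, don)
                ok, label = cc.canonical_or_annotated(j, genome, annotation)
                assert not ok and label == "neither"
                return
        pytest.skip("no shiftable gene found")

    def test_minus_strand_flanks(self):
        #      acc=10          don=20
        seq = "T" * 8 + "AC" + "G" * 10 + "CT" + "T" * 8
        genome = {"chr1": seq}
        annotation = Annotation([])
        j = cc.BackspliceJunction("chr1", "-", 10, 20)
        ok, label = cc.canonical_or_annotated(j, genome, annotation)
        assert ok and label == "canonical"
        # oracle: reverse-complement the locus and apply the + strand rule
        mirrored = {"chr1": revcomp(seq)}
        L = len(seq)
        jm = cc.BackspliceJunction("chr1", "+", L - 20, L - 10)
        ok_m, label_m = cc.canonical_or_annotated(jm, mirrored, annotation)
        assert ok_m and label_m == "canonical"

    def test_flank_off_end_is_neither(self):
        genome = {"chr1": "ACGTACGTAC"}
        j = cc.BackspliceJunction("chr1", "+", 1, 10)
        ok, label = cc.canonical_or_annotated(j, genome, Annotation([]))
        assert not ok and label == "neither"


class TestCountJunctions:
    def test_counts(self, genome_annotation):
        genome, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        records = [
            make_record(gene, acc, don, record_id=f"r{i}", library_id="A")
            for i in range(40)
        ]
        (j,) = cc.count_junctions(records)
        assert j.counts == {"A": 40}

    def test_duplicate_record_id_counted_once(self, genome_annotation):
        _, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        records = [
            make_record(gene, acc, don, record_id="dup", library_id="A"),
            make_record(gene, acc, don, record_id="dup", library_id="A"),
            make_record(gene, acc, don, record_id="dup", library_id="B"),
        ]
        (j,) = cc.count_junctions(records)
        assert j.counts == {"A": 1, "B": 1}

    def test_count_conservation(self, genome_annotation, simulated_records):
        genome, annotation = genome_annotation
        records, _ = simulated_records
        accepted, _ = cc.apply_filters(records, genome, annotation)
        junctions = cc.count_junctions(accepted)
        total = sum(sum(j.counts.values()) for j in junctions)
        distinct = {(r.record_id, r.library_id) for r in accepted}
        assert total == len(distinct)

    def test_strand_symmetry_under_genome_mirror(
        self, small_config, genome_annotation
    ):
        genome, annotation = genome_annotation
        spec = sd.make_truth_spec(annotation, small_config, 4, libraries=["A"])
        records, _ = sd.simulate_chimeric_records(
            genome, annotation, spec, small_config, decoys_per_class=8
        )
        lengths = {c: len(s) for c, s in genome.items()}
        mirror_genome = {c: revcomp(s) for c, s in genome.items()}
        mirror_ann = Annotation(
            [
                GeneModel(
                    g.gene_id, g.chrom, "-" if g.strand == "+" else "+", g.biotype,
                    [(lengths[g.chrom] - e, lengths[g.chrom] - s) for s, e in g.exons],
                )
                for g in annotation.genes
            ]
        )

        def mirror_record(r):
            from dataclasses import replace

            return replace(
                r,
                start_a=lengths[r.chrom_a] - r.end_a,
                end_a=lengths[r.chrom_a] - r.start_a,
                strand_a="-" if r.strand_a == "+" else "+",
                start_b=lengths[r.chrom_b] - r.end_b,
                end_b=lengths[r.chrom_b] - r.start_b,
                strand_b="-" if r.strand_b == "+" else "+",
            )

        mirrored = [mirror_record(r) for r in records]
        acc1, _ = cc.apply_filters(records, genome, annotation)
        acc2, _ = cc.apply_filters(mirrored, mirror_genome, mirror_ann)
        keys1 = {
            (j.chrom, j.strand, j.acceptor_pos, j.donor_pos, tuple(sorted(j.counts.items())))
            for j in cc.count_junctions(acc1)
        }
        keys2 = {
            (
                j.chrom,
                "-" if j.strand == "+" else "+",
                lengths[j.chrom] - j.donor_pos,
                lengths[j.chrom] - j.acceptor_pos,
                tuple(sorted(j.counts.items())),
            )
            for j in cc.count_junctions(acc2)
        }
        assert keys1 == keys2


class TestSelectTargets:
    def test_high_confidence_in_at_least_one_library(self, genome_annotation):
        _, annotation = genome_annotation
        gene, acc, don = boundary_junction(annotation)
        high = cc.BackspliceJunction(gene.chrom, gene.strand, acc, don, {"A": 40, "B": 5})
        low = cc.BackspliceJunction(gene.chrom, gene.strand, acc, don, {"A": 29, "B": 29, "C": 29})
        (c_high,) = cc.select_targets([high], annotation)
        (c_low,) = cc.select_targets([low], annotation)
        assert c_high.status == "high_confidence"
        assert c_low.status == "detected"

    def test_circ_length_sums_exon_lengths(self):
        # exons of 150 and 69 nt -> total 219 (the smallest reported circRNA size)
        gene = GeneModel("G1", "chr1", "+", "protein_coding", [(100, 250), (300, 369)])
        annotation = Annotation([gene])
        j = cc.BackspliceJunction("chr1", "+", 100, 369, {"A": 10})
        (cand,) = cc.select_targets([j], annotation)
        oracle = sum(e - s for s, e in gene.exons)
        assert oracle == 219
        assert cand.circ_length == 219
        assert cand.n_exons == 2

    def test_intergenic_junction_flagged(self, genome_annotation):
        _, annotation = genome_annotation
        j = cc.BackspliceJunction("chrNA", "+", 10, 500, {"A": 3})
        (cand,) = cc.select_targets([j], annotation)
        assert cand.gene_id == cc.INTERGENIC
        assert cand.n_exons == 0
        assert cand.circ_length == 490


class TestNontargetGroup:
    @pytest.fixture()
    def genes(self):
        pc = GeneModel("PC1", "chr1", "+", "protein_coding", [(100, 200), (300, 400)])
        linc = GeneModel("LINC1", "chr1", "+", "lincRNA", [(1000, 1100), (1200, 1300)])
        return Annotation([pc, linc])

    def test_count_threshold_boundary(self, genes):
        j10 = cc.BackspliceJunction("chr1", "+", 100, 400, {"E": 10})
        j9 = cc.BackspliceJunction("chr1", "+", 100, 400, {"E": 9})
        assert len(cc.derive_nontarget_group([j10], [], genes)) == 1
        assert len(cc.derive_nontarget_group([j9], [], genes)) == 0

    def test_single_ip_read_disqualifies(self, genes):
        expr = cc.BackspliceJunction("chr1", "+", 100, 400, {"E": 50})
        ip = cc.BackspliceJunction("chr1", "+", 100, 400, {"IP": 1})
        assert cc.derive_nontarget_group([expr], [ip], genes) == []

    def test_lincrna_host_excluded(self, genes):
        j = cc.BackspliceJunction("chr1", "+", 1000, 1300, {"E": 100})
        assert cc.derive_nontarget_group([j], [], genes) == []

    def test_status_non_target(self, genes):
        j = cc.BackspliceJunction("chr1", "+", 100, 400, {"E": 12})
        (cand,) = cc.derive_nontarget_group([j], [], genes)
        assert cand.status == "non_target"
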
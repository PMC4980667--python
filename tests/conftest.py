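import pytest

from circmotif import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimConfig(seed=7, n_chrom=2, chrom_length=60_000, n_genes=12)


@pytest.fixture(scope="session")
def genome_annotation(small_config):
    genome = sd.make_genome(small_config)
    annotation, patched = sd.make_annotation(genome, small_config)
    return patched, annotation


@pytest.fixture(scope="session")
def simulated_records(small_config, genome_annotation):
    genome, annotation = genome_annotation
    truth_spec = sd.make_truth_spec(
        annotation, small_config, 3,
        libraries=["A", "B", "C"],
        counts=[{"A": 40, "B": 3, "C": 1}, {"A": 10, "B": 2, "C": 5}, {"A": 35, "B": 31, "C": 4}],
    )
    records, truth = sd.simulate_chimeric_records(
        genome, annotation, truth_spec, small_config, decoys_per_class=12
    )
    return records, truth


def boundary_junction(annotation, min_span=100):
    """First exon-boundary junction with a span wide enough for reads."""
    for gene in annotation.genes:
        for i, (s1, _e1) in enumerate(gene.exons):
            for _s2, e2 in gene.exons[i:]:
                if e2 - s1 >= min_span:
                    return gene, s1, e2
    raise AssertionError("no junction site in annotation")


def make_record(
    gene, acc, don, record_id="r1", library_id="L1",
    overhang_a=40, overhang_b=40, chimeric_score=100, best_linear_score=90,
):
    """A criterion-passing chimeric record at an exon-boundary junction."""
    from circmotif.circ_call import ChimericRecord

    la, lb = overhang_a, overhang_b
    if gene.strand == "+":
        seg_a = (don - la, don)
        seg_b = (acc, acc + lb)
    else:
        seg_a = (acc, acc + la)
        seg_b = (don - lb, don)
    return ChimericRecord(
        record_id=record_id,
        library_id=library_id,
        chrom_a=gene.chrom,
        start_a=seg_a[0],
        end_a=seg_a[1],
        strand_a=gene.strand,
        chrom_b=gene.chrom,
        start_b=seg_b[0],
        end_b=seg_b[1],
        strand_b=gene.strand,
        chimeric_score=chimeric_score,
        best_linear_score=best_linear_score,
    )
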
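import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crosscnv.annotate import (
    CATEGORY_ORDER,
    GeneModel,
    annotate_set,
    category_counts,
    classify_region,
    tandem_check,
)
from crosscnv.cohort import Interval
from crosscnv.genome import GenomeSequence, generate_reference
from crosscnv.io import load_gene_models


@pytest.fixture()
def gene():
    # + strand gene: span [10000, 20000), exons at the ends, UTRs inside the
    # terminal exons' flanks, intron in the middle
    return GeneModel(
        gene_id="G1",
        chrom="c",
        start=10_000,
        end=20_000,
        strand="+",
        exons=[(10_000, 11_000), (19_000, 20_000)],
        utrs=[(11_000, 11_200), (18_800, 19_000)],
    )


@pytest.mark.parametrize(
    "start,end,expected",
    [
        (9_000, 21_000, "whole_gene"),
        (10_000, 20_000, "whole_gene"),
        (10_500, 12_000, "exonic"),
        (18_500, 19_500, "exonic"),
        (11_100, 11_150, "UTR"),
        (12_000, 15_000, "intronic"),
        (11_250, 18_700, "intronic"),
        (8_000, 9_000, "upstream"),  # 1 kbp 5' of a + strand gene
        (5_100, 9_900, "upstream"),
        (20_500, 21_000, "downstream"),
        (1_000, 2_000, "intergenic"),
        (26_000, 27_000, "intergenic"),  # beyond the 5 kbp flank
    ],
)
def test_region_categories_plus_strand(gene, start, end, expected):
    assert classify_region(Interval("c", start, end), gene) == expected


def test_flanks_follow_strand(gene):
    minus = GeneModel(
        gene_id="G2", chrom="c", start=10_000, end=20_000, strand="-",
        exons=[(10_000, 11_000)],
    )
    up = Interval("c", 8_000, 9_000)
    down = Interval("c", 20_500, 21_000)
    assert classify_region(up, gene) == "upstream"
    assert classify_region(down, gene) == "downstream"
    assert classify_region(up, minus) == "downstream"
    assert classify_region(down, minus) == "upstream"


def test_flank_width_configurable(gene):
    cnv = Interval("c", 4_000, 4_500)
    assert classify_region(cnv, gene, flank=5000) == "intergenic"
    assert classify_region(cnv, gene, flank=7000) == "upstream"


def test_different_chromosome_is_intergenic(gene):
    assert classify_region(Interval("other", 10_000, 20_000), gene) == "intergenic"


def test_malformed_gene_model_names_gene():
    with pytest.raises(ValueError, match="BAD"):
        GeneModel(gene_id="BAD", chrom="c", start=100, end=200, strand="+",
                  exons=[(50, 150)])


def test_annotation_precedence_across_genes(gene):
    other = GeneModel(
        gene_id="G3", chrom="c", start=30_000, end=40_000, strand="+",
        exons=[(30_000, 31_000)],
    )
    # CNV spans G1's exon and sits inside G3's intron -> exonic at CNV level
    cnv = Interval("c", 10_500, 35_000)
    table = annotate_set([cnv], [gene, other])
    assert table.loc[0, "category"] == "exonic"
    assert table.loc[0, "genes"] == "G1,G3"
    # gene order does not change the call
    table2 = annotate_set([cnv], [other, gene])
    assert table2.loc[0, "category"] == "exonic"
    assert table2.loc[0, "genes"] == "G1,G3"


def test_annotation_counts_sum_to_cnvs(gene):
    cnvs = [
        Interval("c", 9_000, 21_000),
        Interval("c", 12_000, 13_000),
        Interval("c", 1_000, 2_000),
        Interval("c", 8_000, 9_000),
    ]
    table = annotate_set(cnvs, [gene])
    counts = category_counts(table)
    assert sum(counts.values()) == len(cnvs)
    assert counts["whole_gene"] == 1
    assert counts["intronic"] == 1
    assert counts["intergenic"] == 1
    assert counts["upstream"] == 1
    assert list(counts) == CATEGORY_ORDER


def test_no_genes_everything_intergenic():
    table = annotate_set([Interval("c", 0, 1000)], [])
    assert table.loc[0, "category"] == "intergenic"


def test_chromosome_mismatch_rejected(gene):
    with pytest.raises(ValueError, match="chromosome"):
        annotate_set([Interval("chrZ", 0, 1000)], [gene])


def test_gff3_gene_models_loaded(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c\tsrc\tgene\t1001\t3000\t.\t+\t.\tID=gene1;biotype=protein_coding\n"
        "c\tsrc\tmRNA\t1001\t3000\t.\t+\t.\tID=tx1;Parent=gene1\n"
        "c\tsrc\texon\t1001\t1200\t.\t+\t.\tID=ex1;Parent=tx1\n"
        "c\tsrc\texon\t2801\t3000\t.\t+\t.\tID=ex2;Parent=tx1\n"
        "c\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=gene2;biotype=lincRNA\n"
    )
    genes = load_gene_models(gff)
    assert [g.gene_id for g in genes] == ["gene1", "gene2"]
    g1 = genes[0]
    assert (g1.start, g1.end) == (1000, 3000)  # converted to 0-based half-open
    assert g1.exons == [(1000, 1200), (2800, 3000)]
    assert genes[1].biotype == "lincRNA"
    assert genes[1].strand == "-"


# --- tandem / dispersed duplication checks -------------------------------

def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_tandem_verdict_for_duplicated_sequence():
    rng = np.random.default_rng(81)
    s = random_seq(rng, 400)
    assert tandem_check(s + s) == "tandem"


def test_unique_sequence_verdict():
    rng = np.random.default_rng(82)
    assert tandem_check(random_seq(rng, 500)) == "unique"


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=30, max_value=300), st.integers(min_value=0, max_value=2**31 - 1))
def test_tandem_property_for_any_unique_unit(n, seed):
    """S+S reads as tandem for every random S with |S| >= 2k."""
    rng = np.random.default_rng(seed)
    s = random_seq(rng, n)
    assert tandem_check(s + s) == "tandem"


def test_dispersed_duplicate_detected_across_chromosomes():
    genome = generate_reference(2, 5_000, seed=83, unique_k=50)
    rng = np.random.default_rng(84)
    s = genome.chromosomes["chr1"][1000:1600]
    # copy s into chr2 with 10% substitutions
    arr = list(s)
    for i in rng.choice(len(arr), size=len(arr) // 10, replace=False):
        arr[i] = "ACGT"[(("ACGT".index(arr[i])) + 1) % 4]
    mutated = "".join(arr)
    chr2 = genome.chromosomes["chr2"]
    patched = GenomeSequence(
        {
            "chr1": genome.chromosomes["chr1"],
            "chr2": chr2[:2000] + mutated + chr2[2000 + len(mutated):],
        }
    )
    verdict = tandem_check(s, patched, exclude=("chr1", 1000, 1600))
    assert verdict == "dispersed_duplicate"


def test_unique_when_source_locus_excluded():
    genome = generate_reference(1, 5_000, seed=85, unique_k=50)
    s = genome.chromosomes["chr1"][1000:1600]
    assert tandem_check(s, genome, exclude=("chr1", 1000, 1600)) == "unique"
    # without masking, the sequence trivially matches its own source
    assert tandem_check(s, genome) == "dispersed_duplicate"


def test_short_sequence_rejected():
    with pytest.raises(ValueError):
        tandem_check("ACGTACGTACGTACGTACGT", k=11)  # 20 < 2k
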
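import numpy as np
import pandas as pd
import pytest

from phasediv import coords, formats
from phasediv.models import (
    ExpressionMatrix,
    FormatError,
    GeneticMapMarker,
    HaplotypeGenome,
    RegionCall,
    sort_calls,
)


# ---------------------------------------------------------------------------
# coordinate conversions: the three boundary cases, both directions


@pytest.mark.parametrize(
    "internal,onebased",
    [
        ((0, 1), (1, 1)),  # first base
        ((9, 10), (10, 10)),  # last base of a 10 bp sequence
        ((4, 5), (5, 5)),  # length-1 interval
        ((7, 7), (8, 7)),  # zero-length breakpoint
    ],
)
def test_onebased_conversion_round_trip(internal, onebased):
    assert coords.to_onebased(*internal) == onebased
    assert coords.from_onebased(*onebased) == internal


def test_bed_conversion_is_identity():
    assert coords.to_bed(3, 9) == (3, 9)
    assert coords.from_bed(3, 9) == (3, 9)


# ---------------------------------------------------------------------------
# FASTA


def test_read_genome_identity_and_normalization(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nACGT\n>chr2\nacgtn\n>chr3\nACGU\n")
    g = formats.read_genome(str(p), "hap1")
    assert g.length("chr1") == 4
    assert g.chromosomes["chr2"] == "ACGTN"  # case normalization
    assert g.chromosomes["chr3"] == "ACGT"  # U -> T


def test_read_genome_rejects_invalid_character_with_offset(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nACXGT\n")
    with pytest.raises(FormatError, match=r"chr1.*'X' at offset 2"):
        formats.read_genome(str(p))


def test_read_genome_rejects_duplicate_ids(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c\nAC\n>c\nGT\n")
    with pytest.raises(FormatError, match="duplicate"):
        formats.read_genome(str(p))


def test_genome_write_read_round_trip(tmp_path, sim1):
    p = tmp_path / "h1.fa"
    formats.write_genome(sim1.hap1, str(p))
    again = formats.read_genome(str(p), "hap1")
    assert again.chromosomes == sim1.hap1.chromosomes


# ---------------------------------------------------------------------------
# GFF3


GFF_HEADER = "##gff-version 3\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


def test_annotation_plus_and_minus_strand_cds(tmp_path):
    fa = _write(tmp_path, "g.fa", ">c\nATGAAA\n")
    genome = formats.read_genome(fa)
    gff = _write(
        tmp_path,
        "a.gff3",
        GFF_HEADER
        + "c\t.\tgene\t1\t6\t.\t+\t.\tID=gp\n"
        + "c\t.\tmRNA\t1\t6\t.\t+\t.\tID=gp.t;Parent=gp\n"
        + "c\t.\tCDS\t1\t3\t.\t+\t0\tID=gp.c;Parent=gp.t\n"
        + "c\t.\tgene\t1\t6\t.\t-\t.\tID=gm\n"
        + "c\t.\tmRNA\t1\t6\t.\t-\t.\tID=gm.t;Parent=gm\n"
        + "c\t.\tCDS\t1\t3\t.\t-\t0\tID=gm.c;Parent=gm.t\n",
    )
    genes, skipped = formats.read_annotation(gff, genome)
    by_id = {g.gene_id: g for g in genes}
    assert skipped == 0
    assert by_id["gp"].cds_sequence == "ATG"  # direct slice
    assert by_id["gm"].cds_sequence == "CAT"  # reverse complement


def test_annotation_longest_mrna_rule_and_skip_count(tmp_path):
    fa = _write(tmp_path, "g.fa", ">c\n" + "ACGT" * 200 + "\n")
    gff = _write(
        tmp_path,
        "a.gff3",
        GFF_HEADER
        + "c\t.\tgene\t1\t400\t.\t+\t.\tID=g1\n"
        + "c\t.\tmRNA\t1\t400\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        + "c\t.\tCDS\t1\t300\t.\t+\t0\tID=c1;Parent=g1.t1\n"
        + "c\t.\tmRNA\t1\t400\t.\t+\t.\tID=g1.t2;Parent=g1\n"
        + "c\t.\tCDS\t1\t150\t.\t+\t0\tID=c2;Parent=g1.t2\n"
        + "c\t.\tgene\t500\t600\t.\t+\t.\tID=g2\n"
        + "c\t.\tmRNA\t500\t600\t.\t+\t.\tID=g2.t1;Parent=g2\n",
    )
    genome = formats.read_genome(fa)
    genes, skipped = formats.read_annotation(gff, genome)
    assert len(genes) == 1 and skipped == 1  # g2 has no CDS
    assert genes[0].cds_length == 300  # the 300-bp chain retained


def test_annotation_cds_outside_bounds_rejected(tmp_path):
    fa = _write(tmp_path, "g.fa", ">c\nACGTACGT\n")
    gff = _write(
        tmp_path,
        "a.gff3",
        GFF_HEADER
        + "c\t.\tgene\t1\t8\t.\t+\t.\tID=g\n"
        + "c\t.\tmRNA\t1\t8\t.\t+\t.\tID=g.t;Parent=g\n"
        + "c\t.\tCDS\t5\t20\t.\t+\t0\tID=g.c;Parent=g.t\n",
    )
    genome = formats.read_genome(fa)
    with pytest.raises(Exception):
        formats.read_annotation(gff, genome)


def test_annotation_round_trip_on_simulated_genes(tmp_path, sim1):
    gff = tmp_path / "h1.gff3"
    formats.write_annotation(sim1.genes_hap1, str(gff))
    genes, skipped = formats.read_annotation(str(gff), sim1.hap1)
    assert skipped == 0
    orig = {g.gene_id: g for g in sim1.genes_hap1}
    assert len(genes) == len(orig)
    for g in genes:
        o = orig[g.gene_id]
        assert (g.chrom, g.strand, g.start, g.end, g.cds) == (
            o.chrom, o.strand, o.start, o.end, o.cds
        )
        assert g.cds_sequence == o.cds_sequence


# ---------------------------------------------------------------------------
# region TSV


def test_region_calls_single_record_and_vocab(tmp_path):
    p = _write(tmp_path, "r.tsv", "c1\t1\t100\tc1\t1\t100\tSYN\n")
    calls = formats.read_region_calls(p)
    assert len(calls) == 1 and calls[0].rtype == "SYN"
    assert (calls[0].ref_start, calls[0].ref_end) == (0, 100)
    bad = _write(tmp_path, "bad.tsv", "c1\t1\t100\tc1\t1\t100\tDUP\n")
    with pytest.raises(FormatError, match=r"bad\.tsv:1.*'DUP'"):
        formats.read_region_calls(bad)


def test_region_calls_ins_with_absent_ref_side(tmp_path):
    p = _write(tmp_path, "r.tsv", "-\t-\t-\tc1\t11\t40\tINS\n")
    calls = formats.read_region_calls(p)
    c = calls[0]
    assert not c.has_ref and c.qry_len == 30
    out = tmp_path / "again.tsv"
    formats.write_region_calls(calls, str(out))
    assert formats.read_region_calls(str(out)) == calls


def test_region_calls_round_trip_on_simulator_truth(tmp_path, sim1):
    p = tmp_path / "regions.tsv"
    formats.write_region_calls(sim1.truth.regions, str(p))
    again = formats.read_region_calls(str(p))
    assert again == sort_calls(sim1.truth.regions)


# ---------------------------------------------------------------------------
# VCF


def test_vcf_anchor_base_convention(tmp_path):
    #           123456789
    ref = HaplotypeGenome("hap1", {"c": "ACGTAGGCT"})
    qry = HaplotypeGenome("hap2", {"c": "ACGTAGCTA"})
    calls = [
        RegionCall("SNP", ref_chrom="c", ref_start=4, ref_end=5,
                   qry_chrom="c", qry_start=4, qry_end=5,
                   ref_base="A", qry_base="G"),
        # deletion of 1-based 6..8 -> internal [5, 8)
        RegionCall("DEL", ref_chrom="c", ref_start=5, ref_end=8,
                   qry_chrom="c", qry_start=5, qry_end=5),
    ]
    p = tmp_path / "v.vcf"
    formats.write_vcf(calls, ref, qry, str(p))
    lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
    snp, dele = lines
    assert snp.split("\t")[1] == "5" and snp.split("\t")[3] == "A"
    f = dele.split("\t")
    # POS 5 anchor base, 4-base REF reconstructed from the sequence, 1-base ALT
    assert f[1] == "5"
    assert f[3] == ref.chromosomes["c"][4:8] and len(f[3]) == 4
    assert f[4] == ref.chromosomes["c"][4]
    assert formats.read_vcf(str(p)) == sort_calls(calls)


def test_vcf_round_trip_on_simulated_calls(tmp_path, sim1, calls1):
    subset = [c for c in calls1 if c.rtype in ("SNP", "INS", "DEL")][:500]
    p = tmp_path / "v.vcf"
    formats.write_vcf(subset, sim1.hap1, sim1.hap2, str(p))
    assert formats.read_vcf(str(p)) == sort_calls(subset)


# ---------------------------------------------------------------------------
# BED / counts / genetic map


def test_bed_round_trip(tmp_path):
    recs = [("c1", 0, 10, "a"), ("c2", 5, 6, "b")]
    p = tmp_path / "x.bed"
    formats.write_bed(recs, str(p))
    assert formats.read_bed(str(p)) == recs
    assert p.read_text().splitlines()[0] == "c1\t0\t10\ta"  # 0-based half-open


def test_counts_round_trip(tmp_path, sim1):
    p = tmp_path / "c.tsv"
    formats.write_counts(sim1.expression_hap1, str(p))
    again = formats.read_counts(str(p), sim1.expression_hap1.lengths, "hap1")
    assert again.counts.equals(sim1.expression_hap1.counts)


def test_counts_validation():
    df = pd.DataFrame({"leaf:1": [1, -2]}, index=["g1", "g2"])
    with pytest.raises(FormatError, match="non-negative"):
        ExpressionMatrix("hap1", df, pd.Series({"g1": 100.0, "g2": 100.0}))
    df2 = pd.DataFrame({"leaf": [1, 2]}, index=["g1", "g2"])
    with pytest.raises(FormatError, match="tissue:replicate"):
        ExpressionMatrix("hap1", df2, pd.Series({"g1": 100.0, "g2": 100.0}))


def test_genetic_map_round_trip_and_bounds(tmp_path, sim1):
    p = tmp_path / "m.tsv"
    formats.write_genetic_map(sim1.markers, str(p))
    again = formats.read_genetic_map(str(p), sim1.hap1)
    assert [(m.marker_id, m.chrom, m.pos) for m in again] == [
        (m.marker_id, m.chrom, m.pos) for m in sim1.markers
    ]
    assert np.allclose([m.cm for m in again], [m.cm for m in sim1.markers])
    bad = _write(tmp_path, "bad.tsv", "m1\tchr1\t10.0\t99999999\n")
    with pytest.raises(FormatError, match="outside"):
        formats.read_genetic_map(bad, sim1.hap1)
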
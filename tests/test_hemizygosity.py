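import pytest

from phasediv.hemizygosity import (
    call_hemizygous,
    categorize_hemizygous,
    cds_identity,
    summarize_categories,
    summarize_counts,
)
from phasediv.models import GeneModel, HaplotypeGenome, HemizygosityRecord, RegionCall
from phasediv.sequence import random_dna


def simple_gene(gid, hap, chrom, start, end, seq):
    return GeneModel(
        gene_id=gid, haplotype=hap, chrom=chrom, strand="+",
        start=start, end=end, cds=((start, end),), cds_sequence=seq,
    )


def syn_call(chrom, n):
    return RegionCall("SYN", ref_chrom=chrom, ref_start=0, ref_end=n,
                      qry_chrom=chrom, qry_start=0, qry_end=n)


def test_identical_annotations_give_zero_hemizygous(rng):
    seq = random_dna(rng, 5000)
    genes1 = [simple_gene(f"a{i}", "hap1", "c", i * 1000, i * 1000 + 300,
                          seq[i * 1000 : i * 1000 + 300]) for i in range(4)]
    genes2 = [simple_gene(f"b{i}", "hap2", "c", i * 1000, i * 1000 + 300,
                          seq[i * 1000 : i * 1000 + 300]) for i in range(4)]
    r1, r2 = call_hemizygous(genes1, genes2, [syn_call("c", 5000)])
    assert all(r.status == "homozygous" for r in r1 + r2)


def test_partner_below_identity_threshold_is_hemizygous(rng):
    a = random_dna(rng, 300)
    b = random_dna(rng, 300)  # ~25% identity to a
    assert cds_identity(a, b) < 0.5
    g1 = [simple_gene("a", "hap1", "c", 100, 400, a)]
    g2 = [simple_gene("b", "hap2", "c", 100, 400, b)]
    r1, _ = call_hemizygous(g1, g2, [syn_call("c", 1000)])
    assert r1[0].status == "hemizygous"


def test_unknown_chromosome_raises(rng):
    g1 = [simple_gene("a", "hap1", "nowhere", 0, 10, "ACGTACGTAC")]
    with pytest.raises(ValueError, match="unknown chromosome"):
        call_hemizygous(g1, [], [syn_call("c", 100)])


def test_threshold_monotonicity_on_simulation(sim1, calls1):
    counts = []
    for thr in (0.6, 0.8, 0.9, 0.99):
        r1, r2 = call_hemizygous(sim1.genes_hap1, sim1.genes_hap2, calls1, thr)
        counts.append(sum(r.status == "hemizygous" for r in r1 + r2))
    assert counts == sorted(counts)


def test_output_independent_of_gene_input_order(sim1, calls1):
    r1, _ = call_hemizygous(sim1.genes_hap1, sim1.genes_hap2, calls1)
    r1b, _ = call_hemizygous(sim1.genes_hap1[::-1], sim1.genes_hap2[::-1], calls1)
    assert r1 == r1b


def test_hemizygosity_recovery_on_simulation(sim1, calls1):
    r1, r2 = call_hemizygous(sim1.genes_hap1, sim1.genes_hap2, calls1)
    r1 = categorize_hemizygous(r1, sim1.genes_hap1, calls1)
    r2 = categorize_hemizygous(r2, sim1.genes_hap2, calls1)
    for hap, recs in (("hap1", r1), ("hap2", r2)):
        truth = {g for (h, g), v in sim1.truth.hemizygosity.items()
                 if h == hap and v != "homozygous"}
        called = {r.gene_id for r in recs if r.status == "hemizygous"}
        tp = len(truth & called)
        assert tp / len(called) >= 0.95  # precision
        assert tp / len(truth) >= 0.95  # recall
        correct = sum(
            1 for r in recs
            if r.status == "hemizygous" and r.gene_id in truth
            and r.category == sim1.truth.hemizygosity[(hap, r.gene_id)]
        )
        assert correct / len(truth) >= 0.95  # category confusion diagonal


def test_categorize_overlap_rules():
    genes = [
        simple_gene("in_ins", "hap1", "c", 1000, 1400, "A" * 400),
        simple_gene("mostly_hdr", "hap1", "c", 2000, 3000, "A" * 1000),
        simple_gene("nowhere", "hap1", "c", 5000, 5400, "A" * 400),
    ]
    records = [
        HemizygosityRecord(g.gene_id, "hap1", "hemizygous", "unassigned")
        for g in genes
    ]
    calls = [
        RegionCall("DEL", ref_chrom="c", ref_start=900, ref_end=1500,
                   qry_chrom="c", qry_start=900, qry_end=900),
        # covers 60% of mostly_hdr
        RegionCall("HDR", ref_chrom="c", ref_start=2400, ref_end=3600,
                   qry_chrom="c", qry_start=2400, qry_end=3600),
    ]
    out = {r.gene_id: r for r in categorize_hemizygous(records, genes, calls)}
    assert out["in_ins"].category == "insertion"
    assert out["in_ins"].overlap_fraction == 1.0
    assert out["mostly_hdr"].category == "HDR"
    assert out["mostly_hdr"].overlap_fraction == pytest.approx(0.6)
    assert out["nowhere"].category == "unassigned"


def test_category_counts_sum_to_hemizygous_total(sim1, calls1):
    r1, r2 = call_hemizygous(sim1.genes_hap1, sim1.genes_hap2, calls1)
    r1 = categorize_hemizygous(r1, sim1.genes_hap1, calls1)
    summary = summarize_categories(r1)
    s = summary["hap1"]
    assert (
        s["insertion_count"] + s["HDR_count"] + s["unique_count"]
        + s["unassigned_count"] == s["hemizygous_count"]
    )


def test_summary_arithmetic_on_published_scale_counts():
    # counts at the scale of a real ~40k-gene haplotype annotation
    s = summarize_counts(40106, 4863, {"insertion": 2154, "HDR": 2539, "unique": 169})
    assert s["hemizygous_pct"] == 12
    assert s["insertion_pct"] == 44.3
    assert s["HDR_pct"] == 52.2
    s2 = summarize_counts(40223, 4519, {"insertion": 1962, "HDR": 2389, "unique": 167})
    assert s2["hemizygous_pct"] == 11
    assert s2["insertion_pct"] == 43.4
    assert s2["unique_pct"] == 3.7


def test_summary_of_empty_and_zero_hemizygous():
    assert summarize_categories([]) == {}
    recs = [HemizygosityRecord("g1", "hap1", "homozygous")]
    s = summarize_categories(recs)["hap1"]
    assert s["hemizygous_pct"] == 0 and s["insertion_pct"] == 0.0
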
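from collections import Counter


import pytest

from phasediv.models import HaplotypeGenome, RegionCall
from phasediv.sequence import random_dna, revcomp
from phasediv.synteny import (
    ParameterError,
    chain_anchors,
    classify_regions,
    find_anchors,
    region_partition_check,
)


def genome(label, **chroms):
    return HaplotypeGenome(label, dict(chroms))


def brute_force_anchors(ref: HaplotypeGenome, qry: HaplotypeGenome, k: int):
    """Independent oracle: dictionary of canonical k-mer -> occurrences."""

    def table(g):
        t = {}
        for cid, seq in g.chromosomes.items():
            for i in range(len(seq) - k + 1):
                s = seq[i : i + k]
                if "N" in s:
                    continue
                canon = min(s, revcomp(s))
                t.setdefault(canon, []).append((cid, i, s == canon))
        return t

    tr, tq = table(ref), table(qry)
    out = []
    for kmer, occ_r in tr.items():
        occ_q = tq.get(kmer)
        if len(occ_r) == 1 and occ_q is not None and len(occ_q) == 1:
            (rc, rp, rs), (qc, qp, qs) = occ_r[0], occ_q[0]
            out.append((rc, rp, qc, qp, "forward" if rs == qs else "reverse"))
    return sorted(out)


def test_find_anchors_matches_brute_force_oracle(rng):
    seq_a = random_dna(rng, 400)
    seq_b = random_dna(rng, 300)
    # qry shares a 150 bp block of ref, reversed elsewhere
    qry_seq = seq_b[:100] + seq_a[50:200] + revcomp(seq_a[250:350])
    ref = genome("hap1", c1=seq_a, c2=seq_b)
    qry = genome("hap2", cq=qry_seq)
    got = sorted(
        (a.ref_chrom, a.ref_pos, a.qry_chrom, a.qry_pos, a.orientation)
        for a in find_anchors(ref, qry, k=21)
    )
    assert got == brute_force_anchors(ref, qry, 21)


def test_identical_200bp_sequences_give_170_forward_anchors(rng):
    seq = random_dna(rng, 200)
    anchors = find_anchors(genome("hap1", c=seq), genome("hap2", c=seq), k=31)
    assert len(anchors) == 170
    assert all(a.orientation == "forward" and a.ref_pos == a.qry_pos for a in anchors)


def test_reverse_complement_genome_gives_reverse_anchors(rng):
    seq = random_dna(rng, 200)
    anchors = find_anchors(genome("hap1", c=seq), genome("hap2", c=revcomp(seq)), k=31)
    assert len(anchors) == 170
    assert all(a.orientation == "reverse" for a in anchors)


def test_degenerate_repeat_has_no_anchors():
    anchors = find_anchors(genome("hap1", c="A" * 200), genome("hap2", c="A" * 200))
    assert len(anchors) == 0


def test_anchors_never_span_n(rng):
    seq = random_dna(rng, 100) + "N" + random_dna(rng, 100)
    anchors = find_anchors(genome("hap1", c=seq), genome("hap2", c=seq), k=31)
    for a in anchors:
        assert "N" not in seq[a.ref_pos : a.ref_pos + 31]


@pytest.mark.parametrize("k", [10, 9, 65, 32])
def test_k_out_of_range_rejected(rng, k):
    g = genome("hap1", c=random_dna(rng, 100))
    with pytest.raises(ParameterError):
        find_anchors(g, g, k=k)


def test_collinear_identical_genomes_chain_per_chromosome(rng):
    g1 = genome("hap1", c1=random_dna(rng, 2000), c2=random_dna(rng, 2000))
    g2 = HaplotypeGenome("hap2", dict(g1.chromosomes))
    chains = chain_anchors(find_anchors(g1, g2))
    assert len(chains) == 2
    # oracle: each chain must contain every anchor of its chromosome
    assert sorted(c.n_anchors for c in chains) == [2000 - 31 + 1] * 2


def test_planted_inversion_breaks_into_three_chains(rng):
    seq = random_dna(rng, 30_000)
    inv = seq[:10_000] + revcomp(seq[10_000:20_000]) + seq[20_000:]
    chains = chain_anchors(find_anchors(genome("hap1", c=seq), genome("hap2", c=inv)))
    orientations = [c.forward for c in chains]
    assert len(chains) >= 3
    assert orientations[0] and not orientations[1] and orientations[-1]


def test_chains_below_minimum_anchor_count_are_discarded():
    anchors = find_anchors(
        genome("hap1", c="A" * 50), genome("hap2", c="A" * 50)
    )
    assert chain_anchors(anchors, min_chain_anchors=3) == []


def test_identical_genomes_classify_as_single_syn_no_snps(rng):
    seq = random_dna(rng, 5000)
    g1, g2 = genome("hap1", c=seq), genome("hap2", c=seq)
    calls = classify_regions(chain_anchors(find_anchors(g1, g2)), g1, g2)
    by_type = Counter(c.rtype for c in calls)
    assert by_type["SNP"] == 0
    assert by_type["SYN"] == 1


def test_single_snp_called_at_truth_position(rng):
    seq = random_dna(rng, 5000)
    pos = 2500
    alt = "A" if seq[pos] != "A" else "C"
    mutated = seq[:pos] + alt + seq[pos + 1 :]
    g1, g2 = genome("hap1", c=seq), genome("hap2", c=mutated)
    calls = classify_regions(chain_anchors(find_anchors(g1, g2)), g1, g2)
    snps = [c for c in calls if c.rtype == "SNP"]
    assert len(snps) == 1
    assert (snps[0].ref_start, snps[0].ref_base, snps[0].qry_base) == (pos, seq[pos], alt)


def test_ref_qry_swap_symmetry(rng):
    seq = random_dna(rng, 20_000)
    # one deletion, one insertion, a few SNPs
    other = seq[:4000] + seq[4300:]  # 300 bp deletion
    other = other[:9000] + random_dna(rng, 200) + other[9000:]  # 200 bp insertion
    for p in (12_000, 15_000):
        alt = "A" if other[p] != "A" else "C"
        other = other[:p] + alt + other[p + 1 :]
    g1, g2 = genome("hap1", c=seq), genome("hap2", c=other)
    fwd = classify_regions(chain_anchors(find_anchors(g1, g2)), g1, g2)
    g1s = HaplotypeGenome("hap1", {"c": other})
    g2s = HaplotypeGenome("hap2", {"c": seq})
    rev = classify_regions(chain_anchors(find_anchors(g1s, g2s)), g1s, g2s)
    cf, cr = Counter(c.rtype for c in fwd), Counter(c.rtype for c in rev)
    assert cf["SNP"] == cr["SNP"] == 2
    assert cf["INS"] == cr["DEL"] and cf["DEL"] == cr["INS"]
    # intervals transpose
    fwd_del = [(c.ref_start, c.ref_end) for c in fwd if c.rtype == "DEL"]
    rev_ins = [(c.qry_start, c.qry_end) for c in rev if c.rtype == "INS"]
    assert fwd_del == rev_ins


def test_partition_check_reports_injected_defects(sim1, calls1):
    report = region_partition_check(calls1, sim1.hap1, sim1.hap2)
    assert report.ok
    # remove a covering region -> uncovered
    victim = next(i for i, c in enumerate(calls1) if c.rtype == "DEL" and c.ref_len > 100)
    broken = calls1[:victim] + calls1[victim + 1 :]
    rep2 = region_partition_check(broken, sim1.hap1, sim1.hap2)
    assert rep2.total_uncovered("hap1") == calls1[victim].ref_len
    # duplicate a call -> overlap
    dup = calls1 + [calls1[victim]]
    rep3 = region_partition_check(dup, sim1.hap1, sim1.hap2)
    assert rep3.total_overlapped("hap1") == calls1[victim].ref_len


def test_partition_check_excludes_n_runs():
    seq = "ACGTACGTAC" * 10
    g1 = genome("hap1", c=seq + "N" * 20 + seq)
    g2 = genome("hap2", c=seq + "N" * 20 + seq)
    calls = [RegionCall("SYN", ref_chrom="c", ref_start=0, ref_end=100,
                        qry_chrom="c", qry_start=0, qry_end=100),
             RegionCall("SYN", ref_chrom="c", ref_start=120, ref_end=220,
                        qry_chrom="c", qry_start=120, qry_end=220)]
    report = region_partition_check(calls, g1, g2)
    assert report.ok  # the N gap between the two calls is not a defect
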
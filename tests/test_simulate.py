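import numpy as np
import pytest


from phasediv.sequence import revcomp
from phasediv.simulate import (
    ConfigurationError,
    Event,
    SimTruth,
    SimulationConfig,
    apply_edit_script,
    draw_nb_counts,
    simulate_diploid,
)


def quiet_config(**kw):
    base = dict(
        seed=0, n_chromosomes=1, chromosome_length=60_000,
        snp_rate=0.0, n_insertions=0, n_deletions=0, n_inversions=0,
        n_translocations=0, n_hdrs=0, n_unique_segments=0,
        genes_per_chromosome=10, hemizygous_fraction=0.0,
        n_identical_pairs=5, n_de_pairs=0, n_map_markers=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_no_edit_config_yields_identical_haplotypes():
    ds = simulate_diploid(quiet_config())
    assert ds.hap1.chromosomes == ds.hap2.chromosomes


def test_fixed_seed_is_byte_identical():
    a = simulate_diploid(SimulationConfig(seed=3))
    b = simulate_diploid(SimulationConfig(seed=3))
    assert a.hap1.chromosomes == b.hap1.chromosomes
    assert a.hap2.chromosomes == b.hap2.chromosomes
    assert a.expression_hap1.counts.equals(b.expression_hap1.counts)
    assert a.truth.identical_pairs == b.truth.identical_pairs
    assert [m.cm for m in a.markers] == [m.cm for m in b.markers]


def test_single_insertion_length_bookkeeping():
    # length difference oracle over the edit script
    ds = simulate_diploid(quiet_config(n_insertions=1, sv_len_range=(100, 100)))
    ins = [e for evs in ds.truth.events.values() for e in evs if e.kind == "insertion"]
    assert len(ins) == 1
    assert ds.hap2.total_length - ds.hap1.total_length == len(ins[0].alt)


def test_net_length_matches_edit_script(sim1):
    net = 0
    for evs in sim1.truth.events.values():
        for e in evs:
            if e.kind in ("insertion", "unique_hap2", "trans_dst"):
                net += len(e.alt)
            elif e.kind in ("deletion", "unique_hap1", "translocation"):
                net -= e.length
    assert sim1.hap2.total_length - sim1.hap1.total_length == net


def test_apply_edit_script_reproduces_hap2(sim1):
    rebuilt = apply_edit_script(sim1.hap1, sim1.truth)
    assert rebuilt.chromosomes == sim1.hap2.chromosomes


def test_apply_edit_script_primitives():
    ds = simulate_diploid(quiet_config())
    genome = ds.hap1
    cid = next(iter(genome.chromosomes))
    empty = SimTruth(ds.truth.config, {cid: []}, [], {}, [], [], {}, {})
    assert apply_edit_script(genome, empty).chromosomes == genome.chromosomes
    ref_base = genome.chromosomes[cid][1000]
    alt = "A" if ref_base != "A" else "G"
    snp = SimTruth(ds.truth.config, {cid: [Event("snp", cid, 1000, 1001, alt=alt)]},
                   [], {}, [], [], {}, {})
    mutated = apply_edit_script(genome, snp)
    diffs = [i for i, (a, b) in enumerate(zip(genome.chromosomes[cid],
                                              mutated.chromosomes[cid])) if a != b]
    assert diffs == [1000]
    inv = SimTruth(ds.truth.config, {cid: [Event("inversion", cid, 2000, 3000)]},
                   [], {}, [], [], {}, {})
    inverted = apply_edit_script(genome, inv)
    assert inverted.chromosomes[cid][2000:3000] == revcomp(genome.chromosomes[cid][2000:3000])


def test_overlapping_edits_rejected():
    ds = simulate_diploid(quiet_config())
    cid = next(iter(ds.hap1.chromosomes))
    bad = SimTruth(ds.truth.config, {cid: [Event("deletion", cid, 1000, 2000),
                                           Event("deletion", cid, 1500, 2500)]},
                   [], {}, [], [], {}, {})
    with pytest.raises(ConfigurationError, match="overlapping"):
        apply_edit_script(ds.hap1, bad)


def test_truth_regions_partition_non_telomeric_bases(sim1):
    tel = sim1.truth.config.telomere_array_copies * 7
    for hap, genome in (("hap1", sim1.hap1), ("hap2", sim1.hap2)):
        for cid, seq in genome.chromosomes.items():
            cov = np.zeros(len(seq), dtype=np.int16)
            for r in sim1.truth.regions:
                if r.rtype == "SNP":
                    continue
                iv = r.interval(hap)
                if iv and iv[0] == cid:
                    cov[iv[1]:iv[2]] += 1
            assert (cov[tel:-tel] == 1).all(), (hap, cid)


def test_hemizygous_truth_genes_lie_in_their_region_class(sim1):
    regions = sim1.truth.regions
    genes = {("hap1", g.gene_id): g for g in sim1.genes_hap1}
    genes.update({("hap2", g.gene_id): g for g in sim1.genes_hap2})
    want = {"insertion": {"hap1": "DEL", "hap2": "INS"},
            "HDR": {"hap1": "HDR", "hap2": "HDR"},
            "unique": {"hap1": "NOTAL", "hap2": "NOTAL"}}
    for (hap, gid), cat in sim1.truth.hemizygosity.items():
        if cat == "homozygous":
            continue
        g = genes[(hap, gid)]
        rtype = want[cat][hap]
        inside = any(
            r.rtype == rtype
            and (iv := r.interval(hap)) is not None
            and iv[0] == g.chrom and iv[1] <= g.start and g.end <= iv[2]
            for r in regions
        )
        assert inside, (hap, gid, cat)


def test_telomere_arrays_cap_every_chromosome(sim1):
    copies = sim1.truth.config.telomere_array_copies
    for genome in (sim1.hap1, sim1.hap2):
        for seq in genome.chromosomes.values():
            assert seq.startswith(revcomp("TTTAGGG") * copies)
            assert seq.endswith("TTTAGGG" * copies)


def test_identical_pairs_are_byte_equal_and_others_differ(sim1):
    g1 = {g.gene_id: g for g in sim1.genes_hap1}
    g2 = {g.gene_id: g for g in sim1.genes_hap2}
    ident = set(sim1.truth.identical_pairs)
    for a, b in sim1.truth.pairs:
        if (a, b) in ident:
            assert g1[a].cds_sequence == g2[b].cds_sequence
        else:
            assert g1[a].cds_sequence != g2[b].cds_sequence


def test_nb_counts_mean_accuracy():
    # stochastic tolerance: 200 replicates within 5% of the configured mean
    rng = np.random.default_rng(123)
    for mean in (50.0, 200.0, 1000.0):
        draws = draw_nb_counts(rng, mean, dispersion=0.1, size=200)
        assert abs(draws.mean() - mean) / mean < 0.05


def test_infeasible_packing_raises_configuration_error():
    with pytest.raises(ConfigurationError, match="packing|span"):
        simulate_diploid(SimulationConfig(
            seed=0, n_chromosomes=1, chromosome_length=30_000,
            n_inversions=4, inversion_len_range=(20_000, 25_000),
            n_translocations=0,
        ))


def test_de_truth_promoters_carry_extra_variants(sim1):
    de_h1 = {a for a, _ in sim1.truth.de_truth}
    pv = sim1.truth.promoter_variants
    de_mean = np.mean([pv[g] for g in de_h1])
    bg_mean = np.mean([v for g, v in pv.items() if g not in de_h1])
    assert de_mean >= bg_mean + 0.5 * sim1.truth.config.de_promoter_snps
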
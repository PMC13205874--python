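"""Synthetic phased diploid genome with planted truth.

The simulator emulates the structure a haplotype-resolved assembly
comparison assumes: hap-2 is derived from hap-1 by an explicit edit script
(SNPs, insertions, deletions, inversions, cut-and-paste translocations,
highly-diverged-region resequencing and haplotype-unique segments), genes
are planted with known hemizygosity categories, telomeric TTTAGGG arrays
cap every chromosome, genetic-map markers are monotone in cM along bp, and
expression counts are negative-binomial with cis effects tied to planted
promoter variants.

hap-2 is only ever produced by applying the edit script, so the emitted
truth is exact by construction.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    ExpressionMatrix,
    GeneModel,
    GeneticMapMarker,
    HaplotypeGenome,
    RegionCall,
    TISSUES,
    sort_calls,
)
from .sequence import random_dna, revcomp, spliced_cds

TELOMERE_MOTIF = "TTTAGGG"


class ConfigurationError(ValueError):
    """Infeasible simulation configuration (e.g. intervals cannot be packed)."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated phased diploid dataset.

    Counts and rates are scaled-down analogues of a ~300 Mb heterozygous
    allotetraploid haplotype pair (SNP rate ~0.005/bp, ~12% hemizygous
    genes split ~44:52:4 between insertion-, HDR- and unique-resident).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    snp_rate: float = 0.005
    n_insertions: int = 40
    n_deletions: int = 40
    sv_len_range: tuple[int, int] = (50, 5000)  # log-uniform
    n_inversions: int = 2
    inversion_len_range: tuple[int, int] = (5000, 50_000)
    n_translocations: int = 1
    translocation_len_range: tuple[int, int] = (5000, 20_000)
    n_hdrs: int = 6
    hdr_len_range: tuple[int, int] = (2000, 20_000)
    hdr_identity_range: tuple[float, float] = (0.6, 0.8)
    n_unique_segments: int = 2  # per haplotype
    unique_len_range: tuple[int, int] = (3000, 10_000)
    genes_per_chromosome: int = 120
    hemizygous_fraction: float = 0.12
    category_weights: tuple[float, float, float] = (0.44, 0.52, 0.04)
    n_identical_pairs: int = 60
    n_de_pairs: int = 12
    de_promoter_snps: int = 10
    promoter_window: int = 3000
    replicates_per_tissue: int = 3
    nb_dispersion: float = 0.1
    cis_effect_fold: float = 4.0
    hemizygous_expression_boost: float = 2.0
    telomere_array_copies: int = 30
    n_map_markers: int = 30

    def validate(self) -> None:
        for name in (
            "n_chromosomes", "chromosome_length", "n_insertions", "n_deletions",
            "n_inversions", "n_translocations", "n_hdrs", "n_unique_segments",
            "genes_per_chromosome", "n_identical_pairs", "n_de_pairs",
            "de_promoter_snps", "replicates_per_tissue", "telomere_array_copies",
            "n_map_markers", "promoter_window",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.hemizygous_fraction <= 1.0:
            raise ConfigurationError("hemizygous_fraction outside [0, 1]")
        if self.n_translocations > 0 and self.n_chromosomes < 2:
            raise ConfigurationError("translocations require >= 2 chromosomes")
        if self.n_de_pairs > self.n_identical_pairs:
            raise ConfigurationError("n_de_pairs cannot exceed n_identical_pairs")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if any(w < 0 for w in self.category_weights) or sum(self.category_weights) == 0:
            raise ConfigurationError("category_weights must be non-negative, not all zero")


@dataclass
class Event:
    """One planted edit, in hap-1 coordinates (``start == end`` = breakpoint).

    Kinds: snp, deletion, insertion, inversion, hdr, translocation,
    trans_dst (destination half of a translocation), unique_hap1,
    unique_hap2.
    """

    kind: str
    chrom: str
    start: int
    end: int
    alt: str = ""  # SNP alt base / inserted payload / HDR replacement
    link: int = -1  # translocation id tying src and dst halves

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimTruth:
    """Planted truth emitted alongside a simulated dataset."""

    config: SimulationConfig
    events: dict[str, list[Event]]
    regions: list[RegionCall]
    hemizygosity: dict[tuple[str, str], str]  # (haplotype, gene_id) -> category
    pairs: list[tuple[str, str]]
    identical_pairs: list[tuple[str, str]]
    de_truth: dict[tuple[str, str], dict[str, float]]  # pair -> tissue -> hap1/hap2 fold
    promoter_variants: dict[str, int]
    body_spans: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    hap1: HaplotypeGenome
    hap2: HaplotypeGenome
    genes_hap1: list[GeneModel]
    genes_hap2: list[GeneModel]
    expression_hap1: ExpressionMatrix
    expression_hap2: ExpressionMatrix
    markers: list[GeneticMapMarker]
    truth: SimTruth


# ---------------------------------------------------------------------------
# low-level helpers


def _log_uniform_int(rng, lo: int, hi: int) -> int:
    if hi <= lo:
        return lo
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


class _Placer:
    """Non-overlapping interval placement with a separation buffer."""

    def __init__(self, lo: int, hi: int, buffer: int):
        self.lo, self.hi, self.buffer = lo, hi, buffer
        self.starts: list[int] = []
        self.ends: list[int] = []

    def _fits(self, s: int, e: int) -> bool:
        i = bisect.bisect_left(self.starts, s)
        if i > 0 and self.ends[i - 1] + self.buffer > s:
            return False
        if i < len(self.starts) and e + self.buffer > self.starts[i]:
            return False
        return True

    def occupy(self, s: int, e: int) -> None:
        i = bisect.bisect_left(self.starts, s)
        self.starts.insert(i, s)
        self.ends.insert(i, e)

    def place(self, rng, length: int, tries: int = 500) -> tuple[int, int]:
        span = self.hi - self.lo - length
        if span <= 0:
            raise ConfigurationError(
                "infeasible packing: event longer than available span; "
                "reduce event counts or lengths"
            )
        for _ in range(tries):
            s = int(rng.integers(self.lo, self.lo + span + 1))
            if self._fits(s, s + length):
                self.occupy(s, s + length)
                return s, s + length
        raise ConfigurationError(
            "infeasible packing: could not place all intervals; "
            "reduce event counts or lengths"
        )


def _resequence(rng, seq: str, identity: float) -> str:
    """Substitute a (1 - identity) fraction of bases; no indels."""
    n = len(seq)
    m = int(round((1.0 - identity) * n))
    pos = rng.choice(n, size=min(m, n), replace=False)
    out = list(seq)
    bases = "ACGT"
    for p in pos:
        cur = out[p]
        choices = [b for b in bases if b != cur]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def draw_nb_counts(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts with Var = mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# edit-script application (single source of truth for hap-2)


def _walk(seq: str, events: list[Event]):
    """Apply one chromosome's events; return (hap2_seq, qry info, identity map).

    ``qry_info[i]`` is the qry-side (hap-2) coordinate footprint of
    ``events[i]``: a breakpoint position for removals, an interval for
    everything that leaves sequence.  ``identity_map`` is a list of
    (h1_start, h1_end, delta) stretches where hap-2 equals hap-1 coordinates
    plus delta (copied runs, SNP positions and same-length HDR blocks).
    """
    pieces: list[str] = []
    qlen = 0
    prev = 0
    seg_start = 0
    qry_info: list[tuple[int, int]] = []
    identity_map: list[tuple[int, int, int]] = []
    for ev in events:
        if ev.start < prev:
            raise ConfigurationError(f"overlapping edits at {ev.chrom}:{ev.start}")
        pieces.append(seq[prev:ev.start])
        qlen += ev.start - prev
        delta = qlen - ev.start
        if ev.kind == "snp":
            if seq[ev.start] == ev.alt:
                raise ConfigurationError("SNP alt equals ref")
            pieces.append(ev.alt)
            qlen += 1
            qry_info.append((qlen - 1, qlen))
            prev = ev.end
            continue
        if ev.start > seg_start:
            identity_map.append((seg_start, ev.start, delta))
        if ev.kind in ("deletion", "unique_hap1", "translocation"):
            qry_info.append((qlen, qlen))
        elif ev.kind in ("insertion", "unique_hap2", "trans_dst"):
            pieces.append(ev.alt)
            qry_info.append((qlen, qlen + len(ev.alt)))
            qlen += len(ev.alt)
        elif ev.kind == "inversion":
            pieces.append(revcomp(seq[ev.start:ev.end]))
            qry_info.append((qlen, qlen + ev.length))
            qlen += ev.length
        elif ev.kind == "hdr":
            if len(ev.alt) != ev.length:
                raise ConfigurationError("HDR replacement length mismatch")
            pieces.append(ev.alt)
            qry_info.append((qlen, qlen + ev.length))
            identity_map.append((ev.start, ev.end, delta))
            qlen += ev.length
        else:
            raise ConfigurationError(f"unknown event kind {ev.kind!r}")
        prev = ev.end
        seg_start = ev.end
    delta = qlen - prev
    pieces.append(seq[prev:])
    if len(seq) > seg_start:
        identity_map.append((seg_start, len(seq), delta))
    return "".join(pieces), qry_info, identity_map


def apply_edit_script(genome: HaplotypeGenome, truth: SimTruth) -> HaplotypeGenome:
    """Reproduce hap-2 from hap-1 and the planted edit script."""
    chroms: dict[str, str] = {}
    for cid, seq in genome.chromosomes.items():
        hap2_seq, _, _ = _walk(seq, truth.events.get(cid, []))
        chroms[cid] = hap2_seq
    return HaplotypeGenome(label="hap2", chromosomes=chroms)


def _lift(identity_map: list[tuple[int, int, int]], s: int, e: int) -> tuple[int, int]:
    for a, b, d in identity_map:
        if a <= s and e <= b:
            return s + d, e + d
    raise ConfigurationError(f"interval ({s},{e}) crosses an edit boundary")


# ---------------------------------------------------------------------------
# gene structure


@dataclass
class _PlannedGene:
    gene_id: str
    chrom: str
    start: int  # hap1 coords, or payload-relative for payload genes
    end: int
    strand: str
    cds: tuple[tuple[int, int], ...]
    haplotype: str  # which haplotype carries it ('both' for homozygous)
    category: str  # homozygous | insertion | HDR | unique
    pair_serial: int = -1
    payload_event: "Event | None" = None  # hosting insertion/unique_hap2 event


def _gene_structure(rng, gs: int, ge: int) -> tuple[str, tuple[tuple[int, int], ...]]:
    strand = "+" if rng.random() < 0.5 else "-"
    span = ge - gs
    utr5 = int(rng.integers(30, min(120, max(31, span // 6))))
    utr3 = int(rng.integers(30, min(120, max(31, span // 6))))
    a, b = gs + utr5, ge - utr3
    if b - a < 150:
        a, b = gs + 10, ge - 10
    if rng.random() < 0.4 or b - a < 400:
        cds = ((a, b),)
    else:
        intron = int(rng.integers(60, max(61, (b - a) // 5)))
        ex1 = (b - a - intron) // 2
        cds = ((a, a + ex1), (a + ex1 + intron, b))
    return strand, cds


# ---------------------------------------------------------------------------
# the simulator


def simulate_diploid(config: SimulationConfig) -> SimulatedDataset:
    """Generate a phased diploid dataset with complete planted truth.

    Deterministic under a fixed seed; each stage draws from its own
    sub-stream of the seed so adding a later stage never perturbs an
    earlier one.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_seq, rng_ev, rng_gene, rng_snp, rng_expr, rng_map = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    tel = config.telomere_array_copies * len(TELOMERE_MOTIF)
    tel_left = revcomp(TELOMERE_MOTIF) * config.telomere_array_copies
    tel_right = TELOMERE_MOTIF * config.telomere_array_copies
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    L = config.chromosome_length
    body = {cid: (tel, tel + L) for cid in chrom_ids}

    hap1_chroms = {cid: tel_left + random_dna(rng_seq, L) + tel_right for cid in chrom_ids}

    # ----- per-chromosome gene plan ------------------------------------
    w = np.asarray(config.category_weights, dtype=float)
    w = w / w.sum()
    n_hemi = int(round(config.genes_per_chromosome * config.hemizygous_fraction))
    n_ins_res = int(round(n_hemi * w[0]))
    n_uniq_res = int(round(n_hemi * w[2])) if n_hemi else 0
    n_ins_res = min(n_ins_res, n_hemi)
    n_uniq_res = min(n_uniq_res, n_hemi - n_ins_res)
    n_hdr_res = n_hemi - n_ins_res - n_uniq_res
    n_homo = config.genes_per_chromosome - n_hemi

    # ----- event planning ----------------------------------------------
    events: dict[str, list[Event]] = {cid: [] for cid in chrom_ids}
    edge = 1500
    buffer = 600
    reserved_right = {cid: 0 for cid in chrom_ids}

    # hap1-unique segments flush against the right telomere
    uniq1_by_chrom: dict[str, list[tuple[int, int]]] = {cid: [] for cid in chrom_ids}
    for i in range(config.n_unique_segments):
        cid = chrom_ids[i % len(chrom_ids)]
        lu = _log_uniform_int(rng_ev, *config.unique_len_range)
        e = body[cid][1] - reserved_right[cid]
        s = e - lu
        events[cid].append(Event("unique_hap1", cid, s, e))
        uniq1_by_chrom[cid].append((s, e))
        reserved_right[cid] += lu
    # hap2-unique payloads right after the left telomere
    uniq2_by_chrom: dict[str, list[Event]] = {cid: [] for cid in chrom_ids}
    for i in range(config.n_unique_segments):
        cid = chrom_ids[i % len(chrom_ids)]
        lu = _log_uniform_int(rng_ev, *config.unique_len_range)
        ev = Event("unique_hap2", cid, body[cid][0], body[cid][0],
                   alt=random_dna(rng_ev, lu))
        events[cid].append(ev)
        uniq2_by_chrom[cid].append(ev)

    placers = {
        cid: _Placer(body[cid][0] + edge, body[cid][1] - edge - reserved_right[cid], buffer)
        for cid in chrom_ids
    }

    def rr(i: int) -> str:  # round-robin chromosome assignment
        return chrom_ids[i % len(chrom_ids)]

    host_len_lo = max(1800, config.sv_len_range[0])
    host_len_hi = max(host_len_lo + 1, config.sv_len_range[1])

    for i in range(config.n_inversions):
        cid = rr(i)
        ln = _log_uniform_int(rng_ev, *config.inversion_len_range)
        s, e = placers[cid].place(rng_ev, ln)
        events[cid].append(Event("inversion", cid, s, e))

    for i in range(config.n_translocations):
        src = chrom_ids[int(rng_ev.integers(0, len(chrom_ids)))]
        others = [c for c in chrom_ids if c != src]
        dst = others[int(rng_ev.integers(0, len(others)))]
        ln = _log_uniform_int(rng_ev, *config.translocation_len_range)
        s, e = placers[src].place(rng_ev, ln)
        p, _ = placers[dst].place(rng_ev, 0)
        events[src].append(Event("translocation", src, s, e, link=i))
        events[dst].append(Event("trans_dst", dst, p, p, alt=hap1_chroms[src][s:e], link=i))

    # HDRs, with capacity inflation so planned HDR-resident genes fit
    slot = 1500
    hdr_margin = 300
    hdrs_by_chrom: dict[str, list[int]] = {cid: [] for cid in chrom_ids}
    hdr_lens: dict[str, list[int]] = {cid: [] for cid in chrom_ids}
    for i in range(config.n_hdrs):
        cid = rr(i)
        hdr_lens[cid].append(_log_uniform_int(rng_ev, *config.hdr_len_range))
    for cid in chrom_ids:
        need = 2 * n_hdr_res  # hap1- and hap2-resident genes on this chromosome
        lens = hdr_lens[cid]
        if lens:
            def capacity(ls):
                return sum(max(0, (l - 2 * hdr_margin) // slot) for l in ls)
            guard = 0
            while capacity(lens) < need and guard < 1000:
                j = int(np.argmax(lens))
                if lens[j] + slot > config.hdr_len_range[1] and all(
                    l + slot > config.hdr_len_range[1] for l in lens
                ):
                    break
                if lens[j] + slot > config.hdr_len_range[1]:
                    j = int(np.argmin(lens))
                lens[j] += slot
                guard += 1
        for ln in lens:
            s, e = placers[cid].place(rng_ev, ln)
            ident = rng_ev.uniform(*config.hdr_identity_range)
            events[cid].append(
                Event("hdr", cid, s, e, alt=_resequence(rng_ev, hap1_chroms[cid][s:e], ident))
            )
            hdrs_by_chrom[cid].append(len(events[cid]) - 1)

    # deletions (hap-1-only sequence; hosts for hap-1 insertion-resident genes)
    n_del_hosts = min(config.n_deletions, n_ins_res * len(chrom_ids))
    host_dels: dict[str, list[int]] = {cid: [] for cid in chrom_ids}
    for i in range(config.n_deletions):
        if i < n_del_hosts:
            cid = rr(i)
            ln = _log_uniform_int(rng_ev, host_len_lo, host_len_hi)
        else:
            cid = rr(i)
            ln = _log_uniform_int(rng_ev, *config.sv_len_range)
        s, e = placers[cid].place(rng_ev, ln)
        events[cid].append(Event("deletion", cid, s, e))
        if i < n_del_hosts:
            host_dels[cid].append(len(events[cid]) - 1)

    # insertions (hap-2 extra sequence; hosts for hap-2 insertion-resident genes)
    n_ins_hosts = min(config.n_insertions, n_ins_res * len(chrom_ids))
    host_inss: dict[str, list[int]] = {cid: [] for cid in chrom_ids}
    for i in range(config.n_insertions):
        if i < n_ins_hosts:
            cid = rr(i)
            ln = _log_uniform_int(rng_ev, host_len_lo, host_len_hi)
        else:
            cid = rr(i)
            ln = _log_uniform_int(rng_ev, *config.sv_len_range)
        p, _ = placers[cid].place(rng_ev, 0)
        events[cid].append(Event("insertion", cid, p, p, alt=random_dna(rng_ev, ln)))
        if i < n_ins_hosts:
            host_inss[cid].append(len(events[cid]) - 1)

    # ----- gene planning -------------------------------------------------
    genes: list[_PlannedGene] = []
    serial_specific = {"hap1": 0, "hap2": 0}
    pair_serial = 0

    def new_specific_id(hap: str) -> str:
        serial_specific[hap] += 1
        return f"{'h1' if hap == 'hap1' else 'h2'}s{serial_specific[hap]:04d}"

    for cid in chrom_ids:
        ev_list = events[cid]
        # hap-1 insertion-resident genes inside hosting deletions
        for j in range(n_ins_res):
            hosts = host_dels[cid]
            if j >= len(hosts):
                break
            s, e = ev_list[hosts[j]].start, ev_list[hosts[j]].end
            glen = int(rng_gene.integers(400, max(401, min(1200, e - s - 500)) + 1))
            gs = int(rng_gene.integers(s + 250, e - 250 - glen + 1))
            strand, cds = _gene_structure(rng_gene, gs, gs + glen)
            genes.append(_PlannedGene(new_specific_id("hap1"), cid, gs, gs + glen,
                                      strand, cds, "hap1", "insertion"))
        # hap-2 insertion-resident genes inside hosting insertion payloads
        for j in range(n_ins_res):
            hosts = host_inss[cid]
            if j >= len(hosts):
                break
            ev = ev_list[hosts[j]]
            plen = len(ev.alt)
            glen = int(rng_gene.integers(400, max(401, min(1200, plen - 500)) + 1))
            gs = int(rng_gene.integers(250, plen - 250 - glen + 1))
            strand, cds = _gene_structure(rng_gene, gs, gs + glen)
            genes.append(_PlannedGene(new_specific_id("hap2"), cid, gs, gs + glen,
                                      strand, cds, "hap2", "insertion",
                                      payload_event=ev))
        # HDR-resident genes, alternating haplotype across slots
        slots: list[tuple[int, int]] = []
        for hi in hdrs_by_chrom[cid]:
            s, e = ev_list[hi].start, ev_list[hi].end
            nslots = max(0, (e - s - 2 * hdr_margin) // slot)
            for k in range(nslots):
                a = s + hdr_margin + k * slot
                slots.append((a, a + slot))
        placed_h1 = placed_h2 = 0
        for idx, (a, b) in enumerate(slots):
            if placed_h1 >= n_hdr_res and placed_h2 >= n_hdr_res:
                break
            hap = "hap1" if (idx % 2 == 0 and placed_h1 < n_hdr_res) or placed_h2 >= n_hdr_res else "hap2"
            glen = int(rng_gene.integers(500, 1201))
            gs = a + int(rng_gene.integers(0, b - a - glen + 1))
            strand, cds = _gene_structure(rng_gene, gs, gs + glen)
            genes.append(_PlannedGene(new_specific_id(hap), cid, gs, gs + glen,
                                      strand, cds, hap, "HDR"))
            if hap == "hap1":
                placed_h1 += 1
            else:
                placed_h2 += 1
        # unique-resident genes
        for j, (s, e) in enumerate(uniq1_by_chrom[cid][:n_uniq_res]):
            glen = int(rng_gene.integers(400, max(401, min(1200, e - s - 600)) + 1))
            gs = int(rng_gene.integers(s + 300, e - 300 - glen + 1))
            strand, cds = _gene_structure(rng_gene, gs, gs + glen)
            genes.append(_PlannedGene(new_specific_id("hap1"), cid, gs, gs + glen,
                                      strand, cds, "hap1", "unique"))
        for j, ev in enumerate(uniq2_by_chrom[cid][:n_uniq_res]):
            plen = len(ev.alt)
            glen = int(rng_gene.integers(400, max(401, min(1200, plen - 600)) + 1))
            gs = int(rng_gene.integers(300, plen - 300 - glen + 1))
            strand, cds = _gene_structure(rng_gene, gs, gs + glen)
            genes.append(_PlannedGene(new_specific_id("hap2"), cid, gs, gs + glen,
                                      strand, cds, "hap2", "unique", payload_event=ev))
        # homozygous genes in the free (syntenic) space
        occupied = sorted(
            [(ev.start - buffer // 2, ev.end + buffer // 2) for ev in ev_list]
        )
        free: list[tuple[int, int]] = []
        cur = body[cid][0] + 300
        stop = body[cid][1] - reserved_right[cid] - 300
        for s, e in occupied:
            if s > cur:
                free.append((cur, min(s, stop)))
            cur = max(cur, e)
            if cur >= stop:
                break
        if cur < stop:
            free.append((cur, stop))
        free = [(a, b) for a, b in free if b - a > 1000]
        gene_placer_starts: list[int] = []
        gene_placer_ends: list[int] = []

        def gene_fits(s, e):
            i = bisect.bisect_left(gene_placer_starts, s)
            if i > 0 and gene_placer_ends[i - 1] + 200 > s:
                return False
            if i < len(gene_placer_starts) and e + 200 > gene_placer_starts[i]:
                return False
            return True

        flens = np.array([b - a for a, b in free], dtype=float)
        placed = 0
        attempts = 0
        while placed < n_homo and attempts < n_homo * 400:
            attempts += 1
            glen = int(rng_gene.integers(600, 1801))
            fi = int(rng_gene.choice(len(free), p=flens / flens.sum()))
            a, b = free[fi]
            if b - a < glen + 2:
                continue
            gs = int(rng_gene.integers(a, b - glen))
            if not gene_fits(gs, gs + glen):
                continue
            i = bisect.bisect_left(gene_placer_starts, gs)
            gene_placer_starts.insert(i, gs)
            gene_placer_ends.insert(i, gs + glen)
            pair_serial += 1
            strand, cds = _gene_structure(rng_gene, gs, gs + glen)
            genes.append(_PlannedGene(f"g{pair_serial:04d}", cid, gs, gs + glen,
                                      strand, cds, "both", "homozygous",
                                      pair_serial=pair_serial))
            placed += 1
        if placed < n_homo:
            raise ConfigurationError(
                "infeasible packing: could not place all homozygous genes; "
                "reduce genes_per_chromosome or event counts"
            )

    homo_genes = [g for g in genes if g.category == "homozygous"]
    n_pairs = len(homo_genes)
    if config.n_identical_pairs > n_pairs:
        raise ConfigurationError("n_identical_pairs exceeds number of homozygous pairs")
    ident_idx = rng_gene.choice(n_pairs, size=config.n_identical_pairs, replace=False)
    identical_set = {homo_genes[i].pair_serial for i in ident_idx}
    de_pick = rng_gene.choice(
        sorted(identical_set), size=config.n_de_pairs, replace=False
    )
    de_set = {int(x) for x in de_pick}
    de_boost_hap = {s: ("hap1" if rng_gene.random() < 0.5 else "hap2") for s in sorted(de_set)}

    # ----- SNP planting --------------------------------------------------
    ident_cds: dict[str, list[tuple[int, int]]] = {cid: [] for cid in chrom_ids}
    for g in homo_genes:
        if g.pair_serial in identical_set:
            ident_cds[g.chrom].extend(g.cds)

    snp_positions: dict[str, set[int]] = {cid: set() for cid in chrom_ids}

    def excluded_intervals(cid: str) -> list[tuple[int, int]]:
        ivals = []
        for ev in events[cid]:
            if ev.start == ev.end:
                ivals.append((ev.start - 2, ev.end + 2))
            else:
                ivals.append((ev.start, ev.end))
        ivals.extend(ident_cds[cid])
        return sorted(ivals)

    def allowed_intervals(cid: str) -> list[tuple[int, int]]:
        lo, hi = body[cid]
        out = []
        cur = lo
        for s, e in excluded_intervals(cid):
            if s > cur:
                out.append((cur, min(s, hi)))
            cur = max(cur, e)
            if cur >= hi:
                break
        if cur < hi:
            out.append((cur, hi))
        return out

    for cid in chrom_ids:
        allow = allowed_intervals(cid)
        lens = np.array([e - s for s, e in allow], dtype=np.int64)
        total = int(lens.sum())
        n_snp = int(rng_snp.binomial(total, config.snp_rate))
        if n_snp == 0:
            continue
        offs = np.sort(rng_snp.choice(total, size=min(n_snp, total), replace=False))
        cum = np.cumsum(lens)
        iidx = np.searchsorted(cum, offs, side="right")
        starts = np.array([s for s, _ in allow], dtype=np.int64)
        prev_cum = np.concatenate(([0], cum[:-1]))
        pos = starts[iidx] + (offs - prev_cum[iidx])
        snp_positions[cid].update(int(p) for p in pos)

    # guarantee >= 1 CDS SNP for every non-identical homozygous pair, so the
    # planted identical-pair set is exact (skipped entirely when no SNP
    # divergence is requested)
    for g in homo_genes if config.snp_rate > 0 else []:
        if g.pair_serial in identical_set:
            continue
        if any(
            any(a <= p < b for a, b in g.cds) for p in snp_positions[g.chrom]
            if g.start <= p < g.end
        ):
            continue
        a, b = g.cds[int(rng_snp.integers(0, len(g.cds)))]
        for _ in range(50):
            p = int(rng_snp.integers(a, b))
            if p not in snp_positions[g.chrom]:
                snp_positions[g.chrom].add(p)
                break

    # extra promoter SNPs upstream of DE pairs (the planted cis signal)
    promoter_windows: dict[str, tuple[str, int, int]] = {}
    for g in homo_genes:
        if g.pair_serial not in identical_set:
            continue
        if g.strand == "+":
            ws, we = g.start - config.promoter_window, g.start
        else:
            ws, we = g.end, g.end + config.promoter_window
        ws = max(ws, body[g.chrom][0])
        we = min(we, body[g.chrom][1])
        promoter_windows[f"g{g.pair_serial:04d}"] = (g.chrom, ws, we)
        if g.pair_serial not in de_set:
            continue
        excl = excluded_intervals(g.chrom)
        candidates = [
            p for p in range(ws, we)
            if p not in snp_positions[g.chrom]
            and not any(s <= p < e for s, e in excl)
        ]
        k = min(config.de_promoter_snps, len(candidates))
        if k:
            picks = rng_snp.choice(len(candidates), size=k, replace=False)
            snp_positions[g.chrom].update(candidates[int(i)] for i in picks)

    for cid in chrom_ids:
        seq = hap1_chroms[cid]
        for p in sorted(snp_positions[cid]):
            ref = seq[p]
            alts = [b for b in "ACGT" if b != ref]
            events[cid].append(Event("snp", cid, p, p + 1, alt=alts[int(rng_snp.integers(0, 3))]))

    for cid in chrom_ids:
        events[cid].sort(key=lambda ev: (ev.start, ev.end, ev.kind))

    # ----- hap-2 construction + truth regions ---------------------------
    hap2_chroms: dict[str, str] = {}
    qinfo: dict[str, list[tuple[int, int]]] = {}
    imap: dict[str, list[tuple[int, int, int]]] = {}
    ev_index: dict[str, dict[int, int]] = {}
    for cid in chrom_ids:
        hap2_seq, qi, im = _walk(hap1_chroms[cid], events[cid])
        hap2_chroms[cid] = hap2_seq
        qinfo[cid] = qi
        imap[cid] = im
        ev_index[cid] = {id(ev): i for i, ev in enumerate(events[cid])}

    regions: list[RegionCall] = []
    trans_dst_q: dict[int, tuple[str, int, int]] = {}
    for cid in chrom_ids:
        for i, ev in enumerate(events[cid]):
            if ev.kind == "trans_dst":
                trans_dst_q[ev.link] = (cid, *qinfo[cid][i])

    for cid in chrom_ids:
        syn_r = body[cid][0]
        syn_q = body[cid][0]  # left telomere copied unchanged, delta 0
        for i, ev in enumerate(events[cid]):
            qs, qe = qinfo[cid][i]
            if ev.kind == "snp":
                regions.append(RegionCall(
                    "SNP", ref_chrom=cid, ref_start=ev.start, ref_end=ev.end,
                    qry_chrom=cid, qry_start=qs, qry_end=qe,
                    ref_base=hap1_chroms[cid][ev.start], qry_base=ev.alt,
                ))
                continue
            if ev.start > syn_r:
                regions.append(RegionCall(
                    "SYN", ref_chrom=cid, ref_start=syn_r, ref_end=ev.start,
                    qry_chrom=cid, qry_start=syn_q, qry_end=qs,
                ))
            if ev.kind == "deletion":
                regions.append(RegionCall(
                    "DEL", ref_chrom=cid, ref_start=ev.start, ref_end=ev.end,
                    qry_chrom=cid, qry_start=qs, qry_end=qs,
                ))
            elif ev.kind == "unique_hap1":
                regions.append(RegionCall(
                    "NOTAL", ref_chrom=cid, ref_start=ev.start, ref_end=ev.end,
                ))
            elif ev.kind == "insertion":
                regions.append(RegionCall(
                    "INS", ref_chrom=cid, ref_start=ev.start, ref_end=ev.start,
                    qry_chrom=cid, qry_start=qs, qry_end=qe,
                ))
            elif ev.kind == "unique_hap2":
                regions.append(RegionCall(
                    "NOTAL", qry_chrom=cid, qry_start=qs, qry_end=qe,
                ))
            elif ev.kind == "inversion":
                regions.append(RegionCall(
                    "INV", ref_chrom=cid, ref_start=ev.start, ref_end=ev.end,
                    qry_chrom=cid, qry_start=qs, qry_end=qe,
                ))
            elif ev.kind == "hdr":
                regions.append(RegionCall(
                    "HDR", ref_chrom=cid, ref_start=ev.start, ref_end=ev.end,
                    qry_chrom=cid, qry_start=qs, qry_end=qe,
                ))
            elif ev.kind == "translocation":
                dchrom, dqs, dqe = trans_dst_q[ev.link]
                regions.append(RegionCall(
                    "TRANS", ref_chrom=cid, ref_start=ev.start, ref_end=ev.end,
                    qry_chrom=dchrom, qry_start=dqs, qry_end=dqe,
                ))
            # trans_dst contributes no call of its own
            syn_r = ev.end
            syn_q = qe
        if body[cid][1] > syn_r:
            # the stretch after the last event is one copied run: constant delta
            end_q = syn_q + (body[cid][1] - syn_r)
            regions.append(RegionCall(
                "SYN", ref_chrom=cid, ref_start=syn_r, ref_end=body[cid][1],
                qry_chrom=cid, qry_start=syn_q, qry_end=end_q,
            ))
    regions = sort_calls(regions)

    hap1 = HaplotypeGenome("hap1", hap1_chroms)
    hap2 = HaplotypeGenome("hap2", hap2_chroms)

    # ----- gene models on both haplotypes --------------------------------
    genes_h1: list[GeneModel] = []
    genes_h2: list[GeneModel] = []
    hemizygosity: dict[tuple[str, str], str] = {}
    pairs: list[tuple[str, str]] = []

    def make_model(gid, hap, cid, strand, gs, ge, cds, genome):
        return GeneModel(
            gene_id=gid, haplotype=hap, chrom=cid, strand=strand,
            start=gs, end=ge, cds=tuple(cds),
            cds_sequence=spliced_cds(genome.chromosomes[cid], tuple(cds), strand),
        )

    for g in genes:
        if g.category == "homozygous":
            gid1, gid2 = f"h1g{g.pair_serial:04d}", f"h2g{g.pair_serial:04d}"
            genes_h1.append(make_model(gid1, "hap1", g.chrom, g.strand,
                                       g.start, g.end, g.cds, hap1))
            s2, e2 = _lift(imap[g.chrom], g.start, g.end)
            cds2 = tuple(_lift(imap[g.chrom], a, b) for a, b in g.cds)
            genes_h2.append(make_model(gid2, "hap2", g.chrom, g.strand,
                                       s2, e2, cds2, hap2))
            hemizygosity[("hap1", gid1)] = "homozygous"
            hemizygosity[("hap2", gid2)] = "homozygous"
            pairs.append((gid1, gid2))
        elif g.haplotype == "hap1":
            genes_h1.append(make_model(g.gene_id, "hap1", g.chrom, g.strand,
                                       g.start, g.end, g.cds, hap1))
            hemizygosity[("hap1", g.gene_id)] = g.category
        elif g.payload_event is not None:
            ei = ev_index[g.chrom][id(g.payload_event)]
            qs, _ = qinfo[g.chrom][ei]
            gs, ge = g.start + qs, g.end + qs
            cds2 = tuple((a + qs, b + qs) for a, b in g.cds)
            genes_h2.append(make_model(g.gene_id, "hap2", g.chrom, g.strand,
                                       gs, ge, cds2, hap2))
            hemizygosity[("hap2", g.gene_id)] = g.category
        else:  # hap2 HDR-resident: same-length substitution, lift by delta
            s2, e2 = _lift(imap[g.chrom], g.start, g.end)
            cds2 = tuple(_lift(imap[g.chrom], a, b) for a, b in g.cds)
            genes_h2.append(make_model(g.gene_id, "hap2", g.chrom, g.strand,
                                       s2, e2, cds2, hap2))
            hemizygosity[("hap2", g.gene_id)] = g.category

    genes_h1.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    genes_h2.sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    identical_pairs = sorted(
        (f"h1g{s:04d}", f"h2g{s:04d}") for s in identical_set
    )
    de_truth: dict[tuple[str, str], dict[str, float]] = {}
    for s in sorted(de_set):
        fold = config.cis_effect_fold if de_boost_hap[s] == "hap1" else 1.0 / config.cis_effect_fold
        de_truth[(f"h1g{s:04d}", f"h2g{s:04d}")] = {t: fold for t in TISSUES}

    # planted promoter-variant truth (hap-1 window of each identical pair)
    promoter_variants: dict[str, int] = {}
    for g in homo_genes:
        if g.pair_serial not in identical_set:
            continue
        cid, ws, we = promoter_windows[f"g{g.pair_serial:04d}"]
        n_snps_in = sum(1 for p in snp_positions[cid] if ws <= p < we)
        n_sv_in = sum(
            1 for ev in events[cid]
            if ev.kind not in ("snp",)
            and (ev.start < we and ev.end > ws if ev.start < ev.end else ws <= ev.start < we)
        )
        promoter_variants[f"h1g{g.pair_serial:04d}"] = n_snps_in + n_sv_in

    # ----- expression -----------------------------------------------------
    reps = config.replicates_per_tissue
    columns = [f"{t}:{r + 1}" for t in TISSUES for r in range(reps)]
    entity_baseline: dict[str, float] = {}
    entity_tissue: dict[str, dict[str, float]] = {}

    def entity_key(gene_id: str) -> str:
        # homozygous pair members share one expression entity
        if gene_id.startswith(("h1g", "h2g")):
            return "pair" + gene_id[3:]
        return gene_id

    all_entities = sorted({entity_key(g.gene_id) for g in genes_h1 + genes_h2})
    for ek in all_entities:
        entity_baseline[ek] = float(rng_expr.lognormal(math.log(100.0), 1.0))
        entity_tissue[ek] = {t: float(rng_expr.lognormal(0.0, 0.5)) for t in TISSUES}

    de_serials = {s: de_boost_hap[s] for s in de_set}

    def mean_for(gene: GeneModel, tissue: str) -> float:
        ek = entity_key(gene.gene_id)
        mu = entity_baseline[ek] * entity_tissue[ek][tissue]
        if hemizygosity[(gene.haplotype, gene.gene_id)] != "homozygous":
            mu *= config.hemizygous_expression_boost
        if gene.gene_id.startswith(("h1g", "h2g")):
            serial = int(gene.gene_id[3:])
            if serial in de_serials and de_serials[serial] == gene.haplotype:
                mu *= config.cis_effect_fold
        return mu

    def build_matrix(gene_list: list[GeneModel], hap: str) -> ExpressionMatrix:
        rows = {}
        for gene in sorted(gene_list, key=lambda g: g.gene_id):
            vals = []
            for t in TISSUES:
                mu = mean_for(gene, t)
                vals.extend(draw_nb_counts(rng_expr, mu, config.nb_dispersion, reps).tolist())
            rows[gene.gene_id] = vals
        counts = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
        lengths = pd.Series({g.gene_id: float(g.cds_length) for g in gene_list})
        return ExpressionMatrix(haplotype=hap, counts=counts.astype(np.int64),
                                lengths=lengths.reindex(counts.index))

    expr1 = build_matrix(genes_h1, "hap1")
    expr2 = build_matrix(genes_h2, "hap2")

    # ----- genetic map ----------------------------------------------------
    markers: list[GeneticMapMarker] = []
    for cid in chrom_ids:
        n = config.n_map_markers
        if n == 0:
            continue
        pos = np.sort(rng_map.choice(
            np.arange(body[cid][0], body[cid][1]), size=n, replace=False
        ))
        incr = rng_map.uniform(0.5, 2.0, size=n)
        cm = np.cumsum(incr)
        cm = cm / cm[-1] * 120.0  # ~120 cM per chromosome
        for i in range(n):
            markers.append(GeneticMapMarker(f"{cid}_m{i + 1:03d}", cid,
                                            float(cm[i]), int(pos[i])))

    truth = SimTruth(
        config=config,
        events=events,
        regions=regions,
        hemizygosity=hemizygosity,
        pairs=sorted(pairs),
        identical_pairs=identical_pairs,
        de_truth=de_truth,
        promoter_variants=promoter_variants,
        body_spans=dict(body),
    )
    return SimulatedDataset(
        hap1=hap1, hap2=hap2,
        genes_hap1=genes_h1, genes_hap2=genes_h2,
        expression_hap1=expr1, expression_hap2=expr2,
        markers=markers, truth=truth,
    )
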
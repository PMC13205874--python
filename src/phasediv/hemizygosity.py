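"""Hemizygous gene detection and region-class categorization.

A gene is homozygous iff some gene on the other haplotype lies within the
syntenic projection of its locus and has global CDS identity at or above a
threshold; otherwise it is hemizygous (haplotype-specific).  Hemizygous
genes are then attributed to the region class that explains them — the
haplotype-specific insertion they sit in, a highly diverged region (HDR),
or a haplotype-unique (unaligned) segment — by largest overlap with a
minimum-overlap floor and fixed priority insertion > HDR > unique for ties.
"""

from __future__ import annotations

import edlib
from intervaltree import IntervalTree

from .models import GeneModel, HemizygosityRecord, RegionCall
from .projection import SyntenyProjector

CATEGORIES = ("insertion", "HDR", "unique")


def cds_identity(a: str, b: str) -> float:
    """Global (NW) identity between two CDS strings: 1 - dist / max length."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / max(len(a), len(b)))


def _gene_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    return trees


def call_hemizygous(
    genes_h1: list[GeneModel],
    genes_h2: list[GeneModel],
    region_calls: list[RegionCall],
    cds_identity_threshold: float = 0.9,
) -> tuple[list[HemizygosityRecord], list[HemizygosityRecord]]:
    """Classify every gene on both haplotypes as homozygous or hemizygous.

    Partner search is restricted to the syntenic projection window of each
    gene's locus (not genome-wide best hit), so translocated paralogs
    cannot rescue a truly hemizygous gene.  Returns one record list per
    haplotype, sorted by gene id.
    """
    out: list[list[HemizygosityRecord]] = []
    for hap, own, other in (
        ("hap1", genes_h1, genes_h2),
        ("hap2", genes_h2, genes_h1),
    ):
        proj = SyntenyProjector(region_calls, from_hap=hap)
        trees = _gene_trees(other)
        known_chroms = {g.chrom for g in other} | {
            (c.ref_chrom if hap == "hap1" else c.qry_chrom)
            for c in region_calls
            if c.interval(hap) is not None
        }
        records = []
        for g in sorted(own, key=lambda x: x.gene_id):
            if g.chrom not in known_chroms:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
            win = proj.window(g.chrom, g.start, g.end)
            best_id, best_partner = 0.0, None
            if win is not None and win[0] in trees:
                for iv in trees[win[0]].overlap(win[1], win[2]):
                    ident = cds_identity(g.cds_sequence, iv.data.cds_sequence)
                    if ident > best_id:
                        best_id, best_partner = ident, iv.data.gene_id
            if best_partner is not None and best_id >= cds_identity_threshold:
                records.append(HemizygosityRecord(
                    gene_id=g.gene_id, haplotype=hap, status="homozygous",
                    partner_id=best_partner, partner_identity=best_id,
                ))
            else:
                records.append(HemizygosityRecord(
                    gene_id=g.gene_id, haplotype=hap, status="hemizygous",
                    category="unassigned",
                    partner_id=best_partner, partner_identity=best_id or None,
                ))
        out.append(records)
    return out[0], out[1]


def categorize_hemizygous(
    records: list[HemizygosityRecord],
    genes: list[GeneModel],
    region_calls: list[RegionCall],
    min_overlap: float = 0.5,
) -> list[HemizygosityRecord]:
    """Assign each hemizygous gene to insertion / HDR / unique (or unassigned).

    The insertion view is haplotype-relative: for a hap-1 gene the
    "insertions" are DEL calls (sequence present only in hap-1); for a
    hap-2 gene they are INS calls.  Overlap fractions are of the gene span;
    the largest wins if it reaches ``min_overlap``, ties resolved
    insertion > HDR > unique.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    trees: dict[str, dict[str, IntervalTree]] = {c: {} for c in CATEGORIES}

    def add(cat: str, chrom: str, s: int, e: int) -> None:
        if e > s:
            trees[cat].setdefault(chrom, IntervalTree()).addi(s, e)

    hap = next((r.haplotype for r in records), None)
    for c in region_calls:
        iv = c.interval(hap) if hap else None
        if iv is None:
            continue
        chrom, s, e = iv
        if c.rtype == "HDR":
            add("HDR", chrom, s, e)
        elif c.rtype == "NOTAL":
            add("unique", chrom, s, e)
        elif (hap == "hap1" and c.rtype == "DEL") or (hap == "hap2" and c.rtype == "INS"):
            add("insertion", chrom, s, e)

    out = []
    for rec in sorted(records, key=lambda r: r.gene_id):
        if rec.status == "homozygous":
            out.append(rec)
            continue
        g = gene_by_id[rec.gene_id]
        span = g.end - g.start
        fracs = {}
        for cat in CATEGORIES:
            tree = trees[cat].get(g.chrom)
            ov = 0
            if tree is not None:
                for iv in tree.overlap(g.start, g.end):
                    ov += min(iv.end, g.end) - max(iv.begin, g.start)
            fracs[cat] = ov / span if span else 0.0
        best = max(CATEGORIES, key=lambda c: (fracs[c], -CATEGORIES.index(c)))
        out.append(HemizygosityRecord(
            gene_id=rec.gene_id, haplotype=rec.haplotype, status="hemizygous",
            category=best if fracs[best] >= min_overlap else "unassigned",
            overlap_fraction=fracs[best],
            partner_id=rec.partner_id, partner_identity=rec.partner_identity,
        ))
    return out


def summarize_counts(
    total_genes: int, hemizygous: int, by_category: dict[str, int]
) -> dict[str, float]:
    """Percentage arithmetic used in the summary table.

    The hemizygous share of all genes is rounded to the nearest integer;
    category shares of the hemizygous total are rounded to one decimal.
    """
    out: dict[str, float] = {
        "total_genes": total_genes,
        "hemizygous_count": hemizygous,
        "hemizygous_pct": round(100.0 * hemizygous / total_genes) if total_genes else 0.0,
    }
    for cat in (*CATEGORIES, "unassigned"):
        n = by_category.get(cat, 0)
        out[f"{cat}_count"] = n
        out[f"{cat}_pct"] = round(100.0 * n / hemizygous, 1) if hemizygous else 0.0
    return out


def summarize_categories(records: list[HemizygosityRecord]) -> dict[str, dict[str, float]]:
    """Per-haplotype summary: totals, hemizygous %, per-category counts/%."""
    summary: dict[str, dict[str, float]] = {}
    for hap in ("hap1", "hap2"):
        recs = [r for r in records if r.haplotype == hap]
        if not recs:
            continue
        hemi = [r for r in recs if r.status == "hemizygous"]
        by_cat: dict[str, int] = {}
        for r in hemi:
            by_cat[r.category] = by_cat.get(r.category, 0) + 1
        summary[hap] = summarize_counts(len(recs), len(hemi), by_cat)
    return summary
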
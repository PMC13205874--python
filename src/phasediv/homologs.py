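"""One-to-one homologous gene pairing and the identical-pair filter.

Candidate partners are sought inside syntenic projection windows and paired
reciprocal-best by global CDS identity; a pair is *identical* iff the two
CDS strings are byte-equal (which subsumes equal length).  Identical pairs
are the universe for the inter-haplotype differential-expression analysis
and its non-DE control set.
"""

from __future__ import annotations

from intervaltree import IntervalTree

from .hemizygosity import cds_identity
from .models import GeneModel, HomologPair, RegionCall
from .projection import SyntenyProjector


def _best_partners(
    own: list[GeneModel],
    other: list[GeneModel],
    proj: SyntenyProjector,
) -> dict[str, tuple[str | None, float, bool]]:
    """gene_id -> (best partner id or None-if-ambiguous, identity, unique)."""
    trees: dict[str, IntervalTree] = {}
    for g in other:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    out: dict[str, tuple[str | None, float, bool]] = {}
    for g in own:
        win = proj.window(g.chrom, g.start, g.end)
        best: list[str] = []
        best_id = 0.0
        if win is not None and win[0] in trees:
            for iv in trees[win[0]].overlap(win[1], win[2]):
                ident = cds_identity(g.cds_sequence, iv.data.cds_sequence)
                if ident > best_id:
                    best_id, best = ident, [iv.data.gene_id]
                elif ident == best_id and ident > 0.0:
                    best.append(iv.data.gene_id)
        if len(best) == 1:
            out[g.gene_id] = (best[0], best_id, True)
        else:
            out[g.gene_id] = (None, best_id, False)
    return out


def pair_homologs(
    genes_h1: list[GeneModel],
    genes_h2: list[GeneModel],
    region_calls: list[RegionCall],
) -> list[HomologPair]:
    """Reciprocal-best one-to-one pairs within syntenic windows.

    Genes with zero candidates or with ties for best identity are excluded;
    each gene appears in at most one pair.
    """
    fwd = _best_partners(genes_h1, genes_h2, SyntenyProjector(region_calls, "hap1"))
    rev = _best_partners(genes_h2, genes_h1, SyntenyProjector(region_calls, "hap2"))
    g1 = {g.gene_id: g for g in genes_h1}
    g2 = {g.gene_id: g for g in genes_h2}
    pairs: list[HomologPair] = []
    for gid1 in sorted(fwd):
        partner, ident, unique = fwd[gid1]
        if not unique or partner is None:
            continue
        back = rev.get(partner)
        if back is None or back[0] != gid1:
            continue
        identical = g1[gid1].cds_sequence == g2[partner].cds_sequence
        pairs.append(HomologPair(
            gene_id_h1=gid1, gene_id_h2=partner,
            cds_identity=1.0 if identical else ident,
            identical=identical, syntenic=True,
        ))
    return pairs


def filter_identical(pairs: list[HomologPair]) -> list[HomologPair]:
    """Pairs with 100% (byte-equal) coding-sequence identity."""
    return [p for p in pairs if p.identical]
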
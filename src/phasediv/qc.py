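"""Assembly QC: telomere-motif scanning, genetic-map concordance, and
basic assembly statistics.

Telomere scanning counts exact occurrences of the plant telomeric repeat
(TTTAGGG by default) and its reverse complement in fixed windows tiling
each chromosome; a chromosome end is telomere-positive when its terminal
windows hold at least ``min_copies`` copies.  Map concordance is the
Spearman rank correlation between genetic (cM) and physical (bp) marker
positions per chromosome, with an orientation-corrected |rho| for maps
stored in reversed orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneticMapMarker, HaplotypeGenome
from .sequence import revcomp


class ParameterError(ValueError):
    pass


@dataclass
class TelomereProfile:
    chrom: str
    window: int
    counts: np.ndarray  # motif + revcomp occurrences per tiling window
    left_terminal_positive: bool
    right_terminal_positive: bool

    @property
    def total_copies(self) -> int:
        return int(self.counts.sum())


def _count_overlapping(seq: str, motif: str) -> list[int]:
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def telomere_scan(
    genome: HaplotypeGenome,
    motif: str = "TTTAGGG",
    window: int = 10_000,
    terminal_windows: int = 2,
    min_copies: int = 10,
) -> list[TelomereProfile]:
    """Per-window telomere-motif counts (both strands) for every chromosome."""
    if not motif:
        raise ParameterError("motif must be non-empty")
    if window <= 0:
        raise ParameterError("window must be positive")
    profiles = []
    rc = revcomp(motif)
    for cid, seq in genome.chromosomes.items():
        n_win = max(1, -(-len(seq) // window))
        counts = np.zeros(n_win, dtype=np.int64)
        positions = _count_overlapping(seq, motif)
        if rc != motif:
            positions += _count_overlapping(seq, rc)
        for p in positions:
            counts[p // window] += 1
        t = min(terminal_windows, n_win)
        profiles.append(TelomereProfile(
            chrom=cid, window=window, counts=counts,
            left_terminal_positive=bool(counts[:t].sum() >= min_copies),
            right_terminal_positive=bool(counts[-t:].sum() >= min_copies),
        ))
    return profiles


def map_concordance(markers: list[GeneticMapMarker]) -> pd.DataFrame:
    """Per-chromosome genetic-vs-physical map concordance.

    Spearman rho (midranks on ties), marker count, the largest rank
    discordance, and orientation-corrected |rho|.  Chromosomes with fewer
    than 3 markers omit the correlation (NaN).
    """
    by_chrom: dict[str, list[GeneticMapMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m)
    rows = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: m.pos)
        cm = np.array([m.cm for m in ms], dtype=float)
        bp = np.array([m.pos for m in ms], dtype=float)
        if len(ms) >= 3:
            rho = float(stats.spearmanr(bp, cm).statistic)
            r_cm = stats.rankdata(cm)
            r_bp = stats.rankdata(bp)
            max_disc = float(np.max(np.abs(r_cm - r_bp)))
        else:
            rho, max_disc = np.nan, np.nan
        rows.append({
            "chrom": chrom, "n_markers": len(ms),
            "rho": rho, "abs_rho": abs(rho) if np.isfinite(rho) else np.nan,
            "max_rank_discordance": max_disc,
        })
    return pd.DataFrame(rows)


def assembly_stats(genome: HaplotypeGenome) -> dict:
    """Total length, chromosome count, N-gap runs and gapless chromosomes."""
    per_chrom = {}
    gapless = 0
    for cid in genome.chromosomes:
        runs = genome.gap_runs(cid)
        per_chrom[cid] = {
            "length": genome.length(cid),
            "gap_runs": len(runs),
            "gap_bases": sum(e - s for s, e in runs),
        }
        if not runs:
            gapless += 1
    return {
        "haplotype": genome.label,
        "total_length": genome.total_length,
        "n_chromosomes": len(genome.chromosomes),
        "gapless_chromosomes": gapless,
        "chromosomes": per_chrom,
    }
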
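"""Shared domain types for the phased-diploid divergence pipeline.

All coordinates are internal 0-based half-open (see :mod:`phasediv.coords`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence import ALPHABET

HAPLOTYPES = ("hap1", "hap2")

#: Region-call vocabulary, matching the SyRI-style classes the pipeline emits.
REGION_TYPES = frozenset({"SYN", "INV", "TRANS", "INS", "DEL", "HDR", "NOTAL", "SNP"})

#: Region classes that count as structural variants for burden counting.
SV_TYPES = frozenset({"INS", "DEL", "INV", "TRANS", "HDR"})

TISSUES = ("leaf", "stolon", "rhizome", "root")


class FormatError(ValueError):
    """Malformed external file or record."""


@dataclass
class HaplotypeGenome:
    """Named chromosome sequences for one haplotype.

    ``chromosomes`` is an ordered mapping chromosome-id -> uppercase
    sequence over {A,C,G,T,N}.
    """

    label: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if self.label not in HAPLOTYPES:
            raise ValueError(f"haplotype label must be one of {HAPLOTYPES}, got {self.label!r}")
        if not self.chromosomes:
            raise ValueError("genome has no chromosomes")
        for cid, seq in self.chromosomes.items():
            if not seq:
                raise FormatError(f"chromosome {cid!r} is empty")
            bad = set(seq) - ALPHABET
            if bad:
                off = min(seq.index(b) for b in bad)
                raise FormatError(
                    f"chromosome {cid!r}: invalid character {seq[off]!r} at offset {off}"
                )

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def gap_runs(self, chrom: str) -> list[tuple[int, int]]:
        """Maximal runs of N (assembly gaps), internal coordinates."""
        seq = self.chromosomes[chrom]
        runs: list[tuple[int, int]] = []
        i = seq.find("N")
        while i != -1:
            j = i
            while j < len(seq) and seq[j] == "N":
                j += 1
            runs.append((i, j))
            i = seq.find("N", j)
        return runs


@dataclass
class GeneModel:
    """A protein-coding gene with one CDS chain (longest-mRNA rule)."""

    gene_id: str
    haplotype: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds:
            raise ValueError(f"gene {self.gene_id}: empty CDS chain")
        prev_end = None
        for a, b in self.cds:
            if not (self.start <= a < b <= self.end):
                raise ValueError(f"gene {self.gene_id}: CDS ({a},{b}) outside span")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"gene {self.gene_id}: CDS intervals overlap or unsorted")
            prev_end = b
        if len(self.cds_sequence) != self.cds_length:
            raise ValueError(f"gene {self.gene_id}: cds_sequence length mismatch")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class RegionCall:
    """One classified interval pair (or single-haplotype interval).

    One-sided calls: INS carries a zero-length ref interval at the
    breakpoint (qry = hap2 holds the extra sequence); DEL the converse;
    NOTAL has exactly one side, the other side's fields are ``None``.
    SNP calls carry the two bases.
    """

    rtype: str
    ref_chrom: str | None = None
    ref_start: int | None = None
    ref_end: int | None = None
    qry_chrom: str | None = None
    qry_start: int | None = None
    qry_end: int | None = None
    ref_base: str | None = None
    qry_base: str | None = None

    def __post_init__(self) -> None:
        if self.rtype not in REGION_TYPES:
            raise FormatError(f"unknown region type {self.rtype!r}")
        if self.rtype in {"SYN", "INV", "TRANS", "HDR"}:
            if not (self.has_ref and self.has_qry):
                raise ValueError(f"{self.rtype} call requires both intervals")
        if self.rtype == "NOTAL" and (self.ref_chrom is None) == (self.qry_chrom is None):
            raise ValueError("NOTAL call must have exactly one side")

    @property
    def has_ref(self) -> bool:
        return self.ref_chrom is not None

    @property
    def has_qry(self) -> bool:
        return self.qry_chrom is not None

    @property
    def ref_len(self) -> int:
        return 0 if self.ref_start is None else self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return 0 if self.qry_start is None else self.qry_end - self.qry_start

    def interval(self, haplotype: str) -> tuple[str, int, int] | None:
        """(chrom, start, end) of this call on one haplotype, or None."""
        if haplotype == "hap1":
            return (self.ref_chrom, self.ref_start, self.ref_end) if self.has_ref else None
        return (self.qry_chrom, self.qry_start, self.qry_end) if self.has_qry else None


def sort_calls(calls: list[RegionCall]) -> list[RegionCall]:
    """Canonical order: ref-chrom then ref-start, one-sided qry calls by qry."""

    def key(c: RegionCall):
        if c.has_ref:
            return (c.ref_chrom, c.ref_start, c.ref_end, 0, c.qry_start or 0)
        return (c.qry_chrom, c.qry_start, c.qry_end, 1, 0)

    return sorted(calls, key=key)


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x tissue-replicate samples) for one haplotype.

    Columns are named ``tissue:replicate`` (e.g. ``leaf:1``); ``lengths``
    gives effective gene lengths in bp, indexed like ``counts``.
    """

    haplotype: str
    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"haplotype must be one of {HAPLOTYPES}")
        if not self.counts.index.is_unique:
            raise FormatError("duplicate gene ids in counts")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise FormatError("counts must be finite and non-negative")
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()][0]
                raise FormatError(f"no effective length for gene {missing!r}")
        for col in self.counts.columns:
            if ":" not in col:
                raise FormatError(f"sample column {col!r} is not 'tissue:replicate'")

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for col in self.counts.columns:
            t = col.split(":")[0]
            if t not in seen:
                seen.append(t)
        return seen

    def tissue_columns(self, tissue: str) -> list[str]:
        return [c for c in self.counts.columns if c.split(":")[0] == tissue]


@dataclass
class GeneticMapMarker:
    """A genetic-map marker: genetic (cM) and physical (bp) position."""

    marker_id: str
    chrom: str
    cm: float
    pos: int  # internal 0-based

    def __post_init__(self) -> None:
        if self.cm < 0:
            raise ValueError(f"marker {self.marker_id}: cM must be >= 0")


@dataclass
class HomologPair:
    """A one-to-one gene pairing across haplotypes."""

    gene_id_h1: str
    gene_id_h2: str
    cds_identity: float
    identical: bool
    syntenic: bool = True

    def __post_init__(self) -> None:
        if self.identical and self.cds_identity != 1.0:
            raise ValueError("identical pair must have cds_identity == 1.0")


@dataclass
class HemizygosityRecord:
    """Hemizygosity status and (for hemizygous genes) region category."""

    gene_id: str
    haplotype: str
    status: str  # homozygous | hemizygous
    category: str | None = None  # insertion | HDR | unique | unassigned
    overlap_fraction: float = 0.0
    partner_id: str | None = None
    partner_identity: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("homozygous", "hemizygous"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "homozygous" and self.category is not None:
            raise ValueError("homozygous record cannot carry a category")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction outside [0, 1]")


@dataclass
class DEResult:
    """Per-pair differential-expression result across tissues."""

    gene_id_h1: str
    gene_id_h2: str
    log2_fold_change: dict[str, float] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)
    q_value: dict[str, float] = field(default_factory=dict)
    de_flag: bool = False


@dataclass
class PromoterBurden:
    """Variant counts in one gene's strand-aware upstream promoter window."""

    gene_id: str
    haplotype: str
    chrom: str
    start: int
    end: int
    strand: str
    snp_count: int = 0
    sv_count: int = 0

    @property
    def total_variant_count(self) -> int:
        return self.snp_count + self.sv_count

    @property
    def length(self) -> int:
        return self.end - self.start
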
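"""Readers and writers for every external representation the pipeline touches.

Conventions: GFF3 / VCF / TSV files are 1-based inclusive on disk, BED is
0-based half-open; everything is converted to internal 0-based half-open
coordinates through :mod:`phasediv.coords` at this boundary and nowhere
else.  Every writer/reader pair round-trips losslessly on simulator output.
"""

from __future__ import annotations

import re

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import coords
from .models import (
    REGION_TYPES,
    ExpressionMatrix,
    FormatError,
    GeneModel,
    GeneticMapMarker,
    HaplotypeGenome,
    RegionCall,
    sort_calls,
)
from .sequence import spliced_cds

_VALID_RE = re.compile(r"[^ACGTN]")


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str, label: str = "hap1") -> HaplotypeGenome:
    """Read a haplotype assembly from FASTA.

    Sequences are uppercased and U is mapped to T; any residue outside
    {A,C,G,T,N} is rejected with the record name and offset.
    """
    chromosomes: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in chromosomes:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} is empty")
        m = _VALID_RE.search(seq)
        if m:
            raise FormatError(
                f"{path}: record {rec.id!r} has invalid character "
                f"{m.group()!r} at offset {m.start()}"
            )
        chromosomes[rec.id] = seq
    if not chromosomes:
        raise FormatError(f"{path}: no FASTA records")
    return HaplotypeGenome(label=label, chromosomes=chromosomes)


def write_genome(genome: HaplotypeGenome, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_annotation(path: str, genome: HaplotypeGenome) -> tuple[list[GeneModel], int]:
    """Read gene models from GFF3, one per gene via the longest-mRNA rule.

    Returns ``(genes, n_skipped)`` where skipped genes are those without
    any CDS feature.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    skipped = 0
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        chrom = g.seqid
        if chrom not in genome.chromosomes:
            raise FormatError(f"{path}: gene {g.id} on unknown chromosome {chrom!r}")
        best: list[tuple[int, int]] | None = None
        best_len = -1
        for mrna in db.children(g, featuretype="mRNA", order_by="start"):
            cds = [
                coords.from_onebased(c.start, c.end)
                for c in db.children(mrna, featuretype="CDS", order_by="start")
            ]
            clen = sum(b - a for a, b in cds)
            if cds and clen > best_len:
                best, best_len = cds, clen
        if best is None:
            # gene-level CDS without mRNA wrapper
            cds = [
                coords.from_onebased(c.start, c.end)
                for c in db.children(g, featuretype="CDS", order_by="start")
            ]
            if cds:
                best = cds
        if best is None:
            skipped += 1
            continue
        seq = genome.chromosomes[chrom]
        for a, b in best:
            if not 0 <= a < b <= len(seq):
                raise FormatError(f"{path}: gene {g.id} CDS outside chromosome bounds")
        start, end = coords.from_onebased(g.start, g.end)
        genes.append(
            GeneModel(
                gene_id=g.id,
                haplotype=genome.label,
                chrom=chrom,
                strand=g.strand,
                start=start,
                end=end,
                cds=tuple(best),
                cds_sequence=spliced_cds(seq, tuple(best), g.strand),
            )
        )
    return genes, skipped


def write_annotation(genes: list[GeneModel], path: str) -> None:
    """Write gene/mRNA/CDS features (single isoform per gene) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
            s1, e1 = coords.to_onebased(g.start, g.end)
            fh.write(
                f"{g.chrom}\tphasediv\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tphasediv\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.cds, 1):
                a1, b1 = coords.to_onebased(a, b)
                phase = 0  # single-frame toy models
                fh.write(
                    f"{g.chrom}\tphasediv\tCDS\t{a1}\t{b1}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mid}.cds{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# SyRI-style region TSV

_REGION_COLS = (
    "ref_chrom ref_start ref_end qry_chrom qry_start qry_end type ref_base qry_base"
)


def _fmt_side(chrom: str | None, start: int | None, end: int | None) -> tuple[str, str, str]:
    if chrom is None:
        return "-", "-", "-"
    s1, e1 = coords.to_onebased(start, end)
    return chrom, str(s1), str(e1)


def write_region_calls(calls: list[RegionCall], path: str) -> None:
    """Write region calls as a SyRI-style TSV (1-based inclusive).

    Seven canonical columns plus two trailing base columns so SNP calls
    round-trip losslessly; absent sides are '-' and zero-length breakpoint
    intervals are written with start = end + 1.
    """
    with open(path, "w") as fh:
        fh.write("#" + _REGION_COLS.replace(" ", "\t") + "\n")
        for c in sort_calls(calls):
            rc, rs, re_ = _fmt_side(c.ref_chrom, c.ref_start, c.ref_end)
            qc, qs, qe = _fmt_side(c.qry_chrom, c.qry_start, c.qry_end)
            rb = c.ref_base or "-"
            qb = c.qry_base or "-"
            fh.write("\t".join([rc, rs, re_, qc, qs, qe, c.rtype, rb, qb]) + "\n")


def _parse_side(chrom: str, s: str, e: str, path: str, lineno: int):
    if chrom == "-":
        return None, None, None
    try:
        start, end = coords.from_onebased(int(s), int(e))
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: bad coordinates {s!r}/{e!r}") from exc
    if end < start:
        raise FormatError(f"{path}:{lineno}: negative-length interval")
    return chrom, start, end


def read_region_calls(path: str) -> list[RegionCall]:
    """Read a SyRI-style region TSV (7 or 9 tab-separated columns)."""
    calls: list[RegionCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (7, 9):
                raise FormatError(f"{path}:{lineno}: expected 7 or 9 columns, got {len(parts)}")
            rtype = parts[6]
            if rtype not in REGION_TYPES:
                raise FormatError(f"{path}:{lineno}: unknown region type {rtype!r}")
            ref = _parse_side(parts[0], parts[1], parts[2], path, lineno)
            qry = _parse_side(parts[3], parts[4], parts[5], path, lineno)
            rb = qb = None
            if len(parts) == 9:
                rb = None if parts[7] == "-" else parts[7]
                qb = None if parts[8] == "-" else parts[8]
            calls.append(
                RegionCall(
                    rtype=rtype,
                    ref_chrom=ref[0], ref_start=ref[1], ref_end=ref[2],
                    qry_chrom=qry[0], qry_start=qry[1], qry_end=qry[2],
                    ref_base=rb, qry_base=qb,
                )
            )
    return sort_calls(calls)


# ---------------------------------------------------------------------------
# VCF (SNPs and small indels, anchor-base convention)


def write_vcf(
    calls: list[RegionCall],
    ref: HaplotypeGenome,
    qry: HaplotypeGenome,
    path: str,
) -> None:
    """Emit SNP/INS/DEL calls as VCF 4.2 against the hap-1 (ref) assembly.

    Indels use the left-anchor-base convention: a deletion of internal
    ``[s, e)`` becomes POS=s (1-based), REF=ref[s-1:e], ALT=anchor base.
    Qry-side coordinates are preserved in INFO so parsing is lossless.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=VT,Number=1,Type=String,Description="Variant region type">',
        '##INFO=<ID=QCHROM,Number=1,Type=String,Description="hap2 chromosome">',
        '##INFO=<ID=QSTART,Number=1,Type=Integer,Description="hap2 start (1-based)">',
        '##INFO=<ID=QEND,Number=1,Type=Integer,Description="hap2 end (1-based inclusive)">',
    ]
    for cid, seq in ref.chromosomes.items():
        lines.append(f"##contig=<ID={cid},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    n = 0
    for c in sort_calls(calls):
        if c.rtype not in ("SNP", "INS", "DEL"):
            continue
        rseq = ref.chromosomes[c.ref_chrom]
        if c.rtype == "SNP":
            pos1 = c.ref_start + 1
            refa, alta = c.ref_base, c.qry_base
        elif c.rtype == "DEL":
            if c.ref_start == 0:
                raise FormatError("cannot left-anchor a deletion at chromosome start")
            pos1 = c.ref_start  # 1-based position of the anchor base
            refa = rseq[c.ref_start - 1 : c.ref_end]
            alta = rseq[c.ref_start - 1]
        else:  # INS: zero-length ref interval at the breakpoint
            p = c.ref_start
            if p == 0:
                raise FormatError("cannot left-anchor an insertion at chromosome start")
            ins = qry.chromosomes[c.qry_chrom][c.qry_start : c.qry_end]
            pos1 = p
            refa = rseq[p - 1]
            alta = refa + ins
        n += 1
        qs1, qe1 = coords.to_onebased(c.qry_start, c.qry_end)
        info = f"VT={c.rtype};QCHROM={c.qry_chrom};QSTART={qs1};QEND={qe1}"
        lines.append(
            f"{c.ref_chrom}\t{pos1}\tv{n}\t{refa}\t{alta}\t.\tPASS\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> list[RegionCall]:
    """Read back SNP/INS/DEL region calls from a VCF written by write_vcf."""
    calls: list[RegionCall] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            vt = rec.info["VT"]
            qchrom = rec.info["QCHROM"]
            qs, qe = coords.from_onebased(int(rec.info["QSTART"]), int(rec.info["QEND"]))
            alt = rec.alts[0]
            if vt == "SNP":
                calls.append(
                    RegionCall(
                        "SNP",
                        ref_chrom=rec.chrom, ref_start=rec.pos - 1, ref_end=rec.pos,
                        qry_chrom=qchrom, qry_start=qs, qry_end=qe,
                        ref_base=rec.ref, qry_base=alt,
                    )
                )
            elif vt == "DEL":
                calls.append(
                    RegionCall(
                        "DEL",
                        ref_chrom=rec.chrom, ref_start=rec.pos, ref_end=rec.pos + len(rec.ref) - 1,
                        qry_chrom=qchrom, qry_start=qs, qry_end=qe,
                    )
                )
            else:
                calls.append(
                    RegionCall(
                        "INS",
                        ref_chrom=rec.chrom, ref_start=rec.pos, ref_end=rec.pos,
                        qry_chrom=qchrom, qry_start=qs, qry_end=qe,
                    )
                )
    return sort_calls(calls)


# ---------------------------------------------------------------------------
# BED


def write_bed(records: list[tuple[str, int, int, str]], path: str) -> None:
    """Write (chrom, start, end, name) records, 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in records:
            bs, be = coords.to_bed(start, end)
            fh.write(f"{chrom}\t{bs}\t{be}\t{name}\n")


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            start, end = coords.from_bed(int(parts[1]), int(parts[2]))
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], start, end, name))
    return out


# ---------------------------------------------------------------------------
# Counts TSV


def write_counts(matrix: ExpressionMatrix, path: str) -> None:
    df = matrix.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts(path: str, lengths: pd.Series, haplotype: str) -> ExpressionMatrix:
    """Read a counts TSV (gene_id + one 'tissue:replicate' column per sample).

    ``lengths`` supplies effective gene lengths (bp), typically CDS lengths
    from the matching annotation.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except OSError as exc:
        raise FormatError(f"cannot read counts file {path}: {exc}") from exc
    return ExpressionMatrix(haplotype=haplotype, counts=df, lengths=lengths)


def lengths_from_annotation(genes: list[GeneModel]) -> pd.Series:
    return pd.Series({g.gene_id: g.cds_length for g in genes}, dtype=float)


# ---------------------------------------------------------------------------
# Genetic map TSV


def write_genetic_map(markers: list[GeneticMapMarker], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#marker_id\tchrom\tcM\tbp\n")
        for m in markers:
            fh.write(f"{m.marker_id}\t{m.chrom}\t{m.cm:.6g}\t{m.pos + 1}\n")


def read_genetic_map(path: str, genome: HaplotypeGenome | None = None) -> list[GeneticMapMarker]:
    markers: list[GeneticMapMarker] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            mid, chrom, cm, bp = parts
            marker = GeneticMapMarker(mid, chrom, float(cm), int(bp) - 1)
            if genome is not None:
                if chrom not in genome.chromosomes:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if not 0 <= marker.pos < genome.length(chrom):
                    raise FormatError(f"{path}:{lineno}: bp outside chromosome")
            markers.append(marker)
    return markers
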
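"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

ALPHABET = frozenset("ACGTN")

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase ACGTN)."""
    return seq.translate(_RC)[::-1]


def random_dna(rng, length: int) -> str:
    """Uniform random sequence over {A,C,G,T}."""
    return "".join(rng.choice(("A", "C", "G", "T"), size=length).tolist())


def spliced_cds(chrom_seq: str, cds: tuple[tuple[int, int], ...], strand: str) -> str:
    """Extract a spliced, strand-corrected CDS.

    ``cds`` intervals are internal coordinates, sorted ascending.  On the
    minus strand the result is the reverse complement of the concatenation,
    i.e. the intervals taken in decreasing coordinate order.
    """
    s = "".join(chrom_seq[a:b] for a, b in cds)
    return revcomp(s) if strand == "-" else s
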
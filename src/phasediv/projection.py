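"""Syntenic projection of loci between haplotypes via region calls.

Positions inside a two-sided call (SYN/INV/TRANS/HDR) map linearly between
its ref and qry intervals (reversed for INV); positions in one-sided
regions collapse to the nearest flanking two-sided boundary.  Used by the
hemizygosity and homolog modules to restrict partner search to the
corresponding locus rather than the whole genome.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .models import RegionCall

_TWO_SIDED = ("SYN", "INV", "TRANS", "HDR")


@dataclass
class _Segment:
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    dst_end: int
    reverse: bool

    def map_pos(self, p: int) -> tuple[str, int]:
        span = max(self.src_end - self.src_start, 1)
        frac = (p - self.src_start) / span
        if self.reverse:
            frac = 1.0 - frac
        return self.dst_chrom, int(round(self.dst_start + frac * (self.dst_end - self.dst_start)))


class SyntenyProjector:
    """Maps intervals from one haplotype to the other through region calls."""

    def __init__(self, calls: list[RegionCall], from_hap: str):
        self.from_hap = from_hap
        self._segments: dict[str, list[_Segment]] = {}
        self._starts: dict[str, list[int]] = {}
        for c in calls:
            if c.rtype not in _TWO_SIDED:
                continue
            if from_hap == "hap1":
                src = (c.ref_chrom, c.ref_start, c.ref_end)
                dst = (c.qry_chrom, c.qry_start, c.qry_end)
            else:
                src = (c.qry_chrom, c.qry_start, c.qry_end)
                dst = (c.ref_chrom, c.ref_start, c.ref_end)
            self._segments.setdefault(src[0], []).append(
                _Segment(src[1], src[2], dst[0], dst[1], dst[2], c.rtype == "INV")
            )
        for chrom, segs in self._segments.items():
            segs.sort(key=lambda s: s.src_start)
            self._starts[chrom] = [s.src_start for s in segs]

    def map_point(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Project one position; None if the chromosome has no mapped segment."""
        segs = self._segments.get(chrom)
        if not segs:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i >= 0 and segs[i].src_start <= pos < segs[i].src_end:
            return segs[i].map_pos(pos)
        # between segments: collapse to the nearest flanking boundary
        if i < 0:
            return segs[0].map_pos(segs[0].src_start)
        left = segs[i].map_pos(segs[i].src_end - 1)
        if i + 1 < len(segs):
            right = segs[i + 1].map_pos(segs[i + 1].src_start)
            if left[0] == right[0]:
                lo, hi = sorted((left[1], right[1]))
                return left[0], (lo + hi) // 2
        return left

    def window(self, chrom: str, start: int, end: int, slack: int = 1000):
        """Projected window for a locus, expanded by ``slack`` on both sides.

        Returns (chrom, start, end) on the other haplotype, or None when no
        projection exists (e.g. locus on an entirely unaligned chromosome).
        """
        a = self.map_point(chrom, start)
        b = self.map_point(chrom, max(start, end - 1))
        if a is None or b is None:
            return None
        if a[0] != b[0]:
            # locus straddles a translocation boundary: use the start side
            b = a
        lo, hi = sorted((a[1], b[1]))
        return a[0], max(0, lo - slack), hi + 1 + slack
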
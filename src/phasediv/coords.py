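"""Coordinate-convention conversions.

Internally every interval in this package is 0-based, half-open
``[start, end)``.  Conversion to and from external conventions happens in
exactly one place — this module — so that off-by-one behaviour is audited
once:

* GFF3 / VCF / SyRI-style TSV / genetic-map TSV: 1-based, inclusive.
* BED: 0-based, half-open (identical to the internal convention).

A zero-length internal interval ``[p, p)`` (an insertion breakpoint)
serializes to the 1-based pair ``(p + 1, p)``; the arithmetic below is its
own inverse, so breakpoints round-trip losslessly.
"""

from __future__ import annotations


def to_onebased(start: int, end: int) -> tuple[int, int]:
    """Internal half-open ``[start, end)`` -> 1-based inclusive ``(s, e)``."""
    return start + 1, end


def from_onebased(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive ``(s, e)`` -> internal half-open ``[start, end)``."""
    return start1 - 1, end1


def to_bed(start: int, end: int) -> tuple[int, int]:
    """Internal -> BED (identity; exists so callers name the convention)."""
    return start, end


def from_bed(start: int, end: int) -> tuple[int, int]:
    """BED -> internal (identity)."""
    return start, end
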
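"""Coordinate conventions, centralized so GFF3 and bedGraph never drift.

Internal convention everywhere in this package: 0-based, half-open
``[start, end)`` intervals, as in BED/bedGraph. GFF3 is 1-based inclusive;
the two helpers below are the only place the conversion happens.
"""

from __future__ import annotations


def to_gff3(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if end0 < start0:
        raise ValueError(f"end < start: [{start0}, {end0})")
    return start0 + 1, end0


def from_gff3(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid GFF3 interval: [{start1}, {end1}]")
    return start1 - 1, end1
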
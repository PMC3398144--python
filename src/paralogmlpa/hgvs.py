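"""HGVS-style coding-coordinate arithmetic with intronic offsets.

Positions follow the ``c.`` convention of transcript coordinates: ``c.100`` is
the 100th coding nucleotide; ``c.1145-942`` lies in the intron upstream of the
exon whose first base is c.1145, 942 nt 5' of it; ``c.2174+1097`` lies 1097 nt
3' of the exon ending at c.2174; ``c.*92`` is the 92nd base of the 3' UTR.
Ranges such as ``c.1360_1361`` or ``c.1145-880_1145-879`` denote the start
coordinate for ordering purposes.

Intron lengths are not part of the coordinate system, so spans are only
defined between positions that share an anchoring exon boundary or are both
exonic (coding, or both 3' UTR).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

from .errors import UnsupportedCoordinatesError

__all__ = ["HgvsPosition", "parse_hgvs", "hgvs_span_length"]

# One position: optional "*" (3'UTR), digits, optional +/- intronic offset.
_POS_RE = re.compile(r"(\*?)(\d+)(?:([+-])(\d+))?")

# Sort bucket for 3'UTR anchors: any *n orders after every coding position.
_UTR_BASE = 10**7


@total_ordering
@dataclass(frozen=True)
class HgvsPosition:
    """A parsed ``c.`` position: exonic anchor plus optional intronic offset."""

    anchor: int  # coding (or UTR) nucleotide number anchoring the position
    offset: int = 0  # 0 = exonic; <0 = intron 5' of anchor; >0 = intron 3' of anchor
    utr3: bool = False  # anchor counts from the stop codon (``*`` positions)

    @property
    def exonic(self) -> bool:
        return self.offset == 0

    def sort_key(self) -> tuple[int, int]:
        base = self.anchor + _UTR_BASE if self.utr3 else self.anchor
        return (base, self.offset)

    def __lt__(self, other: "HgvsPosition") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        star = "*" if self.utr3 else ""
        if self.offset == 0:
            return f"c.{star}{self.anchor}"
        sign = "+" if self.offset > 0 else "-"
        return f"c.{star}{self.anchor}{sign}{abs(self.offset)}"


def parse_hgvs(text: str) -> HgvsPosition:
    """Parse a ``c.``-style position; ranges collapse to their start.

    Accepts e.g. ``c.100``, ``c.1360_1361``, ``c.1145-942``,
    ``c.2174+1097_2174+1099``, ``c.*92``.
    """
    if not isinstance(text, str):
        raise UnsupportedCoordinatesError(f"not an HGVS string: {text!r}")
    body = text.strip()
    if body.startswith("c."):
        body = body[2:]
    first = body.split("_", 1)[0]
    m = _POS_RE.fullmatch(first)
    if m is None:
        raise UnsupportedCoordinatesError(f"cannot parse HGVS position {text!r}")
    star, anchor, sign, off = m.groups()
    offset = 0
    if sign is not None:
        offset = int(off) if sign == "+" else -int(off)
    return HgvsPosition(anchor=int(anchor), offset=offset, utr3=bool(star))


def _coerce(p: "HgvsPosition | str") -> HgvsPosition:
    return p if isinstance(p, HgvsPosition) else parse_hgvs(p)


def hgvs_span_length(a: "HgvsPosition | str", b: "HgvsPosition | str") -> int:
    """Inclusive nucleotide count between two positions.

    Symmetric in its arguments. Supported pairs: both exonic in the same
    domain (coding/coding or UTR/UTR), or both anchored to the same exon
    boundary with same-sign intronic offsets (one of the two may be the
    anchor base itself). Anything else would require an intron length the
    coordinate system does not carry.
    """
    pa, pb = _coerce(a), _coerce(b)
    if pa.utr3 != pb.utr3:
        raise UnsupportedCoordinatesError(
            f"cannot span across the stop codon: {pa} vs {pb}"
        )
    if pa.exonic and pb.exonic:
        return abs(pa.anchor - pb.anchor) + 1
    if pa.anchor == pb.anchor:
        oa, ob = pa.offset, pb.offset
        if oa * ob < 0:
            raise UnsupportedCoordinatesError(
                f"offsets straddle the anchor exon: {pa} vs {pb}"
            )
        return abs(oa - ob) + 1
    raise UnsupportedCoordinatesError(
        f"positions on different unanchored introns: {pa} vs {pb}"
    )
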
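"""PSV-level analyses downstream of dosage calling.

Given an ordered readout of paralog-discriminating sites (PSVs) across an
amplicon, :func:`map_breakpoint` delimits the recombination breakpoint
region, counts the interior discordant PSVs and classifies the exchange as
crossover (durable origin switch) or gene conversion (a donor tract flanked
by host sequence on both sides). :func:`insilico_asp` models the duplex
allele-specific PCR that detects a breakpoint-spanning haplotype even in the
dosage-masked configuration. :func:`bound_deletion` turns an array-probe
retained/deleted track into inner/outer deletion size bounds, and
:func:`expected_generations` converts an interduplicon genetic distance into
the expected number of meioses until one recombination separates the
duplicons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ParameterError, RangeError
from .hgvs import HgvsPosition, hgvs_span_length, parse_hgvs
from .locus_model import (
    GENE,
    PSEUDOGENE,
    DiploidGenotype,
    Haplotype,
    LocusMap,
    PSVRecord,
    packaged_locus,
)
from .synthetic_cohort import psv_origin

__all__ = [
    "BreakpointCall",
    "ASPAssay",
    "ProbeStateTrack",
    "DeletionBounds",
    "map_breakpoint",
    "insilico_asp",
    "packaged_asp_assay",
    "bound_deletion",
    "expected_generations",
]


@dataclass(frozen=True)
class BreakpointCall:
    """PSV-delimited breakpoint interval.

    ``anchor_up`` is the last position at or 5' of which every PSV carries
    the upstream origin (inclusive); ``anchor_down`` the first position at or
    3' of which every PSV carries the downstream origin (inclusive).
    """

    mechanism: str  # "crossover" | "conversion_tract" | "none"
    anchor_up: HgvsPosition | None = None
    anchor_down: HgvsPosition | None = None
    region_length_bp: int | None = None
    interior_psvs: tuple[tuple[PSVRecord, str], ...] = ()
    upstream_origin: str | None = None
    downstream_origin: str | None = None


def map_breakpoint(
    readout: Sequence[tuple[PSVRecord, str]]
) -> BreakpointCall:
    """Delimit the breakpoint region from an ordered (PSV, origin) readout.

    With all origins identical the mechanism is "none" (anchors undefined).
    A durable switch from the first to the last origin is a crossover; a
    donor run returning to the flanking origin is a conversion tract. The
    interior of the region may interleave origins — the double-Holliday-
    junction signature — without affecting the anchors, which are defined by
    the maximal uniform prefix and suffix.
    """
    if len(readout) < 2:
        raise ParameterError("need at least two PSVs to map a breakpoint")
    positions = [r.pos for r, _ in readout]
    for p1, p2 in zip(positions, positions[1:]):
        if not p1.sort_key() < p2.sort_key():
            raise ParameterError("readout must be ordered 5'->3' without ties")
    origins = [o for _, o in readout]
    first, last = origins[0], origins[-1]

    if all(o == first for o in origins):
        return BreakpointCall(mechanism="none")

    if first == last:
        # Donor island(s) flanked by host origin on both sides.
        runs = _origin_runs(origins)
        donor_runs = [r for r in runs if r[0] != first]
        lo = min(r[1] for r in donor_runs)
        hi = max(r[2] for r in donor_runs)
        return BreakpointCall(
            mechanism="conversion_tract",
            anchor_up=readout[lo][0].pos,
            anchor_down=readout[hi][0].pos,
            region_length_bp=_span(readout[lo][0].pos, readout[hi][0].pos),
            interior_psvs=tuple(readout[lo : hi + 1]),
            upstream_origin=first,
            downstream_origin=first,
        )

    # Crossover: maximal uniform prefix of `first`, maximal suffix of `last`.
    i = 0
    while origins[i] == first:
        i += 1
    j = len(origins) - 1
    while origins[j] == last:
        j -= 1
    anchor_up = readout[i - 1][0].pos
    anchor_down = readout[j + 1][0].pos
    interior = tuple(readout[i : j + 1])
    return BreakpointCall(
        mechanism="crossover",
        anchor_up=anchor_up,
        anchor_down=anchor_down,
        region_length_bp=_span(anchor_up, anchor_down),
        interior_psvs=interior,
        upstream_origin=first,
        downstream_origin=last,
    )


def _origin_runs(origins: Sequence[str]) -> list[tuple[str, int, int]]:
    runs = []
    start = 0
    for k in range(1, len(origins) + 1):
        if k == len(origins) or origins[k] != origins[start]:
            runs.append((origins[start], start, k - 1))
            start = k
    return runs


def _span(a: HgvsPosition, b: HgvsPosition) -> int | None:
    try:
        return hgvs_span_length(a, b)
    except Exception:
        return None


# -- in-silico allele-specific PCR --------------------------------------------


@dataclass(frozen=True)
class ASPAssay:
    """Duplex allele-specific PCR: origin-specific primer pair + control."""

    forward: tuple[HgvsPosition, str]  # (3'-end site, required origin)
    reverse: tuple[HgvsPosition, str]
    product_length_bp: int
    control_region: HgvsPosition
    control_product_length_bp: int

    def __post_init__(self):
        if self.forward[0].sort_key() >= self.reverse[0].sort_key():
            raise ParameterError("forward primer must lie 5' of reverse primer")
        if self.product_length_bp <= 0 or self.control_product_length_bp <= 0:
            raise ParameterError("product lengths must be positive")


def packaged_asp_assay(m: LocusMap | None = None) -> ASPAssay:
    """The intron-10 crossover assay shipped with the locus config."""
    m = m or packaged_locus()
    if not m.asp_assay:
        raise RangeError(f"locus {m.name!r} ships no asp_assay block")
    cfg = m.asp_assay
    return ASPAssay(
        forward=(parse_hgvs(cfg["forward"]["position"]), cfg["forward"]["origin"]),
        reverse=(parse_hgvs(cfg["reverse"]["position"]), cfg["reverse"]["origin"]),
        product_length_bp=int(cfg["product_length_bp"]),
        control_region=parse_hgvs(cfg["control_region"]),
        control_product_length_bp=int(cfg["control_product_length_bp"]),
    )


def _origin_at_position(
    h: Haplotype, pos: HgvsPosition, m: LocusMap
) -> str | None:
    """Paralog origin a haplotype carries at a position; None if absent."""
    # A PSV at exactly this position may carry a fine-scale override.
    for r in m.psv_catalog:
        if r.pos.sort_key() == pos.sort_key():
            gi = m.psv_group(r)
            if h.is_deleted(gi):
                return None
            if h.locus == "pseudogene_locus" and m.site_groups[gi] not in m.pseudogene_exons:
                return None
            return psv_origin(h, r, m)
    gi = m._group_of_position(pos)
    if h.is_deleted(gi):
        return None
    if h.locus == "pseudogene_locus" and m.site_groups[gi] not in m.pseudogene_exons:
        return None
    return h.origin_at(gi)


def insilico_asp(
    g: DiploidGenotype,
    assay: ASPAssay | None = None,
    m: LocusMap | None = None,
) -> list[dict]:
    """Which duplex-PCR products amplify from a diploid genotype.

    The allele-specific product requires a single haplotype carrying the
    required paralog origin at both primer sites in cis; the control product
    amplifies from any haplotype that retains the (paralog-nonspecific)
    control region.
    """
    m = m or packaged_locus()
    assay = assay or packaged_asp_assay(m)
    (fpos, forigin), (rpos, rorigin) = assay.forward, assay.reverse
    # Range check against the locus extent.
    for pos in (fpos, rpos, assay.control_region):
        m._group_of_position(pos)  # raises RangeError if unplaceable

    products: list[dict] = []
    specific_from = [
        h.label
        for h in g.haplotypes
        if _origin_at_position(h, fpos, m) == forigin
        and _origin_at_position(h, rpos, m) == rorigin
    ]
    if specific_from:
        products.append(
            {
                "product": "allele_specific",
                "length_bp": assay.product_length_bp,
                "template_haplotypes": specific_from,
            }
        )
    control_from = [
        h.label
        for h in g.haplotypes
        if _origin_at_position(h, assay.control_region, m) is not None
    ]
    if control_from:
        products.append(
            {
                "product": "control",
                "length_bp": assay.control_product_length_bp,
                "template_haplotypes": control_from,
            }
        )
    return products


def asp_positive(g: DiploidGenotype, assay: ASPAssay | None = None,
                 m: LocusMap | None = None) -> bool:
    """True iff the allele-specific product amplifies."""
    return any(
        p["product"] == "allele_specific" for p in insilico_asp(g, assay, m)
    )


# -- array-probe deletion bounding --------------------------------------------

RETAINED = "retained"
DELETED = "deleted"


@dataclass(frozen=True)
class ProbeStateTrack:
    """Ordered (genomic coordinate, retained/deleted) array-probe states."""

    probes: tuple[tuple[int, str], ...]

    def __post_init__(self):
        coords = [c for c, _ in self.probes]
        if any(a >= b for a, b in zip(coords, coords[1:])):
            raise ParameterError("probe coordinates must strictly increase")
        for _, s in self.probes:
            if s not in (RETAINED, DELETED):
                raise ParameterError(f"invalid probe state {s!r}")


@dataclass(frozen=True)
class DeletionBounds:
    min_size_bp: int
    max_size_bp: int | None
    distal_interval: tuple[int, int] | None  # (last retained, first deleted)
    proximal_interval: tuple[int, int] | None  # (last deleted, next retained)
    one_sided: bool = False


def bound_deletion(track: ProbeStateTrack) -> DeletionBounds | None:
    """Inner/outer size bounds of a contiguous deleted probe run.

    The minimal size spans the innermost (deleted) probes; the maximal size
    spans the outermost retained neighbors; the two flanking gaps are the
    breakpoint intervals. Returns None when no probe is deleted; a run
    touching a track edge yields one-sided bounds (no outer estimate).
    """
    states = [s for _, s in track.probes]
    runs = [r for r in _origin_runs(states) if r[0] == DELETED]
    if not runs:
        return None
    if len(runs) > 1:
        raise ParameterError(
            f"track contains {len(runs)} deleted runs; expected one contiguous run"
        )
    _, lo, hi = runs[0]
    coords = [c for c, _ in track.probes]
    first_del, last_del = coords[lo], coords[hi]
    left = coords[lo - 1] if lo > 0 else None
    right = coords[hi + 1] if hi + 1 < len(coords) else None
    min_size = last_del - first_del
    if left is None or right is None:
        return DeletionBounds(
            min_size_bp=min_size,
            max_size_bp=None,
            distal_interval=(left, first_del) if left is not None else None,
            proximal_interval=(last_del, right) if right is not None else None,
            one_sided=True,
        )
    return DeletionBounds(
        min_size_bp=min_size,
        max_size_bp=right - left,
        distal_interval=(left, first_del),
        proximal_interval=(last_del, right),
    )


# -- recombination clock -------------------------------------------------------


def expected_generations(distance_mb: float, rate_cm_per_mb: float) -> float:
    """Expected meioses until one crossover falls in an interduplicon interval.

    With genetic length d*r centimorgans, the per-meiosis recombination
    fraction is d*r/100, so the waiting time is its reciprocal. Valid in the
    small-interval regime (genetic length well below 50 cM).
    """
    if distance_mb <= 0 or rate_cm_per_mb <= 0:
        raise ParameterError("distance and rate must be positive")
    cm = distance_mb * rate_cm_per_mb
    if cm >= 50:
        raise ParameterError(
            "interval exceeds the small-interval approximation (>= 50 cM)"
        )
    return 100.0 / cm
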
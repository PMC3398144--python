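"""Two-paralog locus model: probe map, PSV catalog, haplotypes, dosage.

The model targets loci like PMS2/PMS2CL on 7p22: a functional gene and a
highly similar pseudogene in an inverted sister duplicon, with interparalog
recombination producing hybrid alleles. Probe sites and paralogous sequence
variants (PSVs) live on a transcript-ordered axis; haplotype structure
(origin tracts, deletions) is expressed at exon-group granularity, which is
the resolution at which MLPA dosage can localize events. Finer structure —
the PSV-by-PSV crossover signature inside an intron — is carried as per-PSV
origin overrides on the haplotype.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    HaplotypeInvariantError,
    LocusConfigError,
    RangeError,
)
from .hgvs import HgvsPosition, hgvs_span_length, parse_hgvs

__all__ = [
    "GENE",
    "PSEUDOGENE",
    "UNIVERSAL",
    "REFERENCE",
    "GENE_LOCUS",
    "PSEUDOGENE_LOCUS",
    "ProbeSite",
    "PSVRecord",
    "Segment",
    "Haplotype",
    "DiploidGenotype",
    "LocusMap",
    "load_locus_map",
    "packaged_locus_path",
    "expected_copy_vector",
    "hgvs_span_length",
]

# Probe specificities / segment origins.
GENE = "gene"
PSEUDOGENE = "pseudogene"
UNIVERSAL = "universal"
REFERENCE = "reference"

# Haplotype loci.
GENE_LOCUS = "gene_locus"
PSEUDOGENE_LOCUS = "pseudogene_locus"

_SPECIFICITIES = {GENE, PSEUDOGENE, UNIVERSAL, REFERENCE}
_PSV_KINDS = {"substitution", "insertion", "deletion", "duplication"}
_PSV_CONSEQUENCES = {"synonymous", "missense", "frameshift", "utr", "intronic"}


@dataclass(frozen=True)
class ProbeSite:
    """One MLPA probe ligation site.

    ``rank`` orders sites 5'->3' along the transcript; reference (control)
    probes sit outside the locus and carry no HGVS position.
    """

    id: str
    exon_label: str
    rank: int
    specificity: str
    ligation_pos: str | None = None
    position: HgvsPosition | None = field(default=None, compare=False)


@dataclass(frozen=True)
class PSVRecord:
    """A paralogous sequence variant: fixed gene/pseudogene difference."""

    id: str
    position: str
    gene_allele: str
    pseudogene_allele: str
    kind: str
    gene_context_consequence: str
    pos: HgvsPosition = field(default=None, compare=False)  # type: ignore[assignment]


@dataclass(frozen=True)
class Segment:
    """Contiguous run of exon groups [start, end] with one paralog origin."""

    start: int
    end: int
    origin: str


@dataclass(frozen=True)
class Haplotype:
    """One physical copy at the gene or pseudogene locus.

    ``segments`` tile the whole exon-group axis; ``deletions`` (gene locus
    only) list deleted group intervals. ``psv_origins`` overrides the
    segment-derived origin for individual PSVs, which is how sub-exon
    breakpoint signatures (e.g. an intron-10 crossover tract) are encoded.
    """

    locus: str
    segments: tuple[Segment, ...]
    deletions: tuple[tuple[int, int], ...] = ()
    label: str = ""
    conversion_tract: bool = False
    psv_origins: Mapping[str, str] = field(default_factory=dict)

    def origin_at(self, group_index: int) -> str:
        for seg in self.segments:
            if seg.start <= group_index <= seg.end:
                return seg.origin
        raise HaplotypeInvariantError(
            f"haplotype {self.label!r}: no segment covers group {group_index}"
        )

    def is_deleted(self, group_index: int) -> bool:
        return any(a <= group_index <= b for a, b in self.deletions)

    @property
    def n_events(self) -> int:
        transitions = sum(
            1
            for s1, s2 in zip(self.segments, self.segments[1:])
            if s1.origin != s2.origin
        )
        return transitions + len(self.deletions)


def pure_haplotype(locus: str, n_groups: int, label: str = "") -> Haplotype:
    origin = GENE if locus == GENE_LOCUS else PSEUDOGENE
    return Haplotype(locus, (Segment(0, n_groups - 1, origin),), label=label or origin)


def suffix_hybrid(
    locus: str,
    n_groups: int,
    tract_start: int,
    label: str = "",
    psv_origins: Mapping[str, str] | None = None,
) -> Haplotype:
    """Single-crossover hybrid: host origin up to ``tract_start``-1, donor after."""
    host = GENE if locus == GENE_LOCUS else PSEUDOGENE
    donor = PSEUDOGENE if locus == GENE_LOCUS else GENE
    if tract_start <= 0 or tract_start >= n_groups:
        raise HaplotypeInvariantError("tract_start must split the axis")
    return Haplotype(
        locus,
        (Segment(0, tract_start - 1, host), Segment(tract_start, n_groups - 1, donor)),
        label=label,
        psv_origins=dict(psv_origins or {}),
    )


@dataclass(frozen=True)
class DiploidGenotype:
    """Two gene-locus and two pseudogene-locus haplotypes, optionally phased."""

    gene_haplotypes: tuple[Haplotype, Haplotype]
    pseudogene_haplotypes: tuple[Haplotype, Haplotype]
    phasing: tuple[tuple[int, int], ...] | None = None
    label: str = ""

    @property
    def haplotypes(self) -> tuple[Haplotype, ...]:
        return self.gene_haplotypes + self.pseudogene_haplotypes

    @property
    def n_events(self) -> int:
        return sum(h.n_events for h in self.haplotypes)


class LocusMap:
    """Exon/probe/PSV geometry of a gene and its pseudogene paralog."""

    def __init__(
        self,
        name: str,
        probe_sites: Sequence[ProbeSite],
        psv_catalog: Sequence[PSVRecord],
        exon_spans: Mapping[str, tuple[int, int]],
        pseudogene_exons: Iterable[str],
        exon10_span_kb: float = 2.7,
        duplicon_inverted: bool = True,
        interduplicon_distance_mb: float = 0.7,
        asp_assay: Mapping | None = None,
    ):
        self.name = name
        self.probe_sites = tuple(probe_sites)
        self.psv_catalog = tuple(
            sorted(psv_catalog, key=lambda r: r.pos.sort_key())
        )
        self.exon_spans = dict(exon_spans)
        self.pseudogene_exons = frozenset(pseudogene_exons)
        self.exon10_span_kb = exon10_span_kb
        self.duplicon_inverted = duplicon_inverted
        self.interduplicon_distance_mb = interduplicon_distance_mb
        self.asp_assay = dict(asp_assay) if asp_assay else None

        self.site_groups = self._derive_groups()
        self._group_index = {g: i for i, g in enumerate(self.site_groups)}
        for s in self.probe_sites:
            if s.specificity != REFERENCE and s.exon_label not in self._group_index:
                raise LocusConfigError(
                    f"probe_sites[{s.id}].exon_label: unknown group {s.exon_label!r}"
                )
        self._site_by_id = {s.id: s for s in self.probe_sites}

    # -- axis ----------------------------------------------------------------

    def _derive_groups(self) -> tuple[str, ...]:
        """Order exon groups by probe position (intron groups interleave)."""
        first_pos: dict[str, tuple[int, int]] = {}
        for s in self.probe_sites:
            if s.specificity == REFERENCE or s.position is None:
                continue
            key = s.position.sort_key()
            if s.exon_label not in first_pos or key < first_pos[s.exon_label]:
                first_pos[s.exon_label] = key
        return tuple(sorted(first_pos, key=first_pos.__getitem__))

    @property
    def n_groups(self) -> int:
        return len(self.site_groups)

    def group_index(self, label: str) -> int:
        try:
            return self._group_index[label]
        except KeyError:
            raise RangeError(f"unknown site group {label!r}") from None

    @property
    def first_shared_group(self) -> int:
        """First group present at the pseudogene locus (duplicon inner end)."""
        return min(self._group_index[g] for g in self.pseudogene_exons)

    # -- probes --------------------------------------------------------------

    def site(self, site_id: str) -> ProbeSite:
        try:
            return self._site_by_id[site_id]
        except KeyError:
            raise RangeError(f"unknown probe site {site_id!r}") from None

    @property
    def assay_sites(self) -> tuple[ProbeSite, ...]:
        """Locus probes, excluding off-locus reference probes."""
        return tuple(s for s in self.probe_sites if s.specificity != REFERENCE)

    @property
    def reference_sites(self) -> tuple[ProbeSite, ...]:
        return tuple(s for s in self.probe_sites if s.specificity == REFERENCE)

    def sites_with_specificity(self, spec: str) -> tuple[ProbeSite, ...]:
        return tuple(s for s in self.probe_sites if s.specificity == spec)

    def discriminating_sites(
        self, from_label: str = "E11"
    ) -> tuple[ProbeSite, ...]:
        """Gene/pseudogene-specific sites at or 3' of ``from_label``.

        These are the sites the reference-qualification (2:2) rule inspects.
        """
        lo = self.group_index(from_label)
        return tuple(
            s
            for s in self.assay_sites
            if s.specificity in (GENE, PSEUDOGENE)
            and self.group_index(s.exon_label) >= lo
        )

    def expected_reference_copies(self, site: ProbeSite) -> int:
        return 4 if site.specificity == UNIVERSAL else 2

    # -- PSVs ----------------------------------------------------------------

    def psv_group(self, psv: PSVRecord) -> int:
        return self._group_of_position(psv.pos)

    def _group_of_position(self, pos: HgvsPosition) -> int:
        if pos.utr3:
            # 3' UTR travels with the last exon.
            return self.n_groups - 1
        spans = self.exon_spans
        if pos.offset == 0:
            for label, (a, b) in spans.items():
                if a <= pos.anchor <= b:
                    return self.group_index(label)
            raise RangeError(f"position {pos} outside all exon spans")
        # Intronic: anchored to the start (offset<0) or end (offset>0) of an
        # exon. If the axis has an explicit intron group adjacent to that
        # boundary, the position belongs to it; otherwise to the anchor exon.
        for label, (a, b) in spans.items():
            if pos.offset < 0 and pos.anchor == a:
                gi = self.group_index(label)
                prev = self.site_groups[gi - 1] if gi > 0 else None
                if prev is not None and prev not in spans:
                    return gi - 1
                return gi
            if pos.offset > 0 and pos.anchor == b:
                gi = self.group_index(label)
                nxt = self.site_groups[gi + 1] if gi + 1 < self.n_groups else None
                if nxt is not None and nxt not in spans:
                    return gi + 1
                return gi
        raise RangeError(f"intronic position {pos} has no anchoring exon boundary")

    def psvs_in_region(
        self, start: "HgvsPosition | str", end: "HgvsPosition | str"
    ) -> tuple[PSVRecord, ...]:
        a = start if isinstance(start, HgvsPosition) else parse_hgvs(start)
        b = end if isinstance(end, HgvsPosition) else parse_hgvs(end)
        ka, kb = sorted((a.sort_key(), b.sort_key()))
        lo = self.psv_catalog[0].pos.sort_key()
        hi = self.psv_catalog[-1].pos.sort_key()
        if kb < lo or ka > hi:
            raise RangeError(f"region {a}..{b} lies outside the PSV catalog")
        return tuple(r for r in self.psv_catalog if ka <= r.pos.sort_key() <= kb)

    # -- haplotype validation ------------------------------------------------

    def validate_haplotype(self, h: Haplotype) -> None:
        segs = h.segments
        if not segs:
            raise HaplotypeInvariantError(f"{h.label!r}: no segments")
        if segs[0].start != 0 or segs[-1].end != self.n_groups - 1:
            raise HaplotypeInvariantError(
                f"{h.label!r}: segments must tile groups 0..{self.n_groups - 1}"
            )
        for s1, s2 in zip(segs, segs[1:]):
            if s2.start != s1.end + 1:
                raise HaplotypeInvariantError(
                    f"{h.label!r}: segments overlap or leave a gap at {s2.start}"
                )
        transitions = sum(
            1 for s1, s2 in zip(segs, segs[1:]) if s1.origin != s2.origin
        )
        if transitions > 1 and not h.conversion_tract:
            raise HaplotypeInvariantError(
                f"{h.label!r}: >1 origin transition without conversion_tract flag"
            )
        if h.locus == GENE_LOCUS:
            # Pseudogene-derived tracts cannot extend 5' of the duplicon.
            for seg in segs:
                if seg.origin == PSEUDOGENE and seg.start < self.first_shared_group:
                    raise HaplotypeInvariantError(
                        f"{h.label!r}: pseudogene origin 5' of the shared duplicon"
                    )
        else:
            if h.deletions:
                raise HaplotypeInvariantError(
                    f"{h.label!r}: deletions are modeled at the gene locus only"
                )
        for a, b in h.deletions:
            if not (0 <= a <= b <= self.n_groups - 1):
                raise HaplotypeInvariantError(
                    f"{h.label!r}: deletion ({a},{b}) outside the group axis"
                )

    def validate_genotype(self, g: DiploidGenotype) -> None:
        if len(g.gene_haplotypes) != 2 or len(g.pseudogene_haplotypes) != 2:
            raise HaplotypeInvariantError("genotype needs 2+2 haplotypes")
        for h in g.gene_haplotypes:
            if h.locus != GENE_LOCUS:
                raise HaplotypeInvariantError("gene_haplotypes must be gene_locus")
            self.validate_haplotype(h)
        for h in g.pseudogene_haplotypes:
            if h.locus != PSEUDOGENE_LOCUS:
                raise HaplotypeInvariantError(
                    "pseudogene_haplotypes must be pseudogene_locus"
                )
            self.validate_haplotype(h)

    # -- dosage --------------------------------------------------------------

    def haplotype_contribution(self, h: Haplotype, site: ProbeSite) -> int:
        """0/1 copies this haplotype contributes at a probe site."""
        if site.specificity == REFERENCE:
            raise ValueError("reference probes are genome-wide, not per-haplotype")
        gi = self.group_index(site.exon_label)
        label = site.exon_label
        if h.locus == PSEUDOGENE_LOCUS and label not in self.pseudogene_exons:
            return 0  # structurally absent from the pseudogene locus
        if h.is_deleted(gi):
            return 0
        origin = h.origin_at(gi)
        if (
            h.locus == GENE_LOCUS
            and origin == PSEUDOGENE
            and label not in self.pseudogene_exons
        ):
            return 0  # pseudogene-derived tract lacks exon 10
        if site.specificity == UNIVERSAL:
            return 1
        return 1 if origin == site.specificity else 0


def expected_copy_vector(
    g: DiploidGenotype, m: LocusMap
) -> dict[str, int]:
    """Noise-free integer copies per probe site for a diploid genotype.

    Universal sites count both origins; paralog-specific sites count matching
    origins only; autosomal reference probes are always two copies.
    """
    m.validate_genotype(g)
    out: dict[str, int] = {}
    for site in m.probe_sites:
        if site.specificity == REFERENCE:
            out[site.id] = 2
        else:
            out[site.id] = sum(
                m.haplotype_contribution(h, site) for h in g.haplotypes
            )
    return out


# -- configuration loading ---------------------------------------------------


def packaged_locus_path() -> Path:
    """Path of the packaged PMS2/PMS2CL locus description."""
    return Path(
        importlib.resources.files("paralogmlpa").joinpath("data/pms2_pms2cl.yaml")
    )


def _require(cfg: Mapping, key: str, context: str):
    if key not in cfg:
        raise LocusConfigError(f"{context}: missing required field {key!r}")
    return cfg[key]


def load_locus_map(source: "str | Path | Mapping") -> LocusMap:
    """Load and validate a locus configuration (YAML/JSON path or mapping).

    Raises :class:`LocusConfigError` naming the offending field on any
    schema violation.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if not isinstance(cfg, Mapping):
        raise LocusConfigError("config: top level must be a mapping")

    geometry = _require(cfg, "geometry", "config")
    probes_cfg = _require(cfg, "probe_sites", "config")
    psvs_cfg = _require(cfg, "psv_catalog", "config")
    exon_spans_raw = _require(geometry, "exon_spans", "geometry")
    pseudo_exons = _require(geometry, "pseudogene_exons", "geometry")

    exon_spans: dict[str, tuple[int, int]] = {}
    for label, span in exon_spans_raw.items():
        if (
            not isinstance(span, (list, tuple))
            or len(span) != 2
            or not all(isinstance(x, int) for x in span)
            or span[0] > span[1]
        ):
            raise LocusConfigError(
                f"geometry.exon_spans[{label}]: expected [start, end] integers"
            )
        exon_spans[label] = (span[0], span[1])

    parsed: list[tuple] = []
    seen_ids: set[str] = set()
    for i, p in enumerate(probes_cfg):
        ctx = f"probe_sites[{i}]"
        pid = _require(p, "id", ctx)
        if pid in seen_ids:
            raise LocusConfigError(f"{ctx}.id: duplicate probe id {pid!r}")
        seen_ids.add(pid)
        spec = _require(p, "specificity", ctx)
        if spec not in _SPECIFICITIES:
            raise LocusConfigError(f"{ctx}.specificity: invalid value {spec!r}")
        exon_label = _require(p, "exon_label", ctx)
        lig = p.get("ligation_pos")
        pos = None
        if spec != REFERENCE:
            if lig is None:
                raise LocusConfigError(f"{ctx}.ligation_pos: required for {spec} probes")
            pos = parse_hgvs(str(lig))
        parsed.append((str(pid), str(exon_label), spec, lig, pos))

    # Ranks follow the transcript-ordered 5'->3' axis; co-located probe pairs
    # (e.g. the gene/pseudogene intron-12 probes) keep their config order.
    locus_probes = [t for t in parsed if t[2] != REFERENCE]
    ref_probes = [t for t in parsed if t[2] == REFERENCE]
    locus_probes.sort(key=lambda t: t[4].sort_key())
    probe_sites = [
        ProbeSite(
            id=pid,
            exon_label=exon_label,
            rank=rank,
            specificity=spec,
            ligation_pos=str(lig) if lig is not None else None,
            position=pos,
        )
        for rank, (pid, exon_label, spec, lig, pos) in enumerate(
            locus_probes + ref_probes
        )
    ]

    psv_catalog: list[PSVRecord] = []
    for i, r in enumerate(psvs_cfg):
        ctx = f"psv_catalog[{i}]"
        kind = _require(r, "kind", ctx)
        if kind not in _PSV_KINDS:
            raise LocusConfigError(f"{ctx}.kind: invalid value {kind!r}")
        cons = _require(r, "gene_context_consequence", ctx)
        if cons not in _PSV_CONSEQUENCES:
            raise LocusConfigError(
                f"{ctx}.gene_context_consequence: invalid value {cons!r}"
            )
        ga = str(_require(r, "gene_allele", ctx))
        pa = str(_require(r, "pseudogene_allele", ctx))
        if ga == pa:
            raise LocusConfigError(
                f"{ctx}: gene_allele equals pseudogene_allele ({ga!r})"
            )
        position = str(_require(r, "position", ctx))
        psv_catalog.append(
            PSVRecord(
                id=str(_require(r, "id", ctx)),
                position=position,
                gene_allele=ga,
                pseudogene_allele=pa,
                kind=kind,
                gene_context_consequence=cons,
                pos=parse_hgvs(position),
            )
        )

    m = LocusMap(
        name=str(cfg.get("name", "locus")),
        probe_sites=probe_sites,
        psv_catalog=psv_catalog,
        exon_spans=exon_spans,
        pseudogene_exons=pseudo_exons,
        exon10_span_kb=float(geometry.get("exon10_span_kb", 2.7)),
        duplicon_inverted=bool(geometry.get("duplicon_inverted", True)),
        interduplicon_distance_mb=float(
            geometry.get("interduplicon_distance_mb", 0.7)
        ),
        asp_assay=cfg.get("asp_assay"),
    )
    # Every PSV must be placeable on the group axis (orderable vs probes).
    for r in m.psv_catalog:
        m.psv_group(r)
    return m


_PACKAGED: LocusMap | None = None


def packaged_locus() -> LocusMap:
    """The packaged PMS2/PMS2CL map (cached)."""
    global _PACKAGED
    if _PACKAGED is None:
        _PACKAGED = load_locus_map(packaged_locus_path())
    return _PACKAGED
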
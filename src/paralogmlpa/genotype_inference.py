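"""Diploid genotype enumeration from called copy-number profiles.

MLPA dosage at a duplicated locus under-determines the genotype: a probe
only counts how many haplotypes carry its paralog-specific sequence, not
which locus they sit at. This module enumerates every diploid configuration
(two gene-locus and two pseudogene-locus haplotypes, each with at most one
crossover breakpoint or one contiguous deletion) whose noise-free copy
vector reproduces the called profile, ranks configurations by event count,
classifies alleles, and flags the dosage-invisible "masked" configuration
(a deleterious hybrid travelling with its reciprocal hybrid, balancing every
probe back to 2:2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .locus_model import (
    GENE,
    GENE_LOCUS,
    PSEUDOGENE,
    PSEUDOGENE_LOCUS,
    REFERENCE,
    DiploidGenotype,
    Haplotype,
    LocusMap,
    Segment,
    pure_haplotype,
    suffix_hybrid,
)
from .mlpa_calling import NO_CALL, CopyNumberProfile

__all__ = [
    "AlleleClass",
    "Constraints",
    "GenotypeSolutionSet",
    "SampleReport",
    "classify_haplotype",
    "enumerate_genotypes",
    "interpret_sample",
]

# Allele classes, ordered by severity for reporting.
NORMAL = "normal"
NONDELETERIOUS_HYBRID = "nondeleterious_hybrid"
DELETERIOUS_HYBRID = "deleterious_hybrid"
EXON_DELETION = "exon_deletion"
WHOLE_GENE_DELETION = "whole_gene_deletion"

_DELETERIOUS = {DELETERIOUS_HYBRID, EXON_DELETION, WHOLE_GENE_DELETION}


@dataclass(frozen=True)
class AlleleClass:
    value: str

    @property
    def deleterious(self) -> bool:
        return self.value in _DELETERIOUS


def classify_haplotype(h: Haplotype, m: LocusMap) -> AlleleClass:
    """Classify a gene-locus haplotype.

    Whole-gene deletion if every group is deleted; exon deletion if any probe
    group is deleted; deleterious hybrid if the pseudogene-derived tract
    reaches exon 11 (whose pseudogene alleles frameshift the gene) or starts
    5' of it (loss of exon 10, absent from the pseudogene); nondeleterious
    hybrid for tracts confined to the exon 12 .. 3'UTR region, where the
    pseudogene alleles do not truncate the reading frame.
    """
    if h.locus != GENE_LOCUS:
        raise ParameterError(
            "classify_haplotype applies to gene-locus haplotypes only"
        )
    n = m.n_groups
    deleted = set()
    for a, b in h.deletions:
        deleted.update(range(a, b + 1))
    if len(deleted) == n:
        return AlleleClass(WHOLE_GENE_DELETION)
    if deleted:
        return AlleleClass(EXON_DELETION)
    pseudo_groups = {
        gi
        for seg in h.segments
        if seg.origin == PSEUDOGENE
        for gi in range(seg.start, seg.end + 1)
    }
    if not pseudo_groups:
        return AlleleClass(NORMAL)
    e11 = m.group_index("E11")
    if min(pseudo_groups) <= e11:
        return AlleleClass(DELETERIOUS_HYBRID)
    return AlleleClass(NONDELETERIOUS_HYBRID)


@dataclass(frozen=True)
class Constraints:
    """Bounds on the enumeration space (events per haplotype)."""

    max_breakpoints_per_haplotype: int = 1
    max_deletions_per_haplotype: int = 1
    allow_combined_events: bool = False  # breakpoint AND deletion on one hap


@dataclass
class Solution:
    genotype: DiploidGenotype
    n_events: int
    allele_classes: tuple[str, ...]  # gene-locus haplotypes only

    @property
    def deleterious(self) -> bool:
        return any(c in _DELETERIOUS for c in self.allele_classes)


@dataclass
class GenotypeSolutionSet:
    profile_id: str
    solutions: list[Solution]
    classification: str  # normal | deleterious | ambiguous | uninterpretable
    notes: str = ""
    masked_risk: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def minimal_solutions(self) -> list[Solution]:
        if not self.solutions:
            return []
        best = self.solutions[0].n_events
        return [s for s in self.solutions if s.n_events == best]


# -- haplotype candidate spaces ----------------------------------------------


def _gene_candidates(m: LocusMap, c: Constraints) -> list[Haplotype]:
    n = m.n_groups
    out = [pure_haplotype(GENE_LOCUS, n, "g")]
    if c.max_breakpoints_per_haplotype >= 1:
        for start in range(max(m.first_shared_group, 1), n):
            out.append(
                suffix_hybrid(GENE_LOCUS, n, start, f"g->p@{m.site_groups[start]}")
            )
    if c.max_deletions_per_haplotype >= 1:
        hosts = out if c.allow_combined_events else out[:1]
        with_del = []
        for h in hosts:
            for a in range(n):
                for b in range(a, n):
                    with_del.append(
                        Haplotype(
                            GENE_LOCUS,
                            h.segments,
                            ((a, b),),
                            label=h.label + f" del[{m.site_groups[a]}..{m.site_groups[b]}]",
                        )
                    )
        out.extend(with_del)
    return out


def _pseudo_candidates(m: LocusMap, c: Constraints) -> list[Haplotype]:
    n = m.n_groups
    out = [pure_haplotype(PSEUDOGENE_LOCUS, n, "p")]
    if c.max_breakpoints_per_haplotype >= 1:
        # Gene-derived suffixes start at or after exon 11: a crossover 5' of
        # it would have to transfer exon 10, which the pseudogene locus lacks.
        for start in range(m.group_index("E11"), n):
            out.append(
                suffix_hybrid(
                    PSEUDOGENE_LOCUS, n, start, f"p->g@{m.site_groups[start]}"
                )
            )
    return out


def _contribution_matrix(
    haps: Sequence[Haplotype], sites, m: LocusMap
) -> np.ndarray:
    mat = np.zeros((len(haps), len(sites)), dtype=np.int8)
    for i, h in enumerate(haps):
        for j, s in enumerate(sites):
            mat[i, j] = m.haplotype_contribution(h, s)
    return mat


# -- enumeration --------------------------------------------------------------


def enumerate_genotypes(
    p: CopyNumberProfile,
    m: LocusMap,
    constraints: Constraints | None = None,
) -> GenotypeSolutionSet:
    """Exhaustive bounded search for genotypes matching a called profile.

    NO_CALL sites are unconstrained. Solutions are ordered by total event
    count (breakpoints + deletions), ties broken by fewer deleterious
    alleles, then by a lexicographic haplotype encoding, so reports are
    deterministic. Classification follows the minimal-event solutions;
    ``masked_risk`` is set when a deleterious configuration at a higher
    event count also reproduces the profile.
    """
    constraints = constraints or Constraints()
    sites = [s for s in m.assay_sites]
    called_idx = [
        j for j, s in enumerate(sites) if p.calls[s.id].copies != NO_CALL
    ]
    if not called_idx:
        return GenotypeSolutionSet(
            p.sample_id, [], "uninterpretable", notes="no called sites"
        )
    target = np.array(
        [p.calls[sites[j].id].copies for j in called_idx], dtype=np.int8
    )

    gene_haps = _gene_candidates(m, constraints)
    pseudo_haps = _pseudo_candidates(m, constraints)
    gmat = _contribution_matrix(gene_haps, sites, m)[:, called_idx]
    pmat = _contribution_matrix(pseudo_haps, sites, m)[:, called_idx]

    # Unordered index pairs for each locus.
    g_pairs = [(i, j) for i in range(len(gene_haps)) for j in range(i, len(gene_haps))]
    p_pairs = [(i, j) for i in range(len(pseudo_haps)) for j in range(i, len(pseudo_haps))]
    g_sums = np.array([gmat[i] + gmat[j] for i, j in g_pairs], dtype=np.int8)
    keyed: dict[bytes, list[int]] = {}
    for idx, row in enumerate(g_sums):
        keyed.setdefault(row.tobytes(), []).append(idx)

    solutions: list[Solution] = []
    for pi, pj in p_pairs:
        residual = target - (pmat[pi] + pmat[pj])
        if residual.min() < 0:
            continue
        for g_idx in keyed.get(residual.astype(np.int8).tobytes(), ()):
            gi, gj = g_pairs[g_idx]
            hg = (gene_haps[gi], gene_haps[gj])
            hp = (pseudo_haps[pi], pseudo_haps[pj])
            genotype = DiploidGenotype(hg, hp, label=p.sample_id)
            classes = tuple(classify_haplotype(h, m).value for h in hg)
            solutions.append(
                Solution(genotype, genotype.n_events, classes)
            )

    if not solutions:
        diag = _closest_vector_diagnostics(
            target, called_idx, sites, g_sums, g_pairs, pmat, p_pairs
        )
        return GenotypeSolutionSet(
            p.sample_id,
            [],
            "uninterpretable",
            notes="no genotype within constraint bounds matches the profile",
            diagnostics=diag,
        )

    solutions.sort(
        key=lambda s: (
            s.n_events,
            sum(c in _DELETERIOUS for c in s.allele_classes),
            _encode(s.genotype),
        )
    )
    best = solutions[0].n_events
    minimal = [s for s in solutions if s.n_events == best]
    min_del = [s.deleterious for s in minimal]
    if all(min_del):
        classification = "deleterious"
    elif any(min_del):
        classification = "ambiguous"
    else:
        classification = "normal"
    masked_risk = classification != "deleterious" and any(
        s.deleterious for s in solutions
    )
    notes = ""
    if masked_risk:
        notes = (
            "a deleterious configuration at a higher event count also matches "
            "this dosage profile (possible reciprocal-hybrid masking); "
            "allele-specific PCR across the breakpoint can resolve it"
        )
    return GenotypeSolutionSet(
        p.sample_id, solutions, classification, notes=notes, masked_risk=masked_risk
    )


def _encode(g: DiploidGenotype) -> tuple:
    def hap_key(h: Haplotype):
        return (
            tuple((s.start, s.end, s.origin) for s in h.segments),
            h.deletions,
        )

    return (
        tuple(sorted(hap_key(h) for h in g.gene_haplotypes)),
        tuple(sorted(hap_key(h) for h in g.pseudogene_haplotypes)),
    )


def _closest_vector_diagnostics(
    target, called_idx, sites, g_sums, g_pairs, pmat, p_pairs
):
    """Best-matching expected vectors for an unsatisfiable profile."""
    best_dist = None
    best_vec = None
    for pi, pj in p_pairs:
        base = pmat[pi] + pmat[pj]
        dists = np.abs(g_sums + base - target).sum(axis=1)
        k = int(dists.argmin())
        if best_dist is None or dists[k] < best_dist:
            best_dist = int(dists[k])
            best_vec = (g_sums[k] + base).tolist()
    return {
        "closest_distance": best_dist,
        "closest_vector": {
            sites[j].id: int(v) for j, v in zip(called_idx, best_vec or [])
        },
    }


# -- sample-level interpretation ----------------------------------------------


@dataclass
class SampleReport:
    sample_id: str
    aberrant: bool
    classification: str
    solution_set: GenotypeSolutionSet
    recommended_follow_up: str = ""
    deviant_sites: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        minimal = self.solution_set.minimal_solutions
        return {
            "sample_id": self.sample_id,
            "aberrant": self.aberrant,
            "classification": self.classification,
            "deviant_sites": list(self.deviant_sites),
            "masked_risk": self.solution_set.masked_risk,
            "recommended_follow_up": self.recommended_follow_up,
            "n_solutions": len(self.solution_set.solutions),
            "minimal_event_solutions": [
                {
                    "n_events": s.n_events,
                    "gene_allele_classes": list(s.allele_classes),
                    "haplotypes": [
                        h.label for h in s.genotype.haplotypes
                    ],
                }
                for s in minimal
            ],
            "notes": self.solution_set.notes,
        }


def interpret_sample(
    p: CopyNumberProfile,
    m: LocusMap,
    constraints: Constraints | None = None,
) -> SampleReport:
    """Flag dosage aberration, classify, and recommend follow-up.

    A sample is aberrant iff any called site deviates from the reference
    configuration (2 gene-specific, 2 pseudogene-specific, 4 universal).
    When a deleterious configuration could hide behind a balanced profile,
    the report recommends the breakpoint allele-specific PCR assay.
    """
    deviant = tuple(
        s.id
        for s in m.assay_sites
        if p.calls[s.id].copies != NO_CALL
        and p.calls[s.id].copies != m.expected_reference_copies(s)
    )
    solset = enumerate_genotypes(p, m, constraints)
    follow_up = ""
    if solset.masked_risk:
        follow_up = (
            "breakpoint allele-specific PCR (insilico_asp) to exclude a "
            "masked deleterious hybrid with reciprocal hybrid"
        )
    elif solset.classification == "deleterious":
        follow_up = "confirm by cDNA sequencing / breakpoint PCR"
    return SampleReport(
        sample_id=p.sample_id,
        aberrant=bool(deviant),
        classification=solset.classification,
        solution_set=solset,
        recommended_follow_up=follow_up,
        deviant_sites=deviant,
    )
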
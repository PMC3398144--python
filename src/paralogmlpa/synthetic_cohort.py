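"""Synthetic diploid genotypes and MLPA signals for a two-paralog locus.

Everything the real study obtained from patients and repository DNAs is
emulated here: population backgrounds in which nondeleterious hybrid alleles
are common (carrier fraction ~0.70 in Caucasians), the three patient
archetypes (whole-gene deletion; single-exon deletion; intron-10 crossover
hybrid), multiplicative noise around integer copy ratios, reference-candidate
panels of which only a fraction meet the 2:2 criterion, and PSV origin
readouts of breakpoint-spanning amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ParameterError, RangeError
from .hgvs import HgvsPosition, parse_hgvs
from .locus_model import (
    GENE,
    GENE_LOCUS,
    PSEUDOGENE,
    PSEUDOGENE_LOCUS,
    REFERENCE,
    DiploidGenotype,
    Haplotype,
    LocusMap,
    PSVRecord,
    Segment,
    expected_copy_vector,
    packaged_locus,
    pure_haplotype,
    suffix_hybrid,
)

__all__ = [
    "ARCHETYPES",
    "PopulationModel",
    "NoiseModel",
    "ProbeSignalSet",
    "make_case_genotype",
    "sample_population_genotype",
    "simulate_probe_signals",
    "make_reference_candidates",
    "simulate_psv_readout",
    "random_genotype",
    "signals_to_frame",
]

ARCHETYPES = ("NORMAL", "CH8", "CH11", "TR13", "TR13_MASKED")

BASE_SCALE = 100.0  # arbitrary raw-signal units for a two-copy target

# PSV-level origins across intron 10 for the packaged crossover haplotype:
# gene-specific variants at all discriminating sites 5' of c.1145-942
# (inclusive), pseudogene-specific from c.1145-790 (inclusive) on, and the
# crossover signature in between (pseudogene at -921; gene at -886 and the
# -880_-879 insertion).
CROSSOVER_TRACT = {
    "IVS10_1100": GENE,
    "IVS10_1000": GENE,
    "IVS10_942": GENE,
    "IVS10_921": PSEUDOGENE,
    "IVS10_886": GENE,
    "IVS10_880": GENE,
    "IVS10_790": PSEUDOGENE,
    "IVS10_700": PSEUDOGENE,
    "IVS10_650": PSEUDOGENE,
}
# Complementary pattern on the reciprocal hybrid pseudogene allele.
RECIPROCAL_TRACT = {
    k: (PSEUDOGENE if v == GENE else GENE) for k, v in CROSSOVER_TRACT.items()
}


@dataclass(frozen=True)
class PopulationModel:
    """Nondeleterious-background allele frequencies.

    ``p_hybrid_carrier`` is the fraction of individuals carrying at least one
    nondeleterious hybrid allele (gene or pseudogene locus).
    ``p_n775s_hybrid_allele`` is the population fraction of gene-locus alleles
    whose pseudogene-derived tract covers exon 14 (the p.N775S hybrid;
    reported 4-25% depending on ethnicity). Hybrid tracts start 3' of exon 12
    only; the rarer upstream events are injected deliberately via archetypes,
    never drawn as background.
    """

    p_hybrid_carrier: float = 0.70
    p_n775s_hybrid_allele: float = 0.10
    allowed_nondeleterious_breakpoints: tuple[str, ...] = (
        "IVS12",
        "E13",
        "E14",
        "E15",
    )

    def __post_init__(self):
        if not 0.0 <= self.p_hybrid_carrier <= 1.0:
            raise ParameterError("p_hybrid_carrier must lie in [0, 1]")
        if not 0.0 <= self.p_n775s_hybrid_allele <= 1.0:
            raise ParameterError("p_n775s_hybrid_allele must lie in [0, 1]")

    @property
    def per_allele_hybrid_prob(self) -> float:
        """q such that 1-(1-q)^4 equals the carrier fraction.

        Each of the four haplotypes (two per locus) is independently hybrid
        with probability q, so the carrier fraction is exact by construction.
        """
        return 1.0 - (1.0 - self.p_hybrid_carrier) ** 0.25

    def breakpoint_weights(self) -> dict[str, float]:
        """Tract-start weights consistent with the exon-14 allele fraction.

        P(tract covers E14 | hybrid) = p_n775s / q is split evenly over the
        starts 5' of the exon-14 probe sites; the remainder goes to E15-only
        tracts (the pattern seen for the c.*92dupA hybrid).
        """
        q = self.per_allele_hybrid_prob
        starts = list(self.allowed_nondeleterious_breakpoints)
        if q <= 0.0:
            return {s: 1.0 / len(starts) for s in starts}
        p_cover = min(1.0, self.p_n775s_hybrid_allele / q)
        covering = [s for s in starts if s != "E15"]
        weights = {s: p_cover / len(covering) for s in covering}
        weights["E15"] = 1.0 - p_cover
        return weights


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise on each probe signal."""

    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")


@dataclass(frozen=True)
class ProbeSignalSet:
    """Raw MLPA signals for one sample (arbitrary units)."""

    sample_id: str
    signals: Mapping[str, float]

    def check_against(self, m: LocusMap) -> None:
        from .errors import SchemaError

        want = {s.id for s in m.probe_sites}
        have = set(self.signals)
        if want != have:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise SchemaError(
                f"sample {self.sample_id!r}: probe mismatch "
                f"(missing {missing}, unexpected {extra})"
            )


# -- archetypes ---------------------------------------------------------------


def make_case_genotype(
    archetype: str, m: LocusMap | None = None
) -> DiploidGenotype:
    """Construct one of the documented diploid case archetypes.

    NORMAL: two pure gene and two pure pseudogene alleles (2:2 everywhere).
    CH8: whole-gene-locus deletion plus two hybrid pseudogene alleles with
        gene-derived exons 13-15 (three gene copies there, all universal
        probes see three of four copies).
    CH11: heterozygous single-exon (exon 8) deletion.
    TR13: deleterious gene-locus hybrid pseudogene-derived from exon 11
        (intron-10 crossover tract), a nondeleterious exon-15-only hybrid on
        the other gene allele, one pure pseudogene allele and one hybrid
        pseudogene allele gene-derived from exon 13.
    TR13_MASKED: the deleterious hybrid together with its reciprocal hybrid
        pseudogene allele — dosage-identical to NORMAL at every probe.
    """
    m = m or packaged_locus()
    n = m.n_groups
    gi = m.group_index

    def g_pure(label):
        return pure_haplotype(GENE_LOCUS, n, label)

    def p_pure(label):
        return pure_haplotype(PSEUDOGENE_LOCUS, n, label)

    if archetype == "NORMAL":
        return DiploidGenotype(
            (g_pure("g"), g_pure("g")),
            (p_pure("p"), p_pure("p")),
            label="NORMAL",
        )
    if archetype == "CH8":
        deleted = Haplotype(
            GENE_LOCUS,
            (Segment(0, n - 1, GENE),),
            deletions=((0, n - 1),),
            label="whole-gene deletion",
        )
        hyb = suffix_hybrid(
            PSEUDOGENE_LOCUS, n, gi("E13"), label="p->g from E13"
        )
        return DiploidGenotype(
            (deleted, g_pure("g")), (hyb, hyb), label="CH8"
        )
    if archetype == "CH11":
        e8 = gi("E8")
        del_hap = Haplotype(
            GENE_LOCUS,
            (Segment(0, n - 1, GENE),),
            deletions=((e8, e8),),
            label="exon-8 deletion",
        )
        return DiploidGenotype(
            (del_hap, g_pure("g")), (p_pure("p"), p_pure("p")), label="CH11"
        )
    if archetype in ("TR13", "TR13_MASKED"):
        deleterious = suffix_hybrid(
            GENE_LOCUS,
            n,
            gi("E11"),
            label="deleterious g->p from E11 (intron-10 crossover)",
            psv_origins=CROSSOVER_TRACT,
        )
        if archetype == "TR13":
            nondel = suffix_hybrid(
                GENE_LOCUS, n, gi("E15"), label="nondeleterious g->p at E15"
            )
            p_hyb = suffix_hybrid(
                PSEUDOGENE_LOCUS, n, gi("E13"), label="p->g from E13"
            )
            return DiploidGenotype(
                (deleterious, nondel), (p_pure("p"), p_hyb), label="TR13"
            )
        reciprocal = suffix_hybrid(
            PSEUDOGENE_LOCUS,
            n,
            gi("E11"),
            label="reciprocal p->g from E11",
            psv_origins=RECIPROCAL_TRACT,
        )
        return DiploidGenotype(
            (deleterious, g_pure("g")),
            (reciprocal, p_pure("p")),
            label="TR13_MASKED",
        )
    raise ParameterError(
        f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}"
    )


# -- population backgrounds ---------------------------------------------------


def sample_population_genotype(
    pm: PopulationModel, rng: np.random.Generator, m: LocusMap | None = None
) -> DiploidGenotype:
    """Draw a nondeleterious diploid genotype from the population model.

    Each of the four haplotypes is independently a hybrid with probability
    q = 1-(1-p_hybrid_carrier)^(1/4); hybrid tract starts are drawn from the
    allowed (3'-of-exon-12) breakpoints.
    """
    m = m or packaged_locus()
    n = m.n_groups
    q = pm.per_allele_hybrid_prob
    weights = pm.breakpoint_weights()
    starts = list(weights)
    probs = np.array([weights[s] for s in starts])

    def draw(locus: str, tag: str) -> Haplotype:
        if q > 0.0 and rng.random() < q:
            start_label = starts[rng.choice(len(starts), p=probs)]
            return suffix_hybrid(
                locus, n, m.group_index(start_label),
                label=f"{tag} hybrid from {start_label}",
            )
        return pure_haplotype(locus, n, tag)

    return DiploidGenotype(
        (draw(GENE_LOCUS, "g1"), draw(GENE_LOCUS, "g2")),
        (draw(PSEUDOGENE_LOCUS, "p1"), draw(PSEUDOGENE_LOCUS, "p2")),
        label="population",
    )


def random_genotype(
    rng: np.random.Generator,
    m: LocusMap | None = None,
    p_hybrid: float = 0.4,
    p_deletion: float = 0.2,
) -> DiploidGenotype:
    """Unconstrained random genotype (for property tests): hybrids anywhere in
    the shared region, deletions of arbitrary contiguous group runs."""
    m = m or packaged_locus()
    n = m.n_groups
    shared_lo = max(m.first_shared_group, 1)

    def gene_hap(tag: str) -> Haplotype:
        if rng.random() < p_hybrid:
            start = int(rng.integers(shared_lo, n))
            h = suffix_hybrid(GENE_LOCUS, n, start, label=f"{tag} g->p@{start}")
        else:
            h = pure_haplotype(GENE_LOCUS, n, tag)
        if rng.random() < p_deletion:
            a = int(rng.integers(0, n))
            b = int(rng.integers(a, n))
            h = Haplotype(
                h.locus, h.segments, ((a, b),), label=h.label + f" del({a},{b})"
            )
        return h

    def pseudo_hap(tag: str) -> Haplotype:
        if rng.random() < p_hybrid:
            start = int(rng.integers(m.group_index("E11"), n))
            return suffix_hybrid(
                PSEUDOGENE_LOCUS, n, start, label=f"{tag} p->g@{start}"
            )
        return pure_haplotype(PSEUDOGENE_LOCUS, n, tag)

    return DiploidGenotype(
        (gene_hap("g1"), gene_hap("g2")),
        (pseudo_hap("p1"), pseudo_hap("p2")),
        label="random",
    )


# -- signal simulation --------------------------------------------------------


def simulate_probe_signals(
    g: DiploidGenotype,
    nm: NoiseModel,
    m: LocusMap | None = None,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
    replicates: int = 1,
) -> ProbeSignalSet:
    """Forward model: signal = base * (true copies / reference copies) * noise.

    Reference copies are 2 for paralog-specific and control probes and 4 for
    universal probes; noise is iid lognormal with scale ``nm.sigma``. With
    ``rng`` unset, a generator seeded from ``nm.seed`` is used, so identical
    seeds reproduce identical tables. ``replicates > 1`` averages that many
    independent runs probe-by-probe, as diagnostic MLPA protocols do.
    """
    m = m or packaged_locus()
    rng = rng if rng is not None else np.random.default_rng(nm.seed)
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    truth = expected_copy_vector(g, m)
    signals: dict[str, float] = {}
    for site in m.probe_sites:
        ref = m.expected_reference_copies(site)
        base = BASE_SCALE * (truth[site.id] / ref)
        if nm.sigma > 0:
            factors = rng.lognormal(0.0, nm.sigma, size=replicates)
            signals[site.id] = float(base * np.mean(factors))
        else:
            signals[site.id] = float(base)
    return ProbeSignalSet(sample_id=sample_id, signals=signals)


def is_2_2(g: DiploidGenotype, m: LocusMap) -> bool:
    """True iff every E11-15 discriminating site carries 2 gene and 2
    pseudogene copies (the reference-qualification truth label)."""
    truth = expected_copy_vector(g, m)
    return all(truth[s.id] == 2 for s in m.discriminating_sites())


def make_reference_candidates(
    n: int,
    pm: PopulationModel,
    rng: np.random.Generator,
    m: LocusMap | None = None,
    nm: NoiseModel | None = None,
    replicates: int = 3,
) -> list[tuple[ProbeSignalSet, bool]]:
    """Simulate ``n`` reference-DNA candidates with 2:2 truth labels.

    Candidates are measured in triplicate by default (reference DNAs are
    characterized more carefully than routine samples).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    m = m or packaged_locus()
    nm = nm or NoiseModel()
    out: list[tuple[ProbeSignalSet, bool]] = []
    for i in range(n):
        g = sample_population_genotype(pm, rng, m)
        sig = simulate_probe_signals(
            g, nm, m, sample_id=f"cand{i:03d}", rng=rng, replicates=replicates
        )
        out.append((sig, is_2_2(g, m)))
    return out


# -- PSV readouts -------------------------------------------------------------


def psv_origin(h: Haplotype, psv: PSVRecord, m: LocusMap) -> str:
    """Paralog origin of the sequence a haplotype carries at one PSV."""
    if psv.id in h.psv_origins:
        return h.psv_origins[psv.id]
    return h.origin_at(m.psv_group(psv))


def simulate_psv_readout(
    h: Haplotype,
    region: "tuple[HgvsPosition | str, HgvsPosition | str]",
    m: LocusMap | None = None,
) -> list[tuple[PSVRecord, str]]:
    """Ordered (PSV, observed origin) calls for an amplicon over ``region``.

    The haplotype must cover the region (no deletion across it); conversion
    tracts and crossover signatures interleave origins via per-PSV overrides.
    """
    m = m or packaged_locus()
    a, b = region
    psvs = m.psvs_in_region(a, b)
    for r in psvs:
        if h.is_deleted(m.psv_group(r)):
            raise RangeError(
                f"haplotype {h.label!r} does not cover PSV {r.id} (deleted)"
            )
    return [(r, psv_origin(h, r, m)) for r in psvs]


# -- tabular output -----------------------------------------------------------


def signals_to_frame(samples: Iterable[ProbeSignalSet], m: LocusMap):
    """Samples x probes DataFrame (TSV-ready, probe ids as columns)."""
    import pandas as pd

    cols = [s.id for s in m.probe_sites]
    rows = {s.sample_id: [s.signals[c] for c in cols] for s in samples}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
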
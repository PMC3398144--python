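"""Dosage-quotient analysis: raw probe signals -> integer copy calls.

Normalization follows the standard MLPA two-step: each sample is first scaled
within itself (here by the median over the kit's autosomal reference probes,
which are unaffected by locus CNVs), then divided probe-by-probe by the mean
of the same quantity over a qualified reference panel. A relative signal of
1.0 then means two copies at a paralog-specific probe and four at a universal
probe; 0.5 means one copy, 1.5 three; 0.75 at a universal probe means three
of four copies.

Reference qualification implements the 2:2 prerequisite: a DNA is a valid
reference only if it carries exactly two gene-specific and two
pseudogene-specific copies of every discriminating sequence in exons 11-15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateSampleError,
    PanelConstructionError,
    ParameterError,
    SchemaError,
)
from .locus_model import GENE, PSEUDOGENE, REFERENCE, LocusMap, ProbeSite
from .synthetic_cohort import ProbeSignalSet

__all__ = [
    "NO_CALL",
    "CopyNumberProfile",
    "ReferencePanel",
    "QCVerdict",
    "normalize_signals",
    "call_copy_numbers",
    "qc_reference",
    "build_panel",
]

NO_CALL = "NO_CALL"

DEFAULT_BAND = 0.1  # fraction of the reference copy number
MAX_COPIES = 4


@dataclass(frozen=True)
class ProbeCall:
    relative_signal: float
    copies: "int | str"  # 0..4 or NO_CALL
    expected_reference_copies: int


@dataclass(frozen=True)
class CopyNumberProfile:
    sample_id: str
    calls: Mapping[str, ProbeCall]

    def copies(self, site_id: str) -> "int | str":
        return self.calls[site_id].copies

    def relative(self, site_id: str) -> float:
        return self.calls[site_id].relative_signal


@dataclass(frozen=True)
class QCVerdict:
    """Outcome of the 2:2 reference-qualification rule."""

    status: str  # "qualified" | "disqualified" | "indeterminate"
    offending_sites: tuple[str, ...] = ()
    no_call_sites: tuple[str, ...] = ()

    @property
    def qualified(self) -> bool:
        return self.status == "qualified"


def _intra_scale(signals: Mapping[str, float], m: LocusMap) -> float:
    """Within-sample scaling constant.

    The median over the kit's autosomal reference probes when available
    (robust to large locus aberrations such as a whole-gene deletion),
    otherwise the median over all probes.
    """
    ref_ids = [s.id for s in m.reference_sites]
    values = (
        [signals[i] for i in ref_ids]
        if len(ref_ids) >= 3
        else list(signals.values())
    )
    scale = median(values)
    if scale <= 0:
        raise DegenerateSampleError("zero or negative within-sample median")
    return scale


def _scaled(s: ProbeSignalSet, m: LocusMap) -> dict[str, float]:
    s.check_against(m)
    scale = _intra_scale(s.signals, m)
    return {k: v / scale for k, v in s.signals.items()}


@dataclass
class ReferencePanel:
    """Qualified reference samples with per-probe signal statistics."""

    members: tuple[ProbeSignalSet, ...]
    probe_mean: dict[str, float] = field(default_factory=dict)
    probe_sd: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_members(
        cls, members: Sequence[ProbeSignalSet], m: LocusMap
    ) -> "ReferencePanel":
        if not members:
            raise PanelConstructionError("empty reference panel")
        scaled = [_scaled(s, m) for s in members]
        ids = [site.id for site in m.probe_sites]
        mean = {i: float(np.mean([sc[i] for sc in scaled])) for i in ids}
        sd = {i: float(np.std([sc[i] for sc in scaled], ddof=0)) for i in ids}
        bad = [i for i, v in mean.items() if v <= 0]
        if bad:
            raise PanelConstructionError(f"zero panel mean at probes {bad}")
        return cls(tuple(members), mean, sd)

    def __len__(self) -> int:
        return len(self.members)


def normalize_signals(
    s: ProbeSignalSet, panel: ReferencePanel, m: LocusMap
) -> dict[str, float]:
    """Per-probe relative signals of a sample against a reference panel."""
    scaled = _scaled(s, m)
    if set(panel.probe_mean) != set(scaled):
        raise SchemaError("panel and sample probe sets differ")
    return {i: scaled[i] / panel.probe_mean[i] for i in scaled}


def call_copy_numbers(
    rel: Mapping[str, float],
    m: LocusMap,
    band: float = DEFAULT_BAND,
    sample_id: str = "sample",
) -> CopyNumberProfile:
    """Integer copy calls from relative signals.

    ``copies = round(relative * expected_reference_copies)``; the call is
    withheld (NO_CALL) when the copy estimate sits more than
    ``band * expected_reference_copies`` away from the nearest integer, or
    outside 0..4.
    """
    if not 0.0 < band <= 0.25:
        raise ParameterError("band must lie in (0, 0.25]")
    calls: dict[str, ProbeCall] = {}
    for site in m.probe_sites:
        try:
            r = float(rel[site.id])
        except KeyError:
            raise SchemaError(f"missing relative signal for probe {site.id!r}")
        ref = m.expected_reference_copies(site)
        est = r * ref
        nearest = int(round(est))
        copies: "int | str"
        if (
            nearest < 0
            or nearest > MAX_COPIES
            or abs(est - nearest) > band * ref + 1e-12
        ):
            copies = NO_CALL
        else:
            copies = nearest
        calls[site.id] = ProbeCall(r, copies, ref)
    return CopyNumberProfile(sample_id=sample_id, calls=calls)


def qc_reference(profile: CopyNumberProfile, m: LocusMap) -> QCVerdict:
    """2:2 qualification: every discriminating exon 11-15 site calls exactly
    two gene-specific and two pseudogene-specific copies."""
    offending: list[str] = []
    no_calls: list[str] = []
    for site in m.discriminating_sites():
        c = profile.calls[site.id].copies
        if c == NO_CALL:
            no_calls.append(site.id)
        elif c != 2:
            offending.append(site.id)
    if no_calls and not offending:
        return QCVerdict("indeterminate", no_call_sites=tuple(no_calls))
    if offending:
        return QCVerdict(
            "disqualified",
            offending_sites=tuple(offending),
            no_call_sites=tuple(no_calls),
        )
    return QCVerdict("qualified")


def build_panel(
    candidates: Sequence[ProbeSignalSet],
    m: LocusMap,
    min_size: int = 5,
    band: float = DEFAULT_BAND,
    max_size: "int | None" = None,
    max_rounds: int = 10,
) -> tuple[ReferencePanel, dict[str, QCVerdict]]:
    """Qualify reference candidates and assemble a panel.

    Without a prior panel there is a circularity: candidates can only be
    normalized against themselves. The bootstrap normalizes every candidate
    against the trimmed per-probe mean of the surviving cohort, drops
    disqualified candidates, and repeats until the surviving set is stable.
    Returns the panel plus the per-candidate verdicts of the final round.
    """
    if len(candidates) < min_size:
        raise PanelConstructionError(
            f"{len(candidates)} candidates provided; at least {min_size} required"
        )
    for c in candidates:
        c.check_against(m)

    survivors = list(candidates)
    verdicts: dict[str, QCVerdict] = {}
    for _ in range(max_rounds):
        ref_mean = _cohort_median(survivors, m)
        verdicts = {}
        next_survivors = []
        for c in candidates:
            rel = {
                i: v / ref_mean[i] for i, v in _scaled(c, m).items()
            }
            prof = call_copy_numbers(rel, m, band=band, sample_id=c.sample_id)
            v = qc_reference(prof, m)
            verdicts[c.sample_id] = v
            if v.qualified:
                next_survivors.append(c)
        if [s.sample_id for s in next_survivors] == [
            s.sample_id for s in survivors
        ]:
            break
        survivors = next_survivors if next_survivors else survivors

    qualified = [c for c in candidates if verdicts[c.sample_id].qualified]
    if len(qualified) < min_size:
        raise PanelConstructionError(
            f"only {len(qualified)} of {len(candidates)} candidates qualified; "
            f"{min_size} required"
        )
    if max_size is not None:
        qualified = qualified[:max_size]
    return ReferencePanel.from_members(qualified, m), verdicts


def _cohort_median(
    cohort: Iterable[ProbeSignalSet], m: LocusMap
) -> dict[str, float]:
    """Per-probe median of within-sample-scaled signals.

    Used to break the bootstrap circularity: copy numbers at discriminating
    probes are distributed symmetrically around two in a hybrid-rich cohort,
    so the median recovers the two-copy reference level even when most
    candidates fail the 2:2 criterion.
    """
    scaled = [_scaled(s, m) for s in cohort]
    out: dict[str, float] = {}
    for site in m.probe_sites:
        v = float(np.median([sc[site.id] for sc in scaled]))
        if v <= 0:
            raise DegenerateSampleError(
                f"cohort median collapsed to zero at probe {site.id!r}"
            )
        out[site.id] = v
    return out
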
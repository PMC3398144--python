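"""Shared fixtures: packaged locus, noise-free panels, reduced test locus."""

import numpy as np
import pytest

from paralogmlpa import mlpa_calling as mc
from paralogmlpa import synthetic_cohort as sc
from paralogmlpa.locus_model import (
    LocusMap,
    expected_copy_vector,
    load_locus_map,
    packaged_locus,
)


@pytest.fixture(scope="session")
def m() -> LocusMap:
    return packaged_locus()


@pytest.fixture(scope="session")
def nm0() -> sc.NoiseModel:
    return sc.NoiseModel(sigma=0.0)


@pytest.fixture(scope="session")
def normal_panel(m, nm0) -> mc.ReferencePanel:
    members = [
        sc.simulate_probe_signals(
            sc.make_case_genotype("NORMAL", m), nm0, m, sample_id=f"ref{i}"
        )
        for i in range(5)
    ]
    return mc.ReferencePanel.from_members(members, m)


@pytest.fixture(scope="session")
def profile_for(m, nm0, normal_panel):
    """Noise-free copy-number profile for an archetype."""

    def _make(archetype: str) -> mc.CopyNumberProfile:
        s = sc.simulate_probe_signals(
            sc.make_case_genotype(archetype, m), nm0, m, sample_id=archetype
        )
        rel = mc.normalize_signals(s, normal_panel, m)
        return mc.call_copy_numbers(rel, m, sample_id=archetype)

    return _make


def profile_from_copies(copies: dict, m: LocusMap, sample_id="synthetic"):
    """Build a CopyNumberProfile directly from per-site copy numbers.

    Sites absent from ``copies`` (and all reference probes) default to their
    reference value; the string NO_CALL marks wildcard sites.
    """
    calls = {}
    for site in m.probe_sites:
        ref = m.expected_reference_copies(site)
        c = copies.get(site.id, ref if site.specificity != "reference" else 2)
        rel = 1.0 if c == mc.NO_CALL else c / ref
        calls[site.id] = mc.ProbeCall(rel, c, ref)
    return mc.CopyNumberProfile(sample_id=sample_id, calls=calls)


def profile_from_genotype(g, m: LocusMap, sample_id="truth"):
    return profile_from_copies(expected_copy_vector(g, m), m, sample_id)


REDUCED_LOCUS_CFG = {
    "name": "reduced",
    "geometry": {
        "exon_spans": {
            "E9": [904, 988],
            "E10": [989, 1144],
            "E11": [1145, 2006],
            "E12": [2007, 2174],
            "E13": [2175, 2276],
        },
        "pseudogene_exons": ["E9", "E11", "E12", "E13"],
    },
    "probe_sites": [
        {"id": "E9_g", "exon_label": "E9", "specificity": "gene", "ligation_pos": "c.940_941"},
        {"id": "E10_g", "exon_label": "E10", "specificity": "gene", "ligation_pos": "c.1020_1021"},
        {"id": "E11_g", "exon_label": "E11", "specificity": "gene", "ligation_pos": "c.1360_1361"},
        {"id": "E11_p", "exon_label": "E11", "specificity": "pseudogene", "ligation_pos": "c.1729_1730"},
        {"id": "E12_u", "exon_label": "E12", "specificity": "universal", "ligation_pos": "c.2030_2031"},
        {"id": "E12_g", "exon_label": "E12", "specificity": "gene", "ligation_pos": "c.2050_2051"},
        {"id": "E13_g", "exon_label": "E13", "specificity": "gene", "ligation_pos": "c.2200_2201"},
        {"id": "E13_u", "exon_label": "E13", "specificity": "universal", "ligation_pos": "c.2210_2211"},
        {"id": "E13_p", "exon_label": "E13", "specificity": "pseudogene", "ligation_pos": "c.2230_2231"},
        {"id": "REF01", "exon_label": "CTRL", "specificity": "reference"},
        {"id": "REF02", "exon_label": "CTRL", "specificity": "reference"},
        {"id": "REF03", "exon_label": "CTRL", "specificity": "reference"},
    ],
    "psv_catalog": [
        {"id": "E11_fs", "position": "c.1730", "gene_allele": "A",
         "pseudogene_allele": "AA", "kind": "duplication",
         "gene_context_consequence": "frameshift"},
    ],
}


@pytest.fixture(scope="session")
def reduced_m() -> LocusMap:
    return load_locus_map(REDUCED_LOCUS_CFG)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120514)
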
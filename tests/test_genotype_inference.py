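"""Allele classification and diploid genotype enumeration."""

import itertools

import numpy as np
import pytest

from conftest import profile_from_copies, profile_from_genotype

from paralogmlpa import genotype_inference as gi
from paralogmlpa import mlpa_calling as mc
from paralogmlpa import synthetic_cohort as sc
from paralogmlpa.errors import ParameterError
from paralogmlpa.locus_model import (
    GENE,
    GENE_LOCUS,
    PSEUDOGENE,
    PSEUDOGENE_LOCUS,
    DiploidGenotype,
    Haplotype,
    LocusMap,
    expected_copy_vector,
    pure_haplotype,
    suffix_hybrid,
)


class TestClassifyHaplotype:
    def test_tr13_hybrid_is_deleterious(self, m):
        hap = sc.make_case_genotype("TR13", m).gene_haplotypes[0]
        assert gi.classify_haplotype(hap, m).value == gi.DELETERIOUS_HYBRID

    def test_e13_to_e15_hybrid_is_nondeleterious(self, m):
        hap = suffix_hybrid(GENE_LOCUS, m.n_groups, m.group_index("E13"))
        c = gi.classify_haplotype(hap, m)
        assert c.value == gi.NONDELETERIOUS_HYBRID
        assert not c.deleterious

    def test_pure_gene_is_normal(self, m):
        hap = pure_haplotype(GENE_LOCUS, m.n_groups)
        assert gi.classify_haplotype(hap, m).value == gi.NORMAL

    def test_exon10_loss_is_deleterious(self, m):
        hap = suffix_hybrid(GENE_LOCUS, m.n_groups, m.group_index("E10"))
        assert gi.classify_haplotype(hap, m).value == gi.DELETERIOUS_HYBRID

    def test_deletions(self, m):
        n = m.n_groups
        whole = Haplotype(
            GENE_LOCUS, pure_haplotype(GENE_LOCUS, n).segments, ((0, n - 1),)
        )
        e8 = m.group_index("E8")
        partial = Haplotype(
            GENE_LOCUS, pure_haplotype(GENE_LOCUS, n).segments, ((e8, e8),)
        )
        assert gi.classify_haplotype(whole, m).value == gi.WHOLE_GENE_DELETION
        assert gi.classify_haplotype(partial, m).value == gi.EXON_DELETION

    def test_pseudogene_locus_rejected(self, m):
        hap = pure_haplotype(PSEUDOGENE_LOCUS, m.n_groups)
        with pytest.raises(ParameterError):
            gi.classify_haplotype(hap, m)


class TestEnumerateArchetypes:
    def test_tr13_unique_deleterious_deduction(self, m, profile_for):
        """The 1:3/1:3/2:2/2:2/1:3 pattern forces a gene-locus haplotype
        pseudogene-derived from exon 11."""
        ss = gi.enumerate_genotypes(profile_for("TR13"), m)
        assert ss.classification == "deleterious"
        e11 = m.group_index("E11")
        for s in ss.minimal_solutions:
            assert any(
                h.origin_at(e11) == PSEUDOGENE and h.origin_at(e11 - 1) == GENE
                for h in s.genotype.gene_haplotypes
            )

    def test_ch8_whole_gene_deletion_with_two_hybrid_pseudogenes(
        self, m, profile_for
    ):
        ss = gi.enumerate_genotypes(profile_for("CH8"), m)
        assert ss.classification == "deleterious"
        sol = ss.minimal_solutions[0]
        assert gi.WHOLE_GENE_DELETION in sol.allele_classes
        e13 = m.group_index("E13")
        gene_suffixed = [
            h for h in sol.genotype.pseudogene_haplotypes
            if h.origin_at(e13) == GENE
        ]
        assert len(gene_suffixed) == 2

    def test_ch11_exon_deletion(self, m, profile_for):
        ss = gi.enumerate_genotypes(profile_for("CH11"), m)
        assert ss.classification == "deleterious"
        assert gi.EXON_DELETION in ss.minimal_solutions[0].allele_classes

    def test_balanced_profile_contains_masked_configuration(self, m, profile_for):
        """The 2:2 vector admits both the all-normal genotype and the
        deleterious-plus-reciprocal pair; dosage cannot distinguish them."""
        ss = gi.enumerate_genotypes(profile_for("NORMAL"), m)
        assert ss.classification == "normal"  # minimal = zero events
        assert ss.masked_risk
        assert any(s.n_events == 0 for s in ss.solutions)
        e11 = m.group_index("E11")
        masked = [
            s for s in ss.solutions
            if any(c == gi.DELETERIOUS_HYBRID for c in s.allele_classes)
            and any(
                h.origin_at(e11) == GENE
                for h in s.genotype.pseudogene_haplotypes
            )
        ]
        assert masked, "reciprocal-hybrid configuration missing from solutions"

    def test_wildcard_sites_can_make_classification_ambiguous(self, m, profile_for):
        """Masking exon 11 behind NO_CALLs leaves deleterious and
        nondeleterious minimal solutions side by side."""
        prof = profile_for("TR13")
        copies = {s.id: prof.copies(s.id) for s in m.assay_sites}
        for s in m.assay_sites:
            if s.exon_label == "E11":
                copies[s.id] = mc.NO_CALL
        ss = gi.enumerate_genotypes(profile_from_copies(copies, m), m)
        dels = {s.deleterious for s in ss.minimal_solutions}
        assert dels == {True, False}
        assert ss.classification == "ambiguous"

    def test_unsatisfiable_profile_is_uninterpretable(self, m, profile_for):
        copies = {s.id: 2 for s in m.assay_sites}
        for s in m.assay_sites:
            if s.specificity == "universal":
                copies[s.id] = 4
        # Zero pseudogene-specific copies at exon 11 with four-copy
        # universals elsewhere cannot arise from single-crossover tracts.
        copies["E11_p"] = 0
        ss = gi.enumerate_genotypes(profile_from_copies(copies, m), m)
        assert ss.classification == "uninterpretable"
        assert ss.diagnostics["closest_distance"] >= 1
        assert ss.diagnostics["closest_vector"]


class TestSoundness:
    def test_solutions_reproduce_called_profile(self, m, rng):
        for _ in range(25):
            g = sc.sample_population_genotype(sc.PopulationModel(), rng, m)
            prof = profile_from_genotype(g, m)
            ss = gi.enumerate_genotypes(prof, m)
            for s in ss.solutions[:10]:
                v = expected_copy_vector(s.genotype, m)
                for site in m.assay_sites:
                    assert v[site.id] == prof.copies(site.id)


def _brute_force_solutions(prof, m: LocusMap):
    """Independent oracle: exhaustive generate-and-filter over all bounded
    genotypes on a small locus."""
    n = m.n_groups
    gene_space = [pure_haplotype(GENE_LOCUS, n)]
    gene_space += [
        suffix_hybrid(GENE_LOCUS, n, s)
        for s in range(max(m.first_shared_group, 1), n)
    ]
    gene_space += [
        Haplotype(GENE_LOCUS, pure_haplotype(GENE_LOCUS, n).segments, ((a, b),))
        for a in range(n)
        for b in range(a, n)
    ]
    pseudo_space = [pure_haplotype(PSEUDOGENE_LOCUS, n)]
    pseudo_space += [
        suffix_hybrid(PSEUDOGENE_LOCUS, n, s)
        for s in range(m.group_index("E11"), n)
    ]
    called = [
        s for s in m.assay_sites if prof.calls[s.id].copies != mc.NO_CALL
    ]
    found = set()
    for g1, g2 in itertools.combinations_with_replacement(gene_space, 2):
        for p1, p2 in itertools.combinations_with_replacement(pseudo_space, 2):
            geno = DiploidGenotype((g1, g2), (p1, p2))
            v = expected_copy_vector(geno, m)
            if all(v[s.id] == prof.calls[s.id].copies for s in called):
                found.add(gi._encode(geno))
    return found


class TestOracleEquivalence:
    def test_matches_brute_force_on_reduced_locus(self, reduced_m):
        """Enumeration equals generate-and-filter over the full bounded
        genotype space (random noise-free profiles, small locus)."""
        m = reduced_m
        rng = np.random.default_rng(5)
        for trial in range(40):
            g = sc.random_genotype(rng, m, p_hybrid=0.5, p_deletion=0.3)
            # Keep within default constraint bounds (no combined events).
            if any(
                h.n_events > 1 for h in g.haplotypes
            ):
                continue
            prof = profile_from_genotype(g, m, sample_id=f"t{trial}")
            ss = gi.enumerate_genotypes(prof, m)
            got = {gi._encode(s.genotype) for s in ss.solutions}
            want = _brute_force_solutions(prof, m)
            assert got == want
            assert gi._encode(g) in got


class TestCompletenessUnderSimulation:
    def test_true_genotype_recovered(self, m):
        """With noisy triplicate measurements (the pipeline's protocol) and a
        qualified panel, the generating genotype appears in the solution set
        in >=99% of simulations."""
        rng = np.random.default_rng(6)
        nm = sc.NoiseModel(sigma=0.05)
        members = [
            sc.simulate_probe_signals(
                sc.make_case_genotype("NORMAL", m), nm, m,
                sample_id=f"r{i}", rng=rng, replicates=3,
            )
            for i in range(5)
        ]
        panel = mc.ReferencePanel.from_members(members, m)
        pm = sc.PopulationModel()
        archetypes = itertools.cycle(["CH8", "CH11", "TR13"])
        hits = total = 0
        for i in range(500):
            if i % 5 == 0:
                g = sc.make_case_genotype(next(archetypes), m)
            else:
                g = sc.sample_population_genotype(pm, rng, m)
            s = sc.simulate_probe_signals(
                g, nm, m, sample_id=f"s{i}", rng=rng, replicates=3
            )
            prof = mc.call_copy_numbers(
                mc.normalize_signals(s, panel, m), m, sample_id=s.sample_id
            )
            ss = gi.enumerate_genotypes(prof, m)
            got = {gi._encode(sol.genotype) for sol in ss.solutions}
            total += 1
            hits += gi._encode(g) in got
        assert hits / total >= 0.99


class TestInterpretSample:
    def test_ch11_flags_exon_deletion(self, m, profile_for):
        rep = gi.interpret_sample(profile_for("CH11"), m)
        assert rep.aberrant
        assert rep.classification == "deleterious"
        assert "E8_g1" in rep.deviant_sites

    def test_normal_profile(self, m, profile_for):
        rep = gi.interpret_sample(profile_for("NORMAL"), m)
        assert not rep.aberrant
        assert rep.classification == "normal"

    def test_masked_profile_recommends_asp(self, m, profile_for):
        rep = gi.interpret_sample(profile_for("TR13_MASKED"), m)
        assert not rep.aberrant
        assert rep.solution_set.masked_risk
        assert "allele-specific PCR" in rep.recommended_follow_up
        assert "insilico_asp" in rep.recommended_follow_up

    def test_report_serializes(self, m, profile_for):
        import json

        rep = gi.interpret_sample(profile_for("TR13"), m)
        blob = json.dumps(rep.to_dict())
        assert "deleterious" in blob
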
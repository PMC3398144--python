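# paralogmlpa

Paralog-aware interpretation of MLPA copy-number assays at duplicated loci,
built around the PMS2/PMS2CL problem: the Lynch-syndrome gene *PMS2* (7p22)
sits ~0.7 Mb from its transcribed pseudogene *PMS2CL*, which mirrors exons
9–15 (minus exon 10) inside an inverted 100-kb duplicon. Interparalog
recombination makes **hybrid alleles** — gene copies carrying
pseudogene-derived tracts and vice versa — so common (~70% of individuals
carry at least one) that raw dosage at exons 11–15 cannot be read without
care: a probe only counts how many of the four physical copies carry its
paralog-specific sequence, not *where* they sit.

The package implements the full interpretation chain a diagnostic lab needs:

- **Locus model** (`locus_model`): probe map (24 gene-specific, 5
  pseudogene-specific, 5 universal, 10 autosomal reference probes), a
  catalog of paralogous sequence variants (PSVs), HGVS intronic-offset
  arithmetic, and the noise-free genotype → copy-vector map.
- **Synthetic cohort** (`synthetic_cohort`): diploid genotypes from a
  population model with common nondeleterious hybrids, the three patient
  archetypes (`CH8` whole-gene deletion, `CH11` exon-8 deletion, `TR13`
  intron-10 crossover hybrid, plus the dosage-invisible `TR13_MASKED`
  reciprocal pair), multiplicative lognormal probe noise, and PSV origin
  readouts.
- **Dosage calling** (`mlpa_calling`): two-step normalization (within-sample
  reference-probe median, then a qualified reference panel), integer copy
  calls with a no-call band, and the **2:2 qualification rule** — a DNA is a
  valid reference only if it carries exactly two gene- and two
  pseudogene-specific copies of every discriminating exon 11–15 sequence.
- **Genotype inference** (`genotype_inference`): exhaustive enumeration of
  all diploid haplotype configurations (≤1 crossover or ≤1 contiguous
  deletion per haplotype) matching a called profile, parsimony ranking,
  allele classification, and masked-configuration detection.
- **Breakpoint tools** (`breakpoint_tools`): PSV-delimited breakpoint
  intervals with crossover/conversion classification, in-silico
  allele-specific PCR (ASP), array-probe deletion bounding, and the
  interduplicon recombination clock `generations = 100 / (d_Mb · r_cM/Mb)`.
- **CLI** (`paralogmlpa …`): `simulate`, `qc-refs`, `call`, `infer`,
  `breakpoint`, `asp`, `run-all`.

Dosage semantics: a relative probe signal of 1.0 means two copies at a
paralog-specific probe and four at a universal probe; 0.5 means one copy,
1.5 three, and 0.75 at a universal probe means three of four copies.

## Worked example

```sh
paralogmlpa run-all --seed 17 --out cohort_out
```

simulates the study design — 24 reference candidates screened for the 2:2
criterion, a 5-member qualified panel, then 13 samples (the three patient
archetypes among ten population backgrounds, σ = 0.05, triplicate runs) —
and prints:

```json
{
  "n_samples": 13,
  "classification_counts": {"normal": 10, "deleterious": 3,
                            "ambiguous": 0, "uninterpretable": 0},
  "reference_qc": {"n_candidates": 24, "n_qualified": 8, ...}
}
```

Exactly the three archetype carriers are flagged deleterious. The per-sample
report for `TR13_02` shows the deduced genotype — one gene allele
pseudogene-derived from exon 11 (a frameshifting, hence deleterious,
hybrid), one exon-15-only nondeleterious hybrid, one intact pseudogene and
one pseudogene gene-derived from exon 13 — which is the unique minimal-event
explanation of the observed 1:3 (exons 11, 12, 15) and 2:2 (exons 13, 14)
gene:pseudogene ratios. `cohort_out/matrix.tsv` is the per-site dosage
matrix with `normal` / `uneven_4` / `aberrant` category labels.

Breakpoint mapping on the crossover haplotype's intron-10 PSV readout:

```python
from paralogmlpa import synthetic_cohort as sc, breakpoint_tools as bt
from paralogmlpa.locus_model import packaged_locus

m = packaged_locus()
hap = sc.make_case_genotype("TR13", m).gene_haplotypes[0]
call = bt.map_breakpoint(sc.simulate_psv_readout(hap, ("c.1145-1200", "c.1145-600"), m))
print(call.anchor_up, call.anchor_down, call.region_length_bp, call.mechanism)
# c.1145-942 c.1145-790 153 crossover
```

The 153-bp region contains three interior discordant PSVs — the
double-Holliday-junction signature of recombination with crossover. The
companion duplex ASP assay (239-bp allele-specific + 696-bp control product)
detects the crossover haplotype even in the masked reciprocal configuration,
where dosage is an exact 2:2 everywhere:

```sh
paralogmlpa asp --n-controls 150 --seed 2 --archetype TR13_MASKED
# control_negatives: 150, archetype allele_specific product: 239 bp
```

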
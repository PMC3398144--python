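# Methods

## The locus model

The model covers any two-paralog locus consisting of a functional gene and a
highly similar pseudogene in a sister duplicon; the packaged fixture encodes
PMS2/PMS2CL on 7p22 (inverted duplicons, 0.7 Mb apart; the pseudogene spans
exons 9 and 11–15 and lacks exon 10 through a 2.7-kb deletion).

Coordinates. Probe ligation sites and paralogous sequence variants (PSVs)
carry HGVS-style coding positions with optional intronic offsets
(`c.1145-942` = 942 nt 5' of the first base of the exon starting at
c.1145). Spans are defined only between positions that share an anchoring
exon boundary or are both exonic; anything else would require intron
lengths the coordinate system does not carry and raises an error. All
ordering uses a `(anchor, offset)` sort key computed once at load.

Site groups. Haplotype structure (origin tracts and deletions) is expressed
on an exon-level group axis (E1…E10, E11, E12, IVS12, E13, E14, E15) rather
than per-probe: MLPA cannot localize an event between two probes of the
same exon, and placing breakpoints inside an exon group would violate the
dosage-conservation identity (universal = gene + pseudogene counts) that
co-located probe trios must satisfy. Sub-exon structure — the PSV-by-PSV
crossover signature inside intron 10 — is carried as per-PSV origin
overrides on the haplotype and consumed by the PSV-readout and ASP tools,
not by dosage.

Haplotypes are mosaics with at most one origin transition (the crossover
model); gene-locus haplotypes are gene-derived suffix-hybrids
(`g…g|p…p`), pseudogene-locus haplotypes the mirror image, reflecting that
interparalog exchange swaps the distal (3') portions of the duplicons.
Pseudogene-derived tracts cannot extend 5' of the shared region; a
pseudogene-origin segment contributes zero copies at exon-10 sites (the
sequence is absent), which is why a crossover 5' of exon 11 is
automatically deleterious. Deletions are modeled at the gene locus only —
no pseudogene-deletion case motivates the extra space — and this is a
documented limitation.

Probe fixture. The kit complement (24 gene-specific probes across exons
1–15, 5 pseudogene-specific across exons 11–15, 5 universal across exons
12–15) is fixed; only two ligation positions are public (`c.1360_1361`,
`c.2174+1097_2174+1099`), so the remaining placements, the exon spans
outside the published anchors (E8 = c.804_903, E11 from c.1145, E12 to
c.2174) and the intron-10 PSV positions other than the five printed ones
are plausible fixture conventions, marked as such in the config. Ten
autosomal reference probes (constant two copies) are included because the
real kit carries control probes and because within-sample scaling must
survive a whole-gene deletion (see below).

## Signal model and dosage calling

Forward model: `signal = 100 · (true copies / reference copies) ·
Lognormal(0, σ)` per probe, independent across probes; reference copies are
2 for specific/control probes and 4 for universal probes. Default σ = 0.05,
chosen so that integer levels (0.5 / 0.75 / 1.0 / 1.5 relative) remain
cleanly separated; the generator is deterministic under a fixed seed.
Samples may be measured in replicate and averaged probe-by-probe;
the pipeline defaults to triplicate runs for reference candidates and
cohort samples, mirroring diagnostic practice, which brings the effective
relative-signal σ to ≈0.03 and keeps the no-call rate per profile low.

Normalization is two-step: each sample is scaled by the median over its
reference probes (robust even when half the locus probes are deleted — a
whole-gene-deletion sample would corrupt an all-probe median), then divided
probe-by-probe by the panel mean of the same quantity. Copy calls round
`relative × reference copies` to the nearest integer in 0..4 and withhold
the call (NO_CALL) when the estimate is more than `band × reference
copies` from that integer; default band 0.1, i.e. ±0.2 copies at a
specific probe. NO_CALL sites act as wildcards downstream, never imputed.

Reference qualification implements the 2:2 prerequisite: every
discriminating exon 11–15 site must call exactly two gene- and two
pseudogene-specific copies. Candidates are qualified without a prior panel
by bootstrapping: all candidates are normalized against the per-probe
median of the surviving cohort, disqualified ones dropped, and the loop
repeated to a fixed point. The median is the right center because copy
numbers at discriminating sites are distributed symmetrically around two in
a hybrid-rich cohort; the bootstrap still fails, by design, on pathological
cohorts in which every candidate shares the same imbalance (a
self-referential QC cannot see a uniform shift — real laboratories anchor
on previously characterized DNAs).

## Population model

Each of the four haplotypes is independently a nondeleterious hybrid with
probability `q = 1 − (1 − p_carrier)^(1/4)`, so the carrier fraction
(default 0.70) is exact by construction. Hybrid tracts start 3' of exon 12
(IVS12, E13, E14 or E15); the probability that a gene-locus tract covers
exon 14 — the p.N775S hybrid, the only non-synonymous common variant — is
set by the configured allele fraction (default 0.10, inside the reported
4–25% ethnic range): `P(cover E14 | hybrid) = p_N775S / q`, split evenly
over the covering starts, remainder on exon-15-only tracts. Rarer events 5'
of exon 12 are never drawn as background; they are injected deliberately
via the archetypes. A consequence worth noting: a sample is 2:2 iff the
multiset of tract starts on its gene alleles equals that on its pseudogene
alleles, so the qualification rate exceeds the non-carrier fraction
(reciprocal pairs balance) — the test suite checks the closed form
`Σ_M P(M)²`.

What the generator does not emulate: inter-probe noise correlation
(shared-well effects), mosaicism, >2-copy amplifications, electrophoresis
artifacts, or sequencing errors in PSV readouts. Passing tests therefore
demonstrate the interpretation logic under calibrated multiplicative noise,
not robustness to every failure mode of real capillary data.

## Genotype enumeration

The solution space is the Cartesian product of bounded haplotype spaces:
gene-locus candidates are the pure haplotype, suffix hybrids starting at
any shared group, and single contiguous deletions; pseudogene-locus
candidates are the pure haplotype and gene-derived suffixes starting at or
after exon 11 (a crossover 5' of that would have to transfer exon 10,
which the pseudogene locus lacks). By default a haplotype carries a
breakpoint or a deletion, not both — no published case requires the
combination — and a constraints flag re-enables the combined space.
Matching uses unordered pair sums of per-site contribution vectors hashed
against the called profile, with NO_CALL sites unconstrained; an empty
solution set reports the closest achievable vector as a diagnostic.

Solutions are ranked by total event count, ties broken by fewer deleterious
alleles and then a lexicographic haplotype encoding, making reports
deterministic. Classification follows the minimal-event solutions: all
deleterious → `deleterious`; none → `normal`; disagreement → `ambiguous`.
A separate `masked_risk` flag is raised whenever any deleterious
configuration at higher event count also reproduces the profile — most
importantly the exact-2:2 profile, which admits both the all-normal
genotype (0 events) and a deleterious hybrid travelling with its
reciprocal (2 events). Dosage cannot distinguish these, so the sample
report recommends the breakpoint allele-specific PCR rather than labelling
every balanced profile ambiguous.

## Breakpoint tools

`map_breakpoint` defines the upstream anchor as the last PSV at or 5' of
which every PSV carries the upstream origin (inclusive), the downstream
anchor symmetrically, and reports the inclusive span and the interior
discordant PSVs. A durable origin switch is a crossover; donor runs
flanked on both sides by host origin are a conversion tract (multiple runs
are labelled conversion with their joint extent); uniform readouts return
mechanism `none` with undefined anchors rather than an error. On the
packaged crossover haplotype this yields the c.1145-942 .. c.1145-790
region, 153 bp with three interior PSVs.

`insilico_asp` is origin-based, not thermodynamic: the allele-specific
product requires one haplotype carrying the required origins at both
primer sites in cis; product lengths (239/696 bp) are fixture constants of
the assay. `bound_deletion` reports both inner (between innermost deleted
probes) and outer (between outermost retained neighbors) bounds because
printed "~size" figures do not say which convention they use.
`expected_generations` returns the exact reciprocal of the per-meiosis
recombination fraction, `100 / (d_Mb · r_cM/Mb)`, valid well below 50 cM.

## Problem sizes and numerical choices

Stochastic checks run at the study design scale: 24 reference candidates
per panel, 13-sample cohorts, 150 ASP controls, 500-simulation
recovery/calibration runs, a 10,000-genotype ASP specificity screen, and a
200-profile brute-force enumeration oracle on a 5-exon reduced locus. All
random draws flow from explicit seeds (`numpy.random.default_rng`);
repeated runs are byte-identical. Ties in copy rounding cannot occur away
from band edges (a 1e-12 guard absorbs float error at exact half-band
values); degenerate inputs (zero scaling median, empty cohorts, uniform
readouts, tracks without deleted probes) return typed errors or explicit
empty results as documented per function.

## Known limitations

- Single-crossover (suffix) hybrids only at dosage granularity; multi-run
  conversion tracts are representable via PSV overrides but not enumerated
  from dosage (dosage cannot see them).
- No pseudogene-locus deletions, no amplifications beyond four copies, no
  mosaicism.
- The reference-qualification bootstrap assumes a heterogeneous candidate
  cohort; a uniformly biased cohort passes undetected.
- The packaged probe/PSV positions between published anchors are fixture
  conventions; absolute coordinates matter only for span arithmetic at the
  five printed intron-10 sites, which are exact.
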
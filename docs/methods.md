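# Methods

## The genetic model

The package models a selfing crop population segregating a single recessive
allele that is lethal when homozygous (the mutant seedlings die before
reproducing). Three quantities describe the population: the heterozygote
(carrier) frequency *h* among surviving parents, the mutant allele frequency
*q = h/2* (no live mutant homozygotes exist), and the expected mutant
incidence among bulked selfed progeny *a = h/4* (each carrier family
segregates 3:1). These give the estimators and recurrence in `seedmgmt`:

- `carrier_estimate_from_incidence`: *h = 4a*, *q = 2a*. Both exceed the
  observed incidence whenever *a* > 0, which is why an apparently rare
  phenotype understates the allele's real prevalence.
- `selfing_recurrence`: among survivors of one selfing round,
  *h′ = (h/2)/(1 − h/4)*. The map has the single fixed point 0 and satisfies
  *h/2 < h′ ≤ 2h/3* on (0, 1]: selection against the homozygote only roughly
  halves the carrier frequency per generation, so the allele lingers for many
  generations unless carriers are genotyped and discarded.

The model is single-locus, purely selfing (no outcrossing) and assumes
lethality is strictly pre-reproductive. Multi-generation carrier
accumulation is not modelled: the incidence→carrier estimator is the
one-generation conditional model, and a population maintained for decades
can show a higher standing carrier fraction than it predicts.

## The linkage statistic

For pooled sequencing of *n_g* wild-type ("green") and *n_a* mutant
("albino") plants, each variant site contributes four read counts. The
linkage percent is the share of reads concordant with full linkage to a
recessive causal allele (green reads reference, albino reads alternate).
It is invariant under common scaling of the counts and obeys the complement
identity L(gw, gm, aw, am) + L(gm, gw, am, aw) = 100; both properties are
tested exhaustively for small counts against rational arithmetic. At a site
with no reads the statistic is undefined and raised as an error rather than
reported as 0.

Candidacy requires (a) a strict per-pool depth window, by default
3 < reads < 100 per pool (a summed-depth mode is available via
`FilterConfig(per_pool=False)`), and (b) linkage percent at or above a
threshold, default 100. The threshold default reflects the observed gap in
the motivating study between the causal site (100.00) and the best unlinked
site (74.07); it is configurable for noisier designs. Display rounding is
half-up to two decimals; internal values are unrounded.

Multi-allelic VCF records are skipped with a warning and counted, not
decomposed: pooled AD fields for split records are ambiguous without the
caller's decomposition convention.

## The synthetic-data generator

`simdata` emulates the study design, not read-level sequencing. Defaults are
the study's own conditions: 13 green and 10 albino plants, mean per-pool
depth 10, 216 unlinked background polymorphisms, carrier frequency
h = 0.0544 (4 × the 1.36% incidence), per-read allele-flip error 0.001
(Q30-grade data).

- Albino plants have causal dosage 2 by definition of the phenotype; each
  green plant is a carrier with probability (h/2)/(1 − h/4).
- Background sites draw one population allele frequency per site, uniform on
  [0.05, 0.95], shared by both pools (an unlinked site has the same expected
  frequency in either phenotype class); plant dosages are Binomial(2, f)
  (Hardy–Weinberg). The background class mix (SNP:insertion:deletion ≈
  105:40:72) mirrors the study's observed composition.
- Per site and pool, total depth is Poisson(10) truncated to ≥ 1 —
  the simplest model consistent with a stated genome-wide mean — and mutant
  reads are Binomial(total, f(1−e) + (1−f)e).

What this does *not* emulate: read mapping and alignment artifacts, indel
realignment, base-quality structure, depth overdispersion, linked blocks of
background variation. Tests passing on this generator demonstrate the
statistics and the plumbing, not robustness to alignment noise.

A consequence worth stating plainly: at 10× depth even a clean dataset is
not deterministic. The causal site fails the strict >3-per-pool depth filter
in ≈2% of simulations (P(Poisson(10) ≤ 3 | ≥1) ≈ 1% per pool), and a
background site ties at 100% linkage when one pool happens to sample only
reference and the other only alternate reads (≈e^−10 per site). Unique
recovery of the causal site therefore succeeds in roughly 48–49 of 50 runs,
not always; `tests/test_acceptance.py` asserts the idealised 50/50 and the
shortfall is visible there rather than hidden by re-seeding.

## The gene fixture

The frameshift fixture is a synthetic 346-codon single-exon gene placed at
chr4:1001–2038 with 1000/500 nt flanks. Codon 332 is CGG (Arg); a single C
inserted after CDS position 993 turns it into CCG (Pro) and brings a TAG
stop into frame 8 codons downstream, so the new stop's first base lies 23 nt
3′ of the insertion junction. The layout was verified by direct manual
translation (wild type: no internal stop; mutant: P at 332, stop at codon
340), and the test suite re-verifies it with Biopython's translator,
independent of the projection code.

Consequence calling reports only the first changed residue for frameshifts
(the convention by which such alleles are named, e.g. R332P), maps the
premature stop back to wild-type genomic coordinates through the indel
offset, and uses the standard nuclear code (no selenocysteine or
non-canonical starts). Impact tiers: frameshift or premature stop → high;
missense or in-frame indel → moderate; synonymous → low; noncoding →
modifier.

## CAPS design

Recognition patterns are IUPAC strings compiled to overlapping-match regular
expressions and scanned on both strands (palindromic patterns such as
RCCGGY deduplicate to one strand); an independent position-by-position
matcher serves as the test oracle. Digestion is complete (every site cuts;
no partials, no methylation sensitivity), and fragment lengths always sum to
the amplicon length. Genotype banding: G = wild fragments, A = mutant
fragments, H = their union; an assay with identical G and A patterns is
flagged non-diagnostic.

The study's assay is modelled abstractly — a 300-bp amplicon whose mutant
allele gains one Cfr10I site 100 bp from an end, reproducing the published
band sizes (300 / 100+200 / all three) — because the actual primer
coordinates are not available. Band calling matches observed sizes to the
nearest expected pattern within a per-band tolerance, default 10 bp: gels do
not resolve exact sizes, and the default is a deliberate, configurable
convention. Diagnostic-site comparison is by position sets per allele, so an
indel that merely shifts a shared downstream site can appear as two
diagnostic sites; for assays designed around a single local variant this
does not arise.

## Segregation statistics

`chi_square_gof` is the Pearson statistic with no continuity correction;
the choice is empirical, demonstrated in the tests: all six published family
statistics (0.038, 0.058, 0.014, 0.051, 0.105, 0.179) are reproduced to
three decimals from the printed counts without correction, and none with
Yates' correction. p-values are reported numerically and as printed-table
brackets on the standard grid (0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.8, 0.9,
0.95), boundaries assigned to the lower bracket. One published bracket
(family 240: statistic 0.014, printed "0.8 < p < 0.9") is inconsistent with
its own statistic, whose p is 0.906; the package reports the correct
bracket and the corresponding acceptance assertion fails by design.

Percentages display half-up at three decimals (the convention of the
incidence table, e.g. 74/5438 → 1.361); two-decimal displays round the
three-decimal value (so 158266/336844 → 46.985 → 46.99).

One published column is deliberately not implemented: the ANOVA column of
the segregation table. Its printed Pr(>F) values are not reproducible from
the printed counts by any standard one-way ANOVA formulation, so no guess is
coded.

## Problem sizes and determinism

Tests and the acceptance script run on desk-scale inputs by design: 217
simulated variant sites per run (1 causal + 216 background), 50 simulation
seeds for the recovery property, 10 000 simulated seeds for incidence
checks, 1000 random 500-bp sequences for the site-scanner oracle. All
randomness flows through `numpy.random.default_rng` seeds carried in
`SimConfig` or passed explicitly; identical seeds give byte-identical VCF
and truth-table output. Property-based tests (hypothesis) run derandomised.
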
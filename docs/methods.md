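# Methods

## The trio sibship test

Given single-locus STR genotypes of two reference full siblings S1, S2 and
a tested individual S3, the test compares two hypotheses:

* **R** (related): S1, S2 and S3 are full siblings, i.e. share both parents;
* **U** (unrelated): S1 and S2 are full siblings and S3 is unrelated to them.

Writing G for the genotype set, the likelihood ratio at a locus is

    LR = P(G_S1, G_S2, G_S3 | full sibs) / [ P(G_S1, G_S2 | full sibs) · P(G_S3) ]

Both joint sibling probabilities are computed by exact summation over every
ordered pair of parental genotypes: each parent gets a Hardy–Weinberg prior
(a² for a homozygote, 2ab for a heterozygote) and each child contributes a
Mendelian transmission factor (each parent passes one of its two alleles
with probability 1/2). P(G_S3) is the Hardy–Weinberg probability of the
tested genotype. Multi-locus LRs are the product over independent
autosomal loci; the amelogenin sex marker is parsed but never scored.

The parental allele universe used in the summation is the set of alleles
observed in the sibling set plus **one** aggregated pseudo-allele carrying
all remaining frequency mass (unobserved table alleles plus any residual
mass of a table that does not sum to 1). The aggregation is exact, not an
approximation: no child carries an unobserved allele, so every unobserved
parental allele enters the sum with identical transmission factors and
their contributions add linearly in total unobserved frequency. This is
verified in the test suite by comparing against enumeration over explicit
full allele universes.

The duo sibling index uses the same engine with two genotypes,
U = P(G1)·P(G2). It equals the classical IBD mixture
κ₀ + κ₁·P(G2|1 IBD)/P(G2) + κ₂·1[G1=G2]/P(G2) with (κ₀, κ₁, κ₂) =
(1/4, 1/2, 1/4) for full siblings — a property test checks this identity to
1e-10 on 1,000 random draws. A duo can never be excluded (any two
genotypes have a compatible parent pair), and its SI is bounded below by
κ₀ = 1/4, attained when the pair shares no allele.

## Exclusions and the combined-LR floor

A trio whose three genotypes admit **no** compatible parental pair has
R = 0: a genetic inconsistency (exclusion). Since R is a sum of
non-negative terms, R == 0.0 in floating point exactly when every term is
structurally zero, so exclusion detection is exact.

When combining across loci, an excluded locus would annihilate the
product. Following forensic practice the per-locus LR is floored at 0.001
(configurable) at combination time, keeping combined LRs finite and
log-plottable while still penalising each inconsistency by three decades.
Whether such a floor should apply once per excluded locus or once per
profile is a genuine modelling choice; this package defaults to
**per-locus** substitution (LRs multiply across loci, so a per-locus
surrogate composes naturally, and trios with more inconsistencies score
lower), with `floor_scope="profile"` available to floor the whole product
once instead.

## Canonical trio pattern classes

Concrete genotypes map to pattern classes by replacing alleles with
letters: A–D for alleles observed in the reference pair, in order of first
appearance scanning S1 then S2, and X, Y for tested-individual alleles
absent from both references. The reference pair is oriented so the
genotype with fewer distinct alleles comes first, and among the remaining
labelling freedoms the lexicographically smallest class string is chosen —
making canonicalization deterministic, idempotent and invariant under
allele relabelling and reference swap (property-tested).

Exhaustive enumeration over the seven reference-pair classes (AA/AA,
AA/AB, AA/BB, AA/BC, AB/AB, AB/AC, AB/CD) and every S3 genotype yields
**63 distinct classes: 37 non-excluded and 26 excluded**. Exclusion is
decided combinatorially — existence of an ordered parental genotype pair
over the trio's alleles compatible with all three children — never by
thresholding a float. Historical accounts of this enumeration give totals
of 64 and 27 because the class AB/CD/BC is listed both as excluded and
(correctly — parents AC × BD produce all three) as non-excluded;
first-principles enumeration resolves the double count.

Classes that differ only in the identity of an unobserved allele (e.g.
`AB AB CC` vs `AB AB XX`) are one class; the X/Y spelling is canonical and
the observed-letter spelling is kept as an alias so either resolves.

### Closed forms, and corrections to the published ones

Each non-excluded class carries a closed-form LR as a ratio of polynomials
in the observed-allele frequencies a–d. The forms stored in this package
are derived by **symbolic** parental enumeration (`derive_closed_form`
reproduces every one of the 37 at run time; the test suite asserts exact
agreement, and separately checks the numeric engine against each form at
100 random frequency points to relative 1e-9). Unobserved-allele
frequencies always cancel, so the forms depend only on observed alleles.

Ten historically published forms differ from the exact LR:

| class | exact | published |
|---|---|---|
| AA AB AB | (1+3a+b)/(8ab+8a²b) | (1+3a)/(8ab+8a²b) |
| AB AB AA | (1+3a+b)/(4a+4ab+4a²+8a²b) | (1+3a)/(4a+4ab+4a²+4a²b) |
| AB AB AB | (1+3a+3b+12ab)/(8ab+8a²b+8ab²+16a²b²) | (1+3a+3b+9ab)/(8ab+8a²b+8ab²+8a²b²) |
| AB AB BB | (1+a+3b)/(4b+4ab+4b²+8ab²) | (1+3b)/(4b+4ab+4b²+4ab²) |
| AB AB AX | (1+4a)/(8a+8a²+8ab+16a²b) | (1+4a)/(8a+8a²+8ab+8a²b) |
| AB AB BX | (1+4b)/(8b+8ab+8b²+16ab²) | (1+4b)/(8b+8ab+8b²+8ab²) |
| AB AB XX | 1/(4+4a+4b+8ab) | 1/(4+4a+4b+4ab) |
| AB AC BC | (a+b+c)/(8bc+16abc) | (a+b)/(8bc+16abc) |
| AB AC BX | 1/(8b+16ab) | 1/(8b+8ab) |
| AB AC CX | 1/(8c+16ac) | 1/(8c+8ac) |

The published versions trace to a spreadsheet shorthand that lumps "any
other allele" into a single symbol with frequency 1−a and a uniform 1/4
transmission factor. That shorthand is exact when the extra allele really
is unobserved (which is why the other 27 forms, and the worked AA/AB/AC
example, are correct) but miscounts parent pairs whose lumped allele
coincides with an observed allele B, whose true transmission factor is
1/2. The printed strings are retained on each pattern as
`published_display` with a `matches_published` flag; a regression test
pins the deviation set to exactly these ten classes. The deviations are
modest in magnitude at forensic allele frequencies (the largest arise for
AB AC BC) and do not change any exclusion status.

## Population simulation

Families are simulated under the same model the likelihoods assume: both
parents draw two alleles per locus i.i.d. from the frequency table (HWE),
children receive one uniformly chosen allele from each parent. Population
modes: 3S (two reference siblings + true sibling), 2S1U (+ unrelated
individual drawn from HWE), and duo controls 2S/2U scored with the duo SI.
Duo control populations are fresh draws, not reuses of the trio families.

* **Seeding**: one root seed spawns a `numpy` `SeedSequence` child stream
  per family, so populations are bit-identical given (table, n, mode,
  seed) and independent of generation order. Byte-exact reproducibility of
  the TSV serialisation is tested.
* **Residual mass** of a frequency table is materialised as one explicit
  synthetic allele `_OTHER` during simulation so every sampled genotype is
  scoreable.
* **Scoring** memoises per-locus results by genotype combination, which
  reduces population scoring from one parental enumeration per
  family-locus to one per *distinct* combination (~30 s for 10,000
  15-locus families on one CPU).

### The synthetic panel as a stated world

The population study this package models used a 15-locus Identifiler panel
with frequencies from a published population survey; that table is not
redistributable, so the packaged generator stands in for it: 15 loci
(Identifiler names), 8 alleles per locus, frequencies drawn from a
symmetric Dirichlet with concentration 1.0 (a flat prior over frequency
vectors — some loci come out skewed, some balanced, bracketing realistic
STR heterozygosities), labels mimicking repeat numbers. Equifrequent
panels and other shapes are available through parameters.

What the generator does **not** emulate: real STR allele-frequency shapes
(unimodal around common repeat counts), mutation (so true siblings are
never excluded by construction — the simulated 3S exclusion count is
exactly 0, while real data would show rare mutation-driven
inconsistencies), population substructure/θ-correction, linkage between
loci, and genotyping error. A green population test therefore establishes
that the *method* separates related from unrelated trios on a comparably
polymorphic panel — sensitivity and specificity ≥ 99% at LR > 1, ≤ 5%
of non-sibling trios escaping exclusion, median log₁₀ LR separation > 10
decades at n = 10,000 — not that any specific published percentage is
reproduced. With a real frequency table supplied, published operating
characteristics are expected to fall within binomial Monte-Carlo error.

## Classification metrics

Sensitivity, specificity, PPV, NPV as usual (percentages). Accuracy is
(TP+TN)/(TP+TN+FP+FN): prose definitions of accuracy as TP/(TP+FP+FN)
circulate in this literature, but only the standard formula reproduces the
operating points those same sources print, so the standard formula is
used. Threshold strictness is explicit: "greater than t" (strict) and "at
least t" (non-strict) are both supported because published operating
points mix the two (LR > 1 strict, LR ≥ 100 non-strict).

Display rounding of percentages is half-up to two decimals and computed
exactly from the integer counts via decimal arithmetic, because binary
floats misround exact halves (e.g. 19 849/20 000 = 99.245% must display as
99.25); unrounded values are kept for computation.

Distribution summaries (mean, sample SD with n−1, min, max of log₁₀ LR)
require strictly positive LRs — i.e. the exclusion floor must already have
been applied.

## Numerical choices

* Likelihood sums run in IEEE double precision over at most 7×8/2 = 28
  parental genotypes; closed-form agreement to relative 1e-9 over random
  frequency points is asserted in tests (observed error ~1e-15).
* The allele universe and the child factors are processed in a canonical
  sorted order, so mathematically exact symmetries (swapping S1/S2,
  permuting a sibling set) are bit-exact, not approximate.
* Allele labels are opaque text ("30.2" is never parsed as a number except
  for display ordering), avoiding float-equality traps on microvariants.
* Frequency tables reject non-positive frequencies and per-locus sums
  above 1 + 1e-9; missing mass becomes residual. An observed allele absent
  from the table raises by default; an optional `min_frequency` floor can
  substitute a value, off by default because silent flooring hides data
  problems.

## Known limitations

Only the full-sibling-of-both vs unrelated hypothesis pair is implemented
(no half-sibling, avuncular or parent–offspring alternatives); no θ/Fst
correction, mutation model, silent/null alleles or linked loci; analytical
power of exclusion is not computed (the empirical per-locus exclusion
fraction in a 2S1U population substitutes); pedigrees beyond one nuclear
family are out of scope.
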
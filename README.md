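# triosib

Trio sibship testing with STR markers: likelihood ratios for "is this
person a full sibling of these two reference siblings?", exhaustive
enumeration of trio genotype classes with verified closed-form LR
formulas, virtual-population simulation, and classification operating
characteristics.

## Who this is for

Forensic geneticists and kinship analysts — e.g. disaster-victim
identification where the only living references for a deceased person are
two confirmed siblings. Comparing one putative sibling against a single
reference is weak (full sibs share no allele at a locus with probability
1/4); testing against **two** reference siblings both sharpens inclusions
and creates the possibility of outright exclusion.

## The statistic

At one STR locus with genotypes G₁, G₂ (reference siblings) and G₃
(tested), the sibship LR compares the hypotheses *all three are full
siblings* vs *S3 unrelated*:

    LR = P(G₁, G₂, G₃ | sibs) / [ P(G₁, G₂ | sibs) · P(G₃) ]

Joint sibling probabilities are exact sums over ordered parental genotype
pairs, with Hardy–Weinberg priors on parents and Mendelian transmission to
each child; P(G₃) is the HWE genotype probability. Per-locus LRs multiply
across independent autosomal loci; a locus where no parental pair can
produce all three genotypes is a genetic inconsistency (LR = 0) and
contributes a floor value (default 0.001) to the product. The duo sibling
index (one reference) is the same construction and equals the classical
IBD mixture with κ = (1/4, 1/2, 1/4).

Every trio of single-locus genotypes falls into one of 63 canonical
pattern classes (letters A–D for alleles seen in the references, X/Y for
new alleles in the tested individual); 37 classes are non-excluded and
carry closed-form LRs — stored in exact, symbolically re-derivable form,
with the historically published (and in ten cases inexact) versions
retained for reference — and 26 are exclusions. See `docs/methods.md` for
the derivation and the corrections.

## Worked example

`examples/trio_case_report.py` scores a worked 15-locus case — two
confirmed siblings S1, S2 and a putative sibling S3 — against a synthetic
frequency table (each observed allele at 10%):

```
locus     S1     S2      S3      SI S1-S3  SI S2-S3  SI S1,S2-S3
D8S1179   12,17  13,15   12,15   1.500     1.500     6.250
CSF1PO    12,13  9,11    9,11    0.250     15.250    12.500
D3S1358   15,17  15,15   17,17   2.750     0.250     2.273
FGA       21,21  21,22   19,22   0.250     1.500     1.136
...
Combined SI                      300994920.918  28827536.366  63091369427906.961
```

The 0.250 cells are pairs sharing no allele: the duo SI falls to the κ₀ =
1/4 prior and no frequency can change that. The trio combined SI exceeds
both duo combined SIs by orders of magnitude — two references are far more
decisive than one.

`examples/simulate_and_classify.py` simulates 2,000 true-sibling (3S) and
2,000 non-sibling (2S1U) trios on a synthetic 15-locus / 8-allele panel
and prints (actual output):

```
population     mean      sd      min      max   (log10 LR)
3S          6.778   2.138    -1.06    14.04
2S1U      -12.743   4.808   -34.49    -0.16

LR > 1     sensitivity  99.90%  specificity 100.00%  accuracy  99.95%
LR >= 100  sensitivity  98.80%  specificity 100.00%  accuracy  99.40%

non-sibling trios with no excluding locus: 31 of 2000 (1.55%)
```

True-sibling trios sit ~20 decades of LR above non-sibling trios; ~98% of
unrelated trios are caught by at least one genetic inconsistency.
`examples/enumerate_patterns.py` prints the full 63-class table with
closed forms.

## Library surface

`triosib` exposes: genotype/profile/frequency-table types and CSV I/O
(`load_frequency_table`, `load_profiles`), the likelihood engine
(`sib_set_likelihood`, `trio_lr_locus`, `duo_si_locus`, `combined_lr`),
pattern machinery (`enumerate_trio_patterns`, `canonicalize_trio`,
`closed_form_lr`, `derive_closed_form`), simulation
(`simulate_population`, `sample_parent`, `sample_child`,
`synthetic_panel`), metrics (`confusion_at_threshold`,
`lr_distribution_summary`, `inconsistency_locus_counts`,
`per_locus_exclusion_power`) and case reporting (`case_report`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-enumerates the canonical trio pattern classes from first principles,
verifies each non-excluded class's closed form against the brute-force
likelihood engine at a seeded random frequency point, and writes the
resulting class count as JSON.
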
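"""Sibship likelihood engine.

The probability that a set of genotypes at one locus belongs to full
siblings is obtained by exact summation over every ordered pair of parental
genotypes: each parent receives a Hardy-Weinberg prior and each child
contributes a Mendelian transmission factor given those parents.

The parental allele universe is the set of alleles observed in the sibling
set plus one aggregated pseudo-allele carrying all remaining probability
mass (unobserved table alleles plus the table's residual mass).  The
aggregation is exact: no child carries an unobserved allele, so the
transmission factors attached to every unobserved parental allele are
identical and their contributions sum linearly in total unobserved
frequency.  This keeps the enumeration at most seven alleles wide no matter
how many alleles the locus has.

Hypotheses compared
-------------------
* trio: S1, S2 and S3 are full siblings (R) versus S1, S2 full siblings and
  S3 unrelated (U); the likelihood ratio is R/U.
* duo: the classical full-sibling index between two genotypes, computed
  with the same engine (it equals the IBD mixture with kappa = 1/4, 1/2,
  1/4).

A locus where no parental pair can produce all three genotypes has R = 0
and is an exclusion (genetic inconsistency).  When multiplying across loci
an excluded locus contributes a configurable floor (default 0.001) instead
of zero so the combined LR stays finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genotypes import (
    NON_AUTOSOMAL_LOCI,
    AlleleFrequencyTable,
    GenotypeObservation,
    Profile,
    allele_sort_key,
    genotype_prob_hwe,
)

__all__ = [
    "DEFAULT_FLOOR",
    "LocusLikelihoodResult",
    "CombinedLR",
    "sib_set_likelihood",
    "trio_lr_locus",
    "duo_si_locus",
    "combined_lr",
]

DEFAULT_FLOOR = 0.001

# Sentinel label for the aggregated unobserved-allele mass.  Never appears in
# user genotypes (labels come from CSV fields and cannot contain this form).
_OTHER = "\x00OTHER"


def _locus_arrays(
    genotypes: Sequence[GenotypeObservation], f: AlleleFrequencyTable
) -> Tuple[List[str], np.ndarray]:
    """Observed-allele universe and its frequency vector (with pseudo-allele).

    The universe is sorted canonically so the summation order (and hence the
    floating-point result) does not depend on the order genotypes were given
    in -- this makes symmetries like swapping the reference siblings exact.
    """
    observed = sorted(
        {a for g in genotypes for a in g.alleles}, key=allele_sort_key
    )
    freqs = [f.freq(a) for a in observed]
    other = 1.0 - sum(freqs)
    if other > 1e-12:
        observed.append(_OTHER)
        freqs.append(other)
    return observed, np.asarray(freqs)


def sib_set_likelihood(
    genotypes: Sequence[GenotypeObservation], f: AlleleFrequencyTable
) -> float:
    """Joint probability that ``genotypes`` are full siblings at one locus.

    Sum over ordered parental genotype pairs of
    ``P_HWE(father) * P_HWE(mother) * prod_children P(child | parents)``.

    With a single genotype this reduces to its Hardy-Weinberg probability.
    """
    if not genotypes:
        raise ValueError("sib_set_likelihood requires at least one genotype")
    locus = genotypes[0].locus_name
    for g in genotypes[1:]:
        if g.locus_name != locus:
            raise ValueError(
                f"genotypes span loci {locus!r} and {g.locus_name!r}"
            )
    alleles, freq = _locus_arrays(genotypes, f)
    k = len(alleles)
    index = {a: i for i, a in enumerate(alleles)}

    # Parental genotypes: all unordered pairs i <= j with HWE priors.
    ii, jj = np.triu_indices(k)
    prior = freq[ii] * freq[jj]
    prior[ii != jj] *= 2.0  # heterozygote 2ab

    # trans[u, g]: probability parental genotype g transmits allele u.
    geno_alleles = np.stack([ii, jj], axis=1)  # (G, 2)
    trans = 0.5 * (
        (geno_alleles[:, 0][None, :] == np.arange(k)[:, None]).astype(float)
        + (geno_alleles[:, 1][None, :] == np.arange(k)[:, None]).astype(float)
    )  # (k, G); homozygote transmits with probability 1, carrier het with 1/2

    total = prior[:, None] * prior[None, :]
    # canonical child order, so sibling-set permutations give identical floats
    for g in sorted(genotypes, key=lambda x: x.alleles):
        u, v = (index[a] for a in g.alleles)
        tu, tv = trans[u], trans[v]
        if u == v:
            child = np.outer(tu, tu)
        else:
            child = np.outer(tu, tv) + np.outer(tv, tu)
        total *= child
    return float(total.sum())


@dataclass(frozen=True)
class LocusLikelihoodResult:
    """Single-locus likelihoods under the sibling (R) and unrelated (U) hypotheses."""

    locus_name: str
    numerator_R: float
    denominator_U: float
    lr: float
    excluded: bool


def trio_lr_locus(
    s1: GenotypeObservation,
    s2: GenotypeObservation,
    s3: GenotypeObservation,
    f: AlleleFrequencyTable,
) -> LocusLikelihoodResult:
    """Trio sibship LR at one locus: full sibling of S1 and S2 vs unrelated.

    ``R = P(S1, S2, S3 full sibs)``;
    ``U = P(S1, S2 full sibs) * P_HWE(S3)``.
    Symmetric under swapping the reference siblings S1 and S2.  ``excluded``
    is True exactly when R = 0, i.e. no parental pair can produce all three.
    """
    if not (s1.locus_name == s2.locus_name == s3.locus_name):
        raise ValueError("trio genotypes must share a locus")
    numerator = sib_set_likelihood([s1, s2, s3], f)
    denominator = sib_set_likelihood([s1, s2], f) * genotype_prob_hwe(s3, f)
    return LocusLikelihoodResult(
        locus_name=s1.locus_name,
        numerator_R=numerator,
        denominator_U=denominator,
        lr=numerator / denominator,
        excluded=numerator == 0.0,
    )


def duo_si_locus(
    g1: GenotypeObservation,
    g2: GenotypeObservation,
    f: AlleleFrequencyTable,
) -> LocusLikelihoodResult:
    """Single-locus sibling index between two genotypes.

    Never an exclusion: any two genotypes are compatible with some parental
    pair, and the LR is bounded below by the kappa_0 = 1/4 term.
    """
    if g1.locus_name != g2.locus_name:
        raise ValueError("duo genotypes must share a locus")
    numerator = sib_set_likelihood([g1, g2], f)
    denominator = genotype_prob_hwe(g1, f) * genotype_prob_hwe(g2, f)
    return LocusLikelihoodResult(
        locus_name=g1.locus_name,
        numerator_R=numerator,
        denominator_U=denominator,
        lr=numerator / denominator,
        excluded=False,
    )


@dataclass(frozen=True)
class CombinedLR:
    """Multi-locus combined LR with the exclusion-floor policy applied."""

    per_locus: Tuple[LocusLikelihoodResult, ...]
    floor_value: float
    combined: float
    log10_combined: float

    @property
    def n_excluded(self) -> int:
        return sum(r.excluded for r in self.per_locus)


FloorScope = Literal["locus", "profile"]


def combine_locus_results(
    results: Sequence[LocusLikelihoodResult],
    floor: float = DEFAULT_FLOOR,
    floor_scope: FloorScope = "locus",
) -> CombinedLR:
    """Multiply per-locus LRs, substituting ``floor`` at excluded loci.

    ``floor_scope="locus"`` (default) substitutes the floor once per excluded
    locus; ``"profile"`` replaces the entire product by the floor if any
    locus excludes.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if not results:
        raise ValueError("no locus results to combine")
    if floor_scope == "locus":
        combined = 1.0
        for r in results:
            combined *= floor if r.excluded else r.lr
    elif floor_scope == "profile":
        if any(r.excluded for r in results):
            combined = floor
        else:
            combined = math.prod(r.lr for r in results)
    else:
        raise ValueError(f"unknown floor_scope {floor_scope!r}")
    return CombinedLR(
        per_locus=tuple(results),
        floor_value=floor,
        combined=combined,
        log10_combined=math.log10(combined),
    )


def combined_lr(
    profiles: Sequence[Profile],
    freqs: Mapping[str, AlleleFrequencyTable],
    floor: float = DEFAULT_FLOOR,
    floor_scope: FloorScope = "locus",
    loci: Optional[Sequence[str]] = None,
) -> CombinedLR:
    """Combined sibship LR for a trio (or duo SI for a pair) of profiles.

    The product runs over the autosomal loci shared by all profiles and
    present in the frequency table (or the explicit ``loci`` subset).
    Sex-typing markers (AMEL) are skipped.
    """
    if len(profiles) == 3:
        scorer = trio_lr_locus
    elif len(profiles) == 2:
        scorer = duo_si_locus
    else:
        raise ValueError("combined_lr takes two (duo) or three (trio) profiles")

    shared = set(profiles[0].genotypes)
    for p in profiles[1:]:
        shared &= set(p.genotypes)
    shared &= set(freqs)
    shared -= {l for l in shared if l.upper() in NON_AUTOSOMAL_LOCI}
    if loci is not None:
        shared &= set(loci)
    if not shared:
        raise ValueError("profiles share no autosomal loci covered by the table")

    results = [
        scorer(*(p.genotype(l) for p in profiles), freqs[l])
        for l in sorted(shared)
    ]
    return combine_locus_results(results, floor=floor, floor_scope=floor_scope)
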
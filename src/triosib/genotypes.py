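"""Core domain types for STR kinship analysis.

Alleles are opaque text labels (repeat designations such as ``"9.3"`` or
``"30.2"``); they are never parsed numerically except to produce a stable
display order.  A locus is described by an :class:`AlleleFrequencyTable`
holding strictly positive population frequencies; tables that omit rare
alleles are accepted and the missing probability mass is tracked as
``residual_mass``.  Genotypes are unordered pairs of allele labels.

Hardy-Weinberg genotype probabilities (``a**2`` for a homozygote, ``2ab``
for a heterozygote) and Mendelian single-allele transmission probabilities
are the two primitives every likelihood computation in this package is
built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

__all__ = [
    "NON_AUTOSOMAL_LOCI",
    "AlleleFrequencyTable",
    "GenotypeObservation",
    "Profile",
    "allele_sort_key",
    "genotype_prob_hwe",
    "transmission_prob",
]

_SUM_TOL = 1e-9

#: Sex-typing markers: parsed and carried in profiles but excluded from all
#: kinship likelihoods.
NON_AUTOSOMAL_LOCI = frozenset({"AMEL", "AMELOGENIN"})


def allele_sort_key(label: str):
    """Numeric-then-lexicographic ordering key for allele labels.

    ``"9"`` sorts before ``"9.3"`` sorts before ``"10"``; non-numeric labels
    (e.g. ``"X"``) sort after all numeric ones, alphabetically.
    """
    try:
        return (0, float(label), label)
    except ValueError:
        return (1, 0.0, label)


class TableError(ValueError):
    """Invalid allele-frequency table."""


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Allele frequencies at a single locus.

    Parameters
    ----------
    locus_name:
        Marker name, e.g. ``"D18S51"``.
    entries:
        Map allele label -> population frequency in (0, 1].
    min_frequency:
        Optional floor substituted for alleles absent from the table.  Off by
        default: an unknown allele raises instead, because silent flooring
        hides data problems.
    """

    locus_name: str
    entries: Mapping[str, float]
    min_frequency: Optional[float] = None
    residual_mass: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if not self.entries:
            raise TableError(f"locus {self.locus_name!r}: empty frequency table")
        total = 0.0
        for allele, freq in self.entries.items():
            if not (0.0 < freq <= 1.0):
                raise TableError(
                    f"locus {self.locus_name!r}, allele {allele!r}: "
                    f"frequency {freq!r} outside (0, 1]"
                )
            total += freq
        if total > 1.0 + _SUM_TOL:
            raise TableError(
                f"locus {self.locus_name!r}: frequencies sum to {total:.6g} > 1"
            )
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "residual_mass", max(0.0, 1.0 - total))

    def freq(self, allele: str) -> float:
        """Frequency of ``allele``, applying ``min_frequency`` if configured."""
        try:
            return self.entries[allele]
        except KeyError:
            if self.min_frequency is not None:
                return self.min_frequency
            raise TableError(
                f"locus {self.locus_name!r}: allele {allele!r} not in frequency table"
            ) from None

    @property
    def alleles(self) -> Tuple[str, ...]:
        return tuple(sorted(self.entries, key=allele_sort_key))

    def __contains__(self, allele: str) -> bool:
        return allele in self.entries


@dataclass(frozen=True)
class GenotypeObservation:
    """Unordered pair of allele labels at one locus (homozygote = same label twice)."""

    locus_name: str
    alleles: Tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("a genotype is exactly two allele labels")
        a, b = self.alleles
        if allele_sort_key(b) < allele_sort_key(a):
            object.__setattr__(self, "alleles", (b, a))
        else:
            object.__setattr__(self, "alleles", (a, b))

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def __str__(self) -> str:
        return f"{self.alleles[0]},{self.alleles[1]}"


@dataclass(frozen=True)
class Profile:
    """Multi-locus genotype profile for one named individual."""

    sample_id: str
    genotypes: Mapping[str, GenotypeObservation]

    def __post_init__(self) -> None:
        for locus, g in self.genotypes.items():
            if g.locus_name != locus:
                raise ValueError(
                    f"profile {self.sample_id!r}: genotype at key {locus!r} "
                    f"is for locus {g.locus_name!r}"
                )
        object.__setattr__(self, "genotypes", dict(self.genotypes))

    @property
    def autosomal_loci(self) -> Tuple[str, ...]:
        return tuple(
            l for l in self.genotypes if l.upper() not in NON_AUTOSOMAL_LOCI
        )

    def genotype(self, locus: str) -> GenotypeObservation:
        return self.genotypes[locus]


def genotype_prob_hwe(g: GenotypeObservation, f: AlleleFrequencyTable) -> float:
    """Hardy-Weinberg probability of genotype ``g``: ``a**2`` or ``2ab``."""
    p, q = (f.freq(a) for a in g.alleles)
    if g.is_homozygous:
        return p * p
    return 2.0 * p * q


def transmission_prob(parent: GenotypeObservation, allele: str) -> float:
    """Probability a parent transmits ``allele``: 1, 1/2 or 0 by Mendel."""
    a, b = parent.alleles
    if a == b:
        return 1.0 if allele == a else 0.0
    if allele == a or allele == b:
        return 0.5
    return 0.0


def make_profile(sample_id: str, genotypes: Iterable[Tuple[str, str, str]]) -> Profile:
    """Convenience constructor from ``(locus, allele1, allele2)`` triples."""
    gmap: Dict[str, GenotypeObservation] = {}
    for locus, a1, a2 in genotypes:
        if locus in gmap:
            raise ValueError(f"profile {sample_id!r}: duplicate locus {locus!r}")
        gmap[locus] = GenotypeObservation(locus, (a1, a2))
    return Profile(sample_id, gmap)
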
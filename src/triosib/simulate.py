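"""Virtual-population simulation for sibship testing.

Families are generated under Hardy-Weinberg equilibrium and Mendelian
transmission: both parents draw two alleles per locus i.i.d. from the
population frequency table, and each child receives one uniformly chosen
allele from each parent.  From such families four population modes are
assembled:

``3S``
    two reference siblings plus a true third sibling (all three share the
    simulated parents); scored with the trio LR.
``2S1U``
    two reference siblings plus an individual drawn independently from HWE;
    scored with the trio LR.
``2S`` / ``2U``
    duo controls -- two siblings, or two unrelated individuals -- scored
    with the duo sibling index.

Population substructure and mutation are deliberately not modelled.

Reproducibility: a single root seed spawns one child RNG stream per family
(:class:`numpy.random.SeedSequence`), so populations are bit-identical for
a given (table, n, mode, seed) and independent of generation order.  A
table's unobserved residual mass is materialised as one explicit synthetic
allele (``_OTHER``) so every simulated genotype can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genotypes import AlleleFrequencyTable, GenotypeObservation, Profile
from .kinship import (
    DEFAULT_FLOOR,
    LocusLikelihoodResult,
    combine_locus_results,
    duo_si_locus,
    trio_lr_locus,
)

__all__ = [
    "MODES",
    "RESIDUAL_ALLELE",
    "TrioRecord",
    "TrioPopulation",
    "sample_parent",
    "sample_child",
    "simulate_population",
]

MODES = ("3S", "2S1U", "2S", "2U")

#: Label given to the aggregated unobserved mass of a frequency table when
#: simulating, so that sampled profiles are always scoreable.
RESIDUAL_ALLELE = "_OTHER"


def _augmented(table: AlleleFrequencyTable) -> AlleleFrequencyTable:
    """Table with residual mass assigned to an explicit ``_OTHER`` allele."""
    if table.residual_mass <= 1e-12:
        return table
    entries = dict(table.entries)
    entries[RESIDUAL_ALLELE] = table.residual_mass
    return AlleleFrequencyTable(table.locus_name, entries, table.min_frequency)


@dataclass(frozen=True)
class TrioRecord:
    """One simulated family record: two or three member profiles plus truth."""

    family_id: int
    mode: str
    members: Tuple[Profile, ...]


@dataclass(frozen=True)
class TrioPopulation:
    """A scored population of simulated trios (or duos).

    ``combined_lrs`` are post-floor combined LRs aligned with ``records``;
    ``excluded`` is an (n, n_loci) boolean matrix of per-locus genetic
    inconsistencies (all False in duo modes, where exclusion cannot occur).
    """

    mode: str
    seed: int
    frequency_table_id: str
    loci: Tuple[str, ...]
    records: Tuple[TrioRecord, ...]
    combined_lrs: np.ndarray
    excluded: np.ndarray
    floor_value: float

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def log10_combined_lrs(self) -> np.ndarray:
        return np.log10(self.combined_lrs)

    def to_tsv(self) -> str:
        """One row per record: family id, member genotype strings, log10 LR."""
        n_members = len(self.records[0].members)
        header = ["family_id", "mode"]
        for m in range(n_members):
            header.append(f"member{m + 1}")
        header += ["n_excluded_loci", "log10_combined_lr"]
        lines = ["\t".join(header)]
        for i, rec in enumerate(self.records):
            cells = [str(rec.family_id), rec.mode]
            for prof in rec.members:
                cells.append(
                    ";".join(
                        f"{l}:{prof.genotype(l)}" for l in self.loci
                    )
                )
            cells.append(str(int(self.excluded[i].sum())))
            cells.append(f"{np.log10(self.combined_lrs[i]):.10g}")
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


def sample_parent(
    freqs: Mapping[str, AlleleFrequencyTable],
    rng: np.random.Generator,
    sample_id: str = "P",
) -> Profile:
    """Draw one individual: at each locus two alleles i.i.d. from the table (HWE)."""
    loci = list(freqs)
    tables = [_augmented(freqs[l]) for l in loci]
    labels = [list(t.entries) for t in tables]
    cum = [np.cumsum([t.entries[a] for a in t.entries]) for t in tables]
    u = rng.random((len(loci), 2))
    genos = {}
    for i, locus in enumerate(loci):
        j1 = int(np.searchsorted(cum[i], u[i, 0], side="right"))
        j2 = int(np.searchsorted(cum[i], u[i, 1], side="right"))
        j1 = min(j1, len(labels[i]) - 1)
        j2 = min(j2, len(labels[i]) - 1)
        genos[locus] = GenotypeObservation(locus, (labels[i][j1], labels[i][j2]))
    return Profile(sample_id, genos)


def sample_child(
    father: Profile,
    mother: Profile,
    rng: np.random.Generator,
    sample_id: str = "C",
) -> Profile:
    """Mendelian child: one uniformly chosen allele from each parent per locus."""
    if set(father.genotypes) != set(mother.genotypes):
        raise ValueError("parents must cover the same loci")
    loci = list(father.genotypes)
    picks = rng.integers(0, 2, size=(len(loci), 2))
    genos = {}
    for i, locus in enumerate(loci):
        pa = father.genotype(locus).alleles[picks[i, 0]]
        ma = mother.genotype(locus).alleles[picks[i, 1]]
        genos[locus] = GenotypeObservation(locus, (pa, ma))
    return Profile(sample_id, genos)


class _LocusScoreCache:
    """Memoises per-locus trio/duo likelihood results by genotype combination.

    Simulated populations revisit the same genotype combinations constantly;
    caching turns the population scoring from O(n * loci) brute-force
    enumerations into O(distinct combinations).
    """

    def __init__(self, tables: Mapping[str, AlleleFrequencyTable]):
        self.tables = tables
        self._trio: Dict[Tuple, LocusLikelihoodResult] = {}
        self._duo: Dict[Tuple, LocusLikelihoodResult] = {}

    def trio(self, g1, g2, g3) -> LocusLikelihoodResult:
        # trio LR is symmetric in the reference pair: normalise the key
        k1, k2 = sorted([g1.alleles, g2.alleles])
        key = (g1.locus_name, k1, k2, g3.alleles)
        res = self._trio.get(key)
        if res is None:
            res = trio_lr_locus(g1, g2, g3, self.tables[g1.locus_name])
            self._trio[key] = res
        return res

    def duo(self, g1, g2) -> LocusLikelihoodResult:
        k1, k2 = sorted([g1.alleles, g2.alleles])
        key = (g1.locus_name, k1, k2)
        res = self._duo.get(key)
        if res is None:
            res = duo_si_locus(g1, g2, self.tables[g1.locus_name])
            self._duo[key] = res
        return res


def simulate_population(
    freqs: Mapping[str, AlleleFrequencyTable],
    n: int,
    mode: str,
    seed: int,
    floor: float = DEFAULT_FLOOR,
    table_id: str = "",
    keep_profiles: bool = True,
) -> TrioPopulation:
    """Simulate and score ``n`` families in the given mode.

    Each record's combined LR is the product of per-locus trio LRs (duo SIs
    in the duo modes) over all loci of the table, with excluded loci
    contributing ``floor``.  Set ``keep_profiles=False`` to drop member
    profiles from the records and save memory on large runs (scores and
    exclusion matrix are always kept).
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    loci = tuple(freqs)
    aug = {l: _augmented(freqs[l]) for l in loci}
    score_tables = {l: freqs[l] if freqs[l].residual_mass <= 1e-12 else aug[l] for l in loci}
    cache = _LocusScoreCache(score_tables)

    streams = np.random.SeedSequence(seed).spawn(n)
    records: List[TrioRecord] = []
    combined = np.empty(n)
    excluded = np.zeros((n, len(loci)), dtype=bool)

    n_sibs = {"3S": 3, "2S1U": 2, "2S": 2, "2U": 0}[mode]
    n_unrelated = {"3S": 0, "2S1U": 1, "2S": 0, "2U": 2}[mode]

    for fam in range(n):
        rng = np.random.default_rng(streams[fam])
        members: List[Profile] = []
        if n_sibs:
            father = sample_parent(aug, rng, "F")
            mother = sample_parent(aug, rng, "M")
            for s in range(n_sibs):
                members.append(sample_child(father, mother, rng, f"S{s + 1}"))
        for u in range(n_unrelated):
            members.append(sample_parent(aug, rng, f"U{u + 1}"))

        results = []
        for j, locus in enumerate(loci):
            gs = [m.genotype(locus) for m in members]
            if len(members) == 3:
                res = cache.trio(*gs)
            else:
                res = cache.duo(*gs)
            excluded[fam, j] = res.excluded
            results.append(res)
        combined[fam] = combine_locus_results(results, floor=floor).combined
        records.append(
            TrioRecord(fam, mode, tuple(members) if keep_profiles else ())
        )

    return TrioPopulation(
        mode=mode,
        seed=seed,
        frequency_table_id=table_id,
        loci=loci,
        records=tuple(records),
        combined_lrs=combined,
        excluded=excluded,
        floor_value=floor,
    )
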
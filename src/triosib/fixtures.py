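"""Synthetic allele-frequency panels and example families.

The published population study behind this package used a 15-locus
Identifiler panel with frequencies from a published population survey that
is not redistributable here.  These generators stand in for such a table: they
produce panels with a configurable number of loci and alleles per locus,
either equifrequent or Dirichlet-drawn, plus optional simulated families
with known truth labels, so every analysis in the package can run without
external downloads.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genotypes import AlleleFrequencyTable, Profile
from .simulate import sample_child, sample_parent

__all__ = ["IDENTIFILER_AUTOSOMAL_LOCI", "synthetic_panel", "synthetic_family"]

#: The 15 autosomal STR loci of the AmpFlSTR Identifiler kit.
IDENTIFILER_AUTOSOMAL_LOCI: Tuple[str, ...] = (
    "D8S1179",
    "D21S11",
    "D7S820",
    "CSF1PO",
    "D3S1358",
    "TH01",
    "D13S317",
    "D16S539",
    "D2S1338",
    "D19S433",
    "VWA",
    "TPOX",
    "D18S51",
    "D5S818",
    "FGA",
)


def synthetic_panel(
    n_loci: int = 15,
    alleles_per_locus: int = 8,
    concentration: Optional[float] = 1.0,
    seed: int = 0,
    locus_names: Optional[Sequence[str]] = None,
) -> Dict[str, AlleleFrequencyTable]:
    """Generate a synthetic multi-locus frequency panel.

    ``concentration`` is the symmetric Dirichlet parameter for the allele
    frequencies (larger = closer to equifrequent); ``None`` gives exactly
    equifrequent alleles.  Allele labels are repeat numbers starting at 8,
    mimicking STR nomenclature.  Frequencies sum to 1 at every locus.
    """
    if n_loci < 1 or alleles_per_locus < 1:
        raise ValueError("need at least one locus and one allele per locus")
    if concentration is not None and concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    if locus_names is None:
        if n_loci <= len(IDENTIFILER_AUTOSOMAL_LOCI):
            locus_names = IDENTIFILER_AUTOSOMAL_LOCI[:n_loci]
        else:
            locus_names = [f"L{i + 1}" for i in range(n_loci)]
    elif len(locus_names) != n_loci:
        raise ValueError("locus_names length must equal n_loci")

    rng = np.random.default_rng(seed)
    labels = [str(8 + i) for i in range(alleles_per_locus)]
    panel: Dict[str, AlleleFrequencyTable] = {}
    for locus in locus_names:
        if concentration is None:
            freqs = np.full(alleles_per_locus, 1.0 / alleles_per_locus)
        else:
            freqs = rng.dirichlet(np.full(alleles_per_locus, concentration))
        # guard against numerically zero frequencies from extreme draws
        freqs = np.clip(freqs, 1e-9, None)
        freqs /= freqs.sum()
        panel[locus] = AlleleFrequencyTable(
            locus, dict(zip(labels, freqs.tolist()))
        )
    return panel


def synthetic_family(
    freqs: Dict[str, AlleleFrequencyTable],
    n_children: int = 3,
    seed: int = 0,
) -> Tuple[Profile, Profile, List[Profile]]:
    """One nuclear family: HWE parents plus ``n_children`` Mendelian children."""
    rng = np.random.default_rng(seed)
    father = sample_parent(freqs, rng, "F")
    mother = sample_parent(freqs, rng, "M")
    children = [
        sample_child(father, mother, rng, f"S{i + 1}") for i in range(n_children)
    ]
    return father, mother, children
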
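"""Shared fixtures: tiny frequency tables and a worked trio case.

The trio case genotypes follow a classic published duo/trio sibship case
(two confirmed siblings and one putative third sibling typed at the 15
Identifiler autosomal loci plus amelogenin).  The accompanying frequency
table is synthetic: the population study's real frequency source is not
redistributable, so each observed allele is assigned a plausible frequency
and the remainder is residual mass.  Only frequency-free quantities (e.g.
duo SI = 1/4 at zero shared alleles) are asserted against published values.
"""

import pytest

from triosib import AlleleFrequencyTable, make_profile

# (locus, S1, S2, S3) genotypes of the worked trio case
TRIO_CASE_GENOTYPES = [
    ("D8S1179", ("12", "17"), ("13", "15"), ("12", "15")),
    ("D21S11", ("29", "31"), ("29", "30.2"), ("30.2", "31")),
    ("D7S820", ("8", "11"), ("8", "11"), ("8", "11")),
    ("CSF1PO", ("12", "13"), ("9", "11"), ("9", "11")),
    ("D3S1358", ("15", "17"), ("15", "15"), ("17", "17")),
    ("TH01", ("9", "9"), ("9", "9"), ("9", "9")),
    ("D13S317", ("10", "11"), ("10", "12"), ("10", "11")),
    ("D16S539", ("12", "12"), ("11", "12"), ("9", "12")),
    ("D2S1338", ("20", "20"), ("22", "25"), ("20", "25")),
    ("D19S433", ("13", "15"), ("13", "13"), ("13", "15")),
    ("VWA", ("14", "17"), ("17", "18"), ("14", "17")),
    ("TPOX", ("11", "11"), ("8", "11"), ("8", "11")),
    ("D18S51", ("13", "15"), ("15", "19"), ("13", "15")),
    ("D5S818", ("7", "12"), ("11", "12"), ("11", "12")),
    ("FGA", ("21", "21"), ("21", "22"), ("19", "22")),
    ("AMEL", ("X", "Y"), ("X", "X"), ("X", "X")),
]


@pytest.fixture(scope="session")
def trio_case_profiles():
    """S1, S2 (reference siblings) and S3 (tested) of the worked case."""
    profiles = []
    for idx, sid in enumerate(["S1", "S2", "S3"]):
        profiles.append(
            make_profile(
                sid, [(locus, *gs[idx]) for locus, *gs in TRIO_CASE_GENOTYPES]
            )
        )
    return tuple(profiles)


@pytest.fixture(scope="session")
def trio_case_freqs():
    """Synthetic frequency table covering the worked case's autosomal alleles."""
    tables = {}
    for locus, *genos in TRIO_CASE_GENOTYPES:
        if locus == "AMEL":
            continue
        alleles = sorted({a for g in genos for a in g})
        tables[locus] = AlleleFrequencyTable(
            locus, {a: 0.1 for a in alleles}
        )
    return tables


@pytest.fixture()
def simple_locus():
    """Three-allele locus with residual mass, used across likelihood tests."""
    return AlleleFrequencyTable("L1", {"A": 0.1, "B": 0.2, "C": 0.3})
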
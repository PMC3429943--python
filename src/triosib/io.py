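"""CSV input, report output.

Formats
-------
Frequency CSV: header ``locus,allele,frequency``, one row per allele, UTF-8.
Per-locus frequencies must be positive and sum to at most 1; any missing
mass is recorded as the locus's residual.

Profile CSV: header ``sample_id,locus,allele1,allele2``; homozygotes repeat
the allele.

Case reports mirror the classic trio case table: per locus the three
genotypes, the two duo sibling indices (S1-S3 and S2-S3) and the trio SI,
plus the three combined products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, TextIO, Tuple, Union

import pandas as pd

from .genotypes import (
    NON_AUTOSOMAL_LOCI,
    AlleleFrequencyTable,
    GenotypeObservation,
    Profile,
)
from .kinship import DEFAULT_FLOOR, combined_lr

__all__ = [
    "load_frequency_table",
    "write_frequency_table",
    "load_profiles",
    "write_profiles",
    "CaseReport",
    "case_report",
]

PathOrStream = Union[str, TextIO]


def load_frequency_table(source: PathOrStream) -> Dict[str, AlleleFrequencyTable]:
    """Read a multi-locus allele-frequency table from CSV.

    Raises on duplicate (locus, allele) rows, non-numeric or non-positive
    frequencies, and per-locus sums exceeding 1.
    """
    df = pd.read_csv(source, dtype={"locus": str, "allele": str})
    expected = {"locus", "allele", "frequency"}
    if set(df.columns) != expected:
        raise ValueError(
            f"frequency CSV must have columns {sorted(expected)}, got {list(df.columns)}"
        )
    if not pd.api.types.is_numeric_dtype(df["frequency"]):
        raise ValueError("frequency column must be numeric")
    dup = df.duplicated(subset=["locus", "allele"])
    if dup.any():
        rows = df[dup][["locus", "allele"]].values.tolist()
        raise ValueError(f"duplicate (locus, allele) rows: {rows}")
    tables: Dict[str, AlleleFrequencyTable] = {}
    for locus, grp in df.groupby("locus", sort=False):
        tables[str(locus)] = AlleleFrequencyTable(
            str(locus), dict(zip(grp["allele"], grp["frequency"].astype(float)))
        )
    return tables


def write_frequency_table(
    tables: Mapping[str, AlleleFrequencyTable], dest: PathOrStream
) -> None:
    rows = [
        {"locus": locus, "allele": allele, "frequency": freq}
        for locus, table in tables.items()
        for allele, freq in table.entries.items()
    ]
    pd.DataFrame(rows, columns=["locus", "allele", "frequency"]).to_csv(
        dest, index=False
    )


def load_profiles(source: PathOrStream) -> Dict[str, Profile]:
    """Read genotype profiles from CSV, keyed by sample id."""
    df = pd.read_csv(
        source, dtype={"sample_id": str, "locus": str, "allele1": str, "allele2": str}
    )
    expected = {"sample_id", "locus", "allele1", "allele2"}
    if set(df.columns) != expected:
        raise ValueError(
            f"profile CSV must have columns {sorted(expected)}, got {list(df.columns)}"
        )
    profiles: Dict[str, Profile] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        genos: Dict[str, GenotypeObservation] = {}
        for _, row in grp.iterrows():
            locus = str(row["locus"])
            if locus in genos:
                raise ValueError(f"sample {sid!r}: duplicate locus {locus!r}")
            genos[locus] = GenotypeObservation(
                locus, (str(row["allele1"]), str(row["allele2"]))
            )
        profiles[str(sid)] = Profile(str(sid), genos)
    return profiles


def write_profiles(profiles: Mapping[str, Profile], dest: PathOrStream) -> None:
    rows = [
        {
            "sample_id": prof.sample_id,
            "locus": locus,
            "allele1": g.alleles[0],
            "allele2": g.alleles[1],
        }
        for prof in profiles.values()
        for locus, g in prof.genotypes.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "locus", "allele1", "allele2"]).to_csv(
        dest, index=False
    )


@dataclass(frozen=True)
class CaseReport:
    """Duo and trio sibling indices for one tested case."""

    sample_ids: Tuple[str, str, str]
    rows: Tuple[dict, ...]  # per-locus: locus, genotypes, duo/trio SIs
    combined_duo_s1_s3: float
    combined_duo_s2_s3: float
    combined_trio: float
    floor_value: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_ids": list(self.sample_ids),
                "floor_value": self.floor_value,
                "per_locus": list(self.rows),
                "combined": {
                    "duo_s1_s3": self.combined_duo_s1_s3,
                    "duo_s2_s3": self.combined_duo_s2_s3,
                    "trio": self.combined_trio,
                },
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        s1, s2, s3 = self.sample_ids
        header = [
            "locus",
            s1,
            s2,
            s3,
            f"SI {s1}-{s3}",
            f"SI {s2}-{s3}",
            f"SI {s1},{s2}-{s3}",
        ]
        lines = ["\t".join(header)]
        for row in self.rows:
            cells = [row["locus"], row["s1"], row["s2"], row["s3"]]
            for key in ("duo_s1_s3", "duo_s2_s3", "trio"):
                v = row.get(key)
                cells.append("" if v is None else f"{v:.3f}")
            lines.append("\t".join(cells))
        lines.append(
            "\t".join(
                [
                    "Combined SI",
                    "",
                    "",
                    "",
                    f"{self.combined_duo_s1_s3:.3f}",
                    f"{self.combined_duo_s2_s3:.3f}",
                    f"{self.combined_trio:.3f}",
                ]
            )
        )
        return "\n".join(lines) + "\n"


def case_report(
    s1: Profile,
    s2: Profile,
    s3: Profile,
    freqs: Mapping[str, AlleleFrequencyTable],
    floor: float = DEFAULT_FLOOR,
) -> CaseReport:
    """Full duo + trio sibling-index report for a tested individual S3.

    Computes, per shared autosomal locus, the duo SI of S3 against each
    reference sibling and the trio SI against both, then the three combined
    products (excluded trio loci contribute ``floor``).  Sex-typing loci are
    reported without indices.
    """
    trio = combined_lr([s1, s2, s3], freqs, floor=floor)
    loci = [r.locus_name for r in trio.per_locus]
    duo13 = combined_lr([s1, s3], freqs, floor=floor, loci=loci)
    duo23 = combined_lr([s2, s3], freqs, floor=floor, loci=loci)
    by_locus = {
        r.locus_name: (r, d13, d23)
        for r, d13, d23 in zip(trio.per_locus, duo13.per_locus, duo23.per_locus)
    }

    rows: List[dict] = []
    shared = [l for l in s1.genotypes if l in s2.genotypes and l in s3.genotypes]
    for locus in shared:
        row = {
            "locus": locus,
            "s1": str(s1.genotype(locus)),
            "s2": str(s2.genotype(locus)),
            "s3": str(s3.genotype(locus)),
        }
        if locus in by_locus:
            r, d13, d23 = by_locus[locus]
            row.update(
                duo_s1_s3=d13.lr,
                duo_s2_s3=d23.lr,
                trio=r.lr,
                trio_excluded=r.excluded,
            )
        else:  # non-autosomal (AMEL) or not covered by the table
            row.update(duo_s1_s3=None, duo_s2_s3=None, trio=None, trio_excluded=None)
        rows.append(row)

    return CaseReport(
        sample_ids=(s1.sample_id, s2.sample_id, s3.sample_id),
        rows=tuple(rows),
        combined_duo_s1_s3=duo13.combined,
        combined_duo_s2_s3=duo23.combined,
        combined_trio=trio.combined,
        floor_value=floor,
    )
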
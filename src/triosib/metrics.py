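"""Classification operating characteristics for sibship LR tests.

A trio (or duo) is called "sibling" when its combined LR clears a
threshold; comparing the calls over a true-sibling population and an
unrelated population gives the confusion matrix and the usual derived
rates.  Following forensic convention the rates are expressed as
percentages:

* sensitivity = 100 * TP / (TP + FN)
* specificity = 100 * TN / (FP + TN)
* PPV = 100 * TP / (TP + FP), NPV = 100 * TN / (TN + FN)
* accuracy = 100 * (TP + TN) / (TP + TN + FP + FN)

Display rounding is half-up to two decimals, computed exactly from the
integer counts so values like 99.245 round to 99.25; the unrounded rates
are kept alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping, Sequence

import numpy as np

from .simulate import TrioPopulation

__all__ = [
    "ConfusionSummary",
    "DistributionSummary",
    "confusion_at_threshold",
    "lr_distribution_summary",
    "inconsistency_locus_counts",
    "per_locus_exclusion_power",
]


def _pct(numer: int, denom: int) -> float:
    return 100.0 * numer / denom if denom else float("nan")


def _pct_rounded(numer: int, denom: int) -> float:
    """Exact half-up 2-decimal percentage from integer counts."""
    if denom == 0:
        return float("nan")
    value = Decimal(100 * numer) / Decimal(denom)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts at an LR threshold plus derived rates (percent)."""

    threshold: float
    strict: bool
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _pct(self.tn, self.fp + self.tn)

    @property
    def ppv(self) -> float:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _pct(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return _pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    def rounded(self) -> Dict[str, float]:
        """Half-up 2-decimal display percentages, computed exactly from counts."""
        return {
            "sensitivity": _pct_rounded(self.tp, self.tp + self.fn),
            "specificity": _pct_rounded(self.tn, self.fp + self.tn),
            "ppv": _pct_rounded(self.tp, self.tp + self.fp),
            "npv": _pct_rounded(self.tn, self.tn + self.fn),
            "accuracy": _pct_rounded(
                self.tp + self.tn, self.tp + self.tn + self.fp + self.fn
            ),
        }

    def as_dict(self) -> Dict[str, float]:
        d = {
            "threshold": self.threshold,
            "strict": self.strict,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }
        return d


def confusion_at_threshold(
    sib_lrs: Sequence[float],
    unrel_lrs: Sequence[float],
    threshold: float,
    strict: bool = False,
) -> ConfusionSummary:
    """Classify two LR populations at a threshold.

    ``strict=True`` calls "sibling" when LR > threshold ("greater than");
    ``strict=False`` when LR >= threshold ("at least").
    """
    if len(sib_lrs) == 0 or len(unrel_lrs) == 0:
        raise ValueError("both LR populations must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sib = np.asarray(sib_lrs, dtype=float)
    unrel = np.asarray(unrel_lrs, dtype=float)
    call_sib = sib > threshold if strict else sib >= threshold
    call_unrel = unrel > threshold if strict else unrel >= threshold
    tp = int(call_sib.sum())
    fp = int(call_unrel.sum())
    return ConfusionSummary(
        threshold=threshold,
        strict=strict,
        tp=tp,
        fn=len(sib) - tp,
        fp=fp,
        tn=len(unrel) - fp,
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Summary of a log10 LR distribution (sample SD, n-1 denominator)."""

    mean: float
    sd: float
    min: float
    max: float
    n: int


def lr_distribution_summary(lrs: Sequence[float]) -> DistributionSummary:
    """Summarise LRs on the log10 scale.  All LRs must be positive (post-floor)."""
    arr = np.asarray(lrs, dtype=float)
    if arr.size == 0:
        raise ValueError("empty LR list")
    if np.any(arr <= 0):
        raise ValueError("LRs must be positive; apply the exclusion floor first")
    logs = np.log10(arr)
    sd = float(np.std(logs, ddof=1)) if logs.size > 1 else 0.0
    return DistributionSummary(
        mean=float(np.mean(logs)),
        sd=sd,
        min=float(np.min(logs)),
        max=float(np.max(logs)),
        n=int(logs.size),
    )


def inconsistency_locus_counts(population: TrioPopulation) -> Dict[int, int]:
    """Histogram: number of excluding loci -> number of trios.

    Bin 0 is the count of trios with no genetic inconsistency at any locus
    (for a true-sibling population that is all of them, absent mutation).
    Bins with zero trios are included up to the maximum observed count.
    """
    per_trio = population.excluded.sum(axis=1).astype(int)
    counts = Counter(per_trio.tolist())
    return {k: counts.get(k, 0) for k in range(int(per_trio.max()) + 1)}


def per_locus_exclusion_power(population: TrioPopulation) -> Dict[str, float]:
    """Empirical fraction of unrelated trios excluded at each locus.

    Only meaningful for a 2S1U population (an exclusion requires a trio with
    a non-sibling member); returns loci sorted most-informative first.
    """
    if population.mode != "2S1U":
        raise ValueError(
            f"exclusion power requires a 2S1U population, got mode {population.mode!r}"
        )
    if population.n == 0:
        raise ValueError("empty population")
    fractions = population.excluded.mean(axis=0)
    ranked = sorted(
        zip(population.loci, fractions), key=lambda kv: kv[1], reverse=True
    )
    return {locus: float(frac) for locus, frac in ranked}
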
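"""Canonical trio genotype-pattern classes and their closed-form LR formulas.

At a single STR locus, a trio (two reference siblings S1, S2 and one tested
individual S3) falls into one of a finite number of genotype classes once
concrete alleles are replaced by placeholder letters: A-D for alleles
observed in the reference pair (in order of first appearance scanning S1
then S2) and X, Y for alleles of S3 absent from both references.

Seven reference-pair classes exist (AA/AA, AA/AB, AA/BB, AA/BC, AB/AB,
AB/AC, AB/CD).  Crossing them with every possible S3 genotype yields 63
distinct classes, of which 37 are non-excluded (some ordered parental
genotype pair can produce all three individuals) and carry a closed-form
likelihood-ratio formula in the allele frequencies a, b, c, d; the other 26
are exclusions (genetic inconsistencies) with sibling-hypothesis
likelihood identically zero.

Exclusion status is decided combinatorially -- existence of a compatible
parental pair -- never by thresholding a floating-point likelihood, so it
is exact and frequency-independent.

Classes that differ only in which placeholder the unobserved allele gets
(e.g. ``AB AB CC`` vs ``AB AB XX``) are the same class; the X/Y spelling is
canonical for display and the observed-letter spelling is kept as an alias
so either name resolves.

The closed forms attached here are the exact rational functions implied by
the parental-enumeration definition (rederivable at run time with
:func:`derive_closed_form`).  For ten classes the historically published
formulas differ from the exact LR -- they carry a lumped "any other allele
at frequency 1-a, transmission 1/4" shorthand that is only exact when the
extra allele is truly unobserved; those printed forms are retained per
pattern as ``published_display`` and flagged via ``matches_published``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import sympy

from .genotypes import GenotypeObservation

__all__ = [
    "REFERENCE_PAIR_CLASSES",
    "LRFormula",
    "TrioPattern",
    "canonicalize_trio",
    "enumerate_trio_patterns",
    "closed_form_lr",
    "observed_spelling",
]

#: The seven canonical reference-sibling-pair classes.
REFERENCE_PAIR_CLASSES: Tuple[Tuple[str, str], ...] = (
    ("AA", "AA"),
    ("AA", "AB"),
    ("AA", "BB"),
    ("AA", "BC"),
    ("AB", "AB"),
    ("AB", "AC"),
    ("AB", "CD"),
)

# Exact closed-form LR for every non-excluded class, keyed by the
# observed-letter spelling (unobserved S3 alleles written with the next
# unused letters).  Each entry was derived once by symbolic summation over
# parental genotype pairs (see :func:`derive_closed_form`, which reproduces
# them at run time) and is verified against the numeric brute-force engine
# by the test suite.
_EXACT_FORMS: Dict[str, str] = {
    "AA AA AA": "(1 + 6a + 9a^2)/(4a^2 + 8a^3 + 4a^4)",
    "AA AA AB": "(1 + 3a)/(4a + 8a^2 + 4a^3)",
    "AA AA BB": "1/(4 + 8a + 4a^2)",
    "AA AA BC": "1/(4 + 8a + 4a^2)",
    "AA AB AA": "(1 + 3a)/(4a^2 + 4a^3)",
    "AA AB BB": "1/(4b + 4ab)",
    "AA AB AB": "(1 + 3a + b)/(8ab + 8a^2b)",
    "AA AB AC": "1/(8a + 8a^2)",
    "AA AB BC": "1/(8b + 8ab)",
    "AA BB AA": "1/(4a^2)",
    "AA BB BB": "1/(4b^2)",
    "AA BB AB": "1/(4ab)",
    "AA BC AA": "1/(4a^2)",
    "AA BC AB": "1/(8ab)",
    "AA BC AC": "1/(8ac)",
    "AA BC BC": "1/(8bc)",
    "AB AB AA": "(1 + 3a + b)/(4a + 4ab + 4a^2 + 8a^2b)",
    "AB AB AB": "(1 + 3a + 3b + 12ab)/(8ab + 8a^2b + 8ab^2 + 16a^2b^2)",
    "AB AB BB": "(1 + a + 3b)/(4b + 4ab + 4b^2 + 8ab^2)",
    "AB AB AC": "(1 + 4a)/(8a + 8a^2 + 8ab + 16a^2b)",
    "AB AB BC": "(1 + 4b)/(8b + 8ab + 8b^2 + 16ab^2)",
    "AB AB CC": "1/(4 + 4a + 4b + 8ab)",
    "AB AB CD": "1/(4 + 4a + 4b + 8ab)",
    "AB AC AA": "1/(4a + 8a^2)",
    "AB AC AB": "(1 + 4a)/(8ab + 16a^2b)",
    "AB AC AC": "(1 + 4a)/(8ac + 16a^2c)",
    "AB AC BB": "1/(4b + 8ab)",
    "AB AC BC": "(a + b + c)/(8bc + 16abc)",
    "AB AC CC": "1/(4c + 8ac)",
    "AB AC CD": "1/(8c + 16ac)",
    "AB AC BD": "1/(8b + 16ab)",
    "AB CD AB": "1/(8ab)",
    "AB CD AC": "1/(16ac)",
    "AB CD AD": "1/(16ad)",
    "AB CD BC": "1/(16bc)",
    "AB CD BD": "1/(16bd)",
    "AB CD CD": "1/(8cd)",
}

# Formulas as printed in the source publication's table.  Ten of them embed
# a systematic "lumped other-allele" shorthand (any extra allele treated as
# frequency 1-a with uniform 1/4 transmission) that is exact only when the
# extra allele is genuinely unobserved; for the classes in
# PUBLISHED_DEVIATIONS the printed form therefore differs from the exact LR.
_PUBLISHED_FORMS: Dict[str, str] = {
    "AA AB AB": "(1 + 3a)/(8ab + 8a^2b)",
    "AB AB AA": "(1 + 3a)/(4a + 4ab + 4a^2 + 4a^2b)",
    "AB AB AB": "(1 + 3a + 3b + 9ab)/(8ab + 8a^2b + 8ab^2 + 8a^2b^2)",
    "AB AB BB": "(1 + 3b)/(4b + 4ab + 4b^2 + 4ab^2)",
    "AB AB AC": "(1 + 4a)/(8a + 8a^2 + 8ab + 8a^2b)",
    "AB AB BC": "(1 + 4b)/(8b + 8ab + 8b^2 + 8ab^2)",
    "AB AB CC": "1/(4 + 4b + 4a + 4ab)",
    "AB AC BC": "(a + b)/(8bc + 16abc)",
    "AB AC CD": "1/(8c + 8ac)",
    "AB AC BD": "1/(8b + 8ab)",
}

#: Canonical class strings whose published formula is not the exact LR.
PUBLISHED_DEVIATIONS = frozenset(
    {
        "AA AB AB",
        "AB AB AA",
        "AB AB AB",
        "AB AB BB",
        "AB AB AX",
        "AB AB BX",
        "AB AB XX",
        "AB AC BC",
        "AB AC BX",
        "AB AC CX",
    }
)

_ABCD = sympy.symbols("a b c d")


def _parse_closed_form(display: str) -> Tuple[sympy.Expr, sympy.Expr]:
    """Parse a compact rational display like ``(1 + 3a)/(8ab + 8a^2b)``."""
    src = display.replace("^", "**")
    # implicit products: digit or variable followed by a variable or "("
    src = re.sub(r"(?<=[0-9abcd])(?=[abcd(])", "*", src)
    expr = sympy.sympify(src, dict(zip("abcd", _ABCD)))
    num, den = sympy.fraction(sympy.together(expr))
    return sympy.expand(num), sympy.expand(den)


@dataclass(frozen=True)
class LRFormula:
    """Closed-form LR as a ratio of polynomials in allele frequencies a-d."""

    display: str
    numerator: sympy.Expr
    denominator: sympy.Expr

    @property
    def variables(self) -> Tuple[str, ...]:
        syms = (self.numerator / self.denominator).free_symbols
        return tuple(sorted(str(s) for s in syms))

    def evaluate(self, a: float = 0.0, b: float = 0.0, c: float = 0.0, d: float = 0.0) -> float:
        return _lambdified(self.display)(a, b, c, d)


@lru_cache(maxsize=None)
def _lambdified(display: str):
    num, den = _parse_closed_form(display)
    return sympy.lambdify(_ABCD, num / den, modules="math")


@dataclass(frozen=True)
class TrioPattern:
    """One canonical (S1, S2, S3) single-locus genotype class.

    ``formula`` is the exact closed-form LR; ``published_display`` is the
    form as printed in the source table, which for the ten classes in
    :data:`PUBLISHED_DEVIATIONS` is not the exact LR.
    """

    s1_pattern: str
    s2_pattern: str
    s3_pattern: str
    excluded: bool
    formula: Optional[LRFormula]
    published_display: Optional[str] = None

    @property
    def matches_published(self) -> Optional[bool]:
        """True if the printed formula equals the exact LR; None when excluded."""
        if self.excluded:
            return None
        return self.class_string not in PUBLISHED_DEVIATIONS

    @property
    def class_string(self) -> str:
        return f"{self.s1_pattern} {self.s2_pattern} {self.s3_pattern}"

    @property
    def table_spelling(self) -> str:
        """Alias with unobserved alleles written using the next observed letters."""
        return observed_spelling(self.class_string)

    def __str__(self) -> str:
        return self.class_string


def observed_spelling(class_string: str) -> str:
    """Rewrite X/Y placeholders with the next unused letters A-F.

    ``"AA AB AX" -> "AA AB AC"``; strings without X/Y pass through.
    """
    s1, s2, s3 = class_string.split()
    used = set(s1 + s2)
    fresh = (ch for ch in "ABCDEF" if ch not in used)
    repl: Dict[str, str] = {}
    out = []
    for ch in s3:
        if ch in "XY":
            if ch not in repl:
                repl[ch] = next(fresh)
            out.append(repl[ch])
        else:
            out.append(ch)
    return f"{s1} {s2} {''.join(sorted(out))}"


def _compatible(child: str, father: Tuple[str, str], mother: Tuple[str, str]) -> bool:
    u, v = child
    return (u in father and v in mother) or (v in father and u in mother)


def _parents_exist(children: List[str]) -> bool:
    """Does any ordered parental genotype pair produce all the children?

    Restricting parental alleles to those carried by some child loses no
    generality: untransmitted parental alleles are unconstrained.
    """
    alleles = sorted({ch for c in children for ch in c})
    genos = list(itertools.combinations_with_replacement(alleles, 2))
    for father, mother in itertools.product(genos, repeat=2):
        if all(_compatible(c, father, mother) for c in children):
            return True
    return False


class ExcludedPatternError(ValueError):
    """Requested a closed-form LR for an excluded (likelihood-zero) class."""


@lru_cache(maxsize=1)
def _registry() -> Dict[str, TrioPattern]:
    patterns: Dict[str, TrioPattern] = {}
    for s1, s2 in REFERENCE_PAIR_CLASSES:
        observed = sorted(set(s1 + s2))
        s3_options = ["".join(p) for p in itertools.combinations_with_replacement(observed, 2)]
        s3_options += [o + "X" for o in observed] + ["XX", "XY"]
        for s3 in s3_options:
            excluded = not _parents_exist([s1, s2, s3])
            formula = None
            published = None
            if not excluded:
                spelling = observed_spelling(f"{s1} {s2} {s3}")
                display = _EXACT_FORMS[spelling]
                num, den = _parse_closed_form(display)
                formula = LRFormula(display, num, den)
                published = _PUBLISHED_FORMS.get(spelling, display)
            patterns[f"{s1} {s2} {s3}"] = TrioPattern(
                s1, s2, s3, excluded, formula, published
            )
    return patterns


def enumerate_trio_patterns() -> List[TrioPattern]:
    """All distinct canonical trio classes (63: 37 non-excluded + 26 excluded)."""
    return list(_registry().values())


def closed_form_lr(pattern) -> LRFormula:
    """Closed-form LR for a non-excluded class.

    Accepts a :class:`TrioPattern` or a class string in either the canonical
    X/Y spelling or the observed-letter alias.
    """
    if isinstance(pattern, TrioPattern):
        key = pattern.class_string
    else:
        key = str(pattern)
    registry = _registry()
    if key not in registry:
        # try resolving an observed-letter alias
        matches = [p for p in registry.values() if p.table_spelling == key]
        if not matches:
            raise KeyError(f"unknown trio pattern class {key!r}")
        pat = matches[0]
    else:
        pat = registry[key]
    if pat.excluded:
        raise ExcludedPatternError(
            f"class {pat.class_string!r} is an exclusion: no LR formula exists"
        )
    assert pat.formula is not None
    return pat.formula


def _allele_orders(g: GenotypeObservation) -> List[Tuple[str, str]]:
    a, b = g.alleles
    if a == b:
        return [(a, b)]
    return [(a, b), (b, a)]


def canonicalize_trio(
    s1: GenotypeObservation,
    s2: GenotypeObservation,
    s3: GenotypeObservation,
) -> Tuple[TrioPattern, Dict[str, str]]:
    """Map concrete genotypes onto their canonical class.

    The reference pair is oriented so the genotype with fewer distinct
    alleles comes first (ties broken toward the lexicographically smaller
    canonical string); letters A-D are assigned in order of first appearance
    scanning S1 then S2, and S3 alleles unseen in the references become X
    then Y.  Among the remaining labelling freedoms the lexicographically
    smallest class string wins, which makes the form deterministic and
    invariant under allele relabelling.

    Returns the :class:`TrioPattern` and the bindings letter -> concrete
    allele, with which the pattern's closed-form LR can be evaluated.
    """
    if not (s1.locus_name == s2.locus_name == s3.locus_name):
        raise ValueError("trio genotypes must share a locus")
    d1, d2 = len(set(s1.alleles)), len(set(s2.alleles))
    if d1 < d2:
        orientations = [(s1, s2)]
    elif d2 < d1:
        orientations = [(s2, s1)]
    else:
        orientations = [(s1, s2), (s2, s1)]

    best: Optional[Tuple[str, Dict[str, str]]] = None
    for p1, p2 in orientations:
        for o1 in _allele_orders(p1):
            for o2 in _allele_orders(p2):
                base: Dict[str, str] = {}
                letters = iter("ABCD")
                for allele in (*o1, *o2):
                    if allele not in base:
                        base[allele] = next(letters)
                for o3 in _allele_orders(s3):
                    mapping = dict(base)
                    unobserved = iter("XY")
                    for allele in o3:
                        if allele not in mapping:
                            mapping[allele] = next(unobserved)
                    parts = [
                        "".join(sorted(mapping[a] for a in g.alleles))
                        for g in (p1, p2, s3)
                    ]
                    candidate = " ".join(parts)
                    if best is None or candidate < best[0]:
                        best = (candidate, mapping)
    assert best is not None
    class_string, mapping = best
    bindings = {letter: allele for allele, letter in mapping.items()}
    return _registry()[class_string], bindings


def derive_closed_form(class_string: str) -> sympy.Expr:
    """Derive the exact LR for a class by symbolic parental enumeration.

    Sums HWE parental priors times Mendelian transmission products over
    every ordered pair of parental genotypes drawn from the class's alleles
    (a, b, c, d for observed, x, y for unobserved) plus one residual allele
    carrying the remaining frequency mass, then cancels R/U.  The x, y and
    residual symbols always cancel, so the result is a rational function of
    a-d only.  Slow (sympy); intended as an oracle, not for scoring.
    """
    key = class_string
    if key not in _registry():
        matches = [
            p for p in _registry().values() if p.table_spelling == key
        ]
        if not matches:
            raise KeyError(f"unknown trio pattern class {key!r}")
        key = matches[0].class_string
    pat = _registry()[key]
    if pat.excluded:
        raise ExcludedPatternError(f"class {key!r} is an exclusion")

    children = [tuple(g) for g in key.split()]
    letters = sorted({ch for g in children for ch in g})
    sym = dict(zip("ABCDXY", (*_ABCD, *sympy.symbols("x y"))))
    freq = {L: sym[L] for L in letters}
    freq["_R"] = 1 - sum(freq.values())
    alleles = [*letters, "_R"]
    genos = list(itertools.combinations_with_replacement(alleles, 2))
    half = sympy.Rational(1, 2)

    def prior(g):
        return freq[g[0]] ** 2 if g[0] == g[1] else 2 * freq[g[0]] * freq[g[1]]

    def trans(g, al):
        return half * ((g[0] == al) + (g[1] == al))

    def pchild(ch, f, m):
        u, v = ch
        if u == v:
            return trans(f, u) * trans(m, u)
        return trans(f, u) * trans(m, v) + trans(f, v) * trans(m, u)

    def sib_likelihood(childset):
        total = sympy.Integer(0)
        for f, m in itertools.product(genos, repeat=2):
            term = prior(f) * prior(m)
            for ch in childset:
                term *= pchild(ch, f, m)
                if term == 0:
                    break
            total += term
        return sympy.expand(total)

    numerator = sib_likelihood(children)
    g3 = children[2]
    hwe3 = freq[g3[0]] ** 2 if g3[0] == g3[1] else 2 * freq[g3[0]] * freq[g3[1]]
    denominator = sympy.expand(sib_likelihood(children[:2]) * hwe3)
    return sympy.cancel(numerator / denominator)


def pattern_table() -> List[Tuple[str, str, str]]:
    """(class, status, formula display) rows for all 63 classes, for reporting."""
    rows = []
    for p in enumerate_trio_patterns():
        rows.append(
            (
                p.class_string,
                "excluded" if p.excluded else "non-excluded",
                p.formula.display if p.formula else "",
            )
        )
    return rows
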
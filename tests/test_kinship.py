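"""Likelihood engine: sib-set likelihoods, trio LR, duo SI, combination."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triosib import (
    AlleleFrequencyTable,
    GenotypeObservation,
    combined_lr,
    duo_si_locus,
    genotype_prob_hwe,
    make_profile,
    sib_set_likelihood,
    trio_lr_locus,
)
from triosib.kinship import combine_locus_results


def g(a, b, locus="L1"):
    return GenotypeObservation(locus, (a, b))


class TestSibSetLikelihood:
    def test_single_genotype_is_hwe_marginal(self, simple_locus):
        assert sib_set_likelihood([g("A", "A")], simple_locus) == pytest.approx(0.01)

    def test_two_sibs_closed_form(self, simple_locus):
        # parent-pair enumeration gives a^2 b (1+a) / 2 for sibs AA, AB
        a, b = 0.1, 0.2
        expected = a * a * b * (1 + a) / 2
        assert sib_set_likelihood(
            [g("A", "A"), g("A", "B")], simple_locus
        ) == pytest.approx(expected)
        assert expected == pytest.approx(0.0011)

    def test_three_sibs_closed_form(self, simple_locus):
        # AA, AB, AC forces parents AB x AC: a^2 b c / 8
        assert sib_set_likelihood(
            [g("A", "A"), g("A", "B"), g("A", "C")], simple_locus
        ) == pytest.approx(7.5e-5)

    def test_empty_rejected(self, simple_locus):
        with pytest.raises(ValueError):
            sib_set_likelihood([], simple_locus)

    def test_normalization_over_third_sibling(self):
        """Summing the trio likelihood over every possible S3 genotype in a
        full allele universe recovers the pair likelihood."""
        t = AlleleFrequencyTable("L1", {"A": 0.3, "B": 0.25, "C": 0.45})
        s1, s2 = g("A", "B"), g("A", "C")
        pair = sib_set_likelihood([s1, s2], t)
        total = sum(
            sib_set_likelihood([s1, s2, g(u, v)], t)
            for u, v in itertools.combinations_with_replacement("ABC", 2)
        )
        assert total == pytest.approx(pair, rel=1e-9)


class TestTrioLR:
    def test_table1_worked_trio(self, simple_locus):
        """AA / AB / AC: LR = 1/(8a + 8a^2)."""
        res = trio_lr_locus(g("A", "A"), g("A", "B"), g("A", "C"), simple_locus)
        assert res.lr == pytest.approx(1 / (8 * 0.1 + 8 * 0.01))
        assert not res.excluded

    def test_opposite_homozygotes_with_het_child(self):
        t = AlleleFrequencyTable("L1", {"A": 0.1, "B": 0.2})
        res = trio_lr_locus(g("A", "A"), g("B", "B"), g("A", "B"), t)
        assert res.lr == pytest.approx(1 / (4 * 0.1 * 0.2))

    def test_exclusion_has_zero_lr(self, simple_locus):
        res = trio_lr_locus(g("A", "A"), g("B", "B"), g("A", "C"), simple_locus)
        assert res.excluded
        assert res.lr == 0.0
        assert res.numerator_R == 0.0
        assert res.denominator_U > 0.0

    @settings(derandomize=True, max_examples=60)
    @given(
        alleles=st.tuples(*[st.sampled_from("ABC") for _ in range(6)]),
        freqs=st.tuples(*[st.floats(0.05, 0.4) for _ in range(3)]),
    )
    def test_reference_pair_exchangeable(self, alleles, freqs):
        total = sum(freqs) + 0.1
        t = AlleleFrequencyTable(
            "L1", {k: v / total for k, v in zip("ABC", freqs)}
        )
        s1, s2, s3 = (g(alleles[i], alleles[i + 1]) for i in (0, 2, 4))
        r12 = trio_lr_locus(s1, s2, s3, t)
        r21 = trio_lr_locus(s2, s1, s3, t)
        assert r12.lr == r21.lr
        assert r12.excluded == r21.excluded


class TestDuoSI:
    def test_no_shared_alleles_is_one_quarter(self):
        """Zero-IBS pairs have SI = kappa_0 = 1/4 regardless of frequencies."""
        t = AlleleFrequencyTable("FGA", {"19": 0.05, "21": 0.2, "22": 0.15})
        res = duo_si_locus(
            g("21", "21", "FGA"), g("19", "22", "FGA"), t
        )
        assert res.lr == pytest.approx(0.25)
        assert not res.excluded

    def test_matching_homozygotes(self):
        t = AlleleFrequencyTable("L1", {"A": 0.5})
        res = duo_si_locus(g("A", "A"), g("A", "A"), t)
        assert res.lr == pytest.approx((1 + 0.5) ** 2 / (4 * 0.25))  # 2.25

    def test_matching_heterozygotes(self):
        # brute-force enumeration gives (1 + a + b + 2ab)/(8ab) = 1.25 at a=b=1/2
        t = AlleleFrequencyTable("L1", {"A": 0.5, "B": 0.5})
        res = duo_si_locus(g("A", "B"), g("A", "B"), t)
        assert res.lr == pytest.approx(1.25)

    def test_kappa_form_identity(self):
        """The engine's duo SI equals the IBD mixture
        1/4 + 1/2 * P(g2|1 IBD)/P(g2) + 1/4 * [g1=g2]/P(g2)
        on 1,000 random genotype/frequency draws."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            k = rng.integers(2, 6)
            raw = rng.dirichlet(np.ones(k)) * rng.uniform(0.7, 1.0)
            labels = [f"a{i}" for i in range(k)]
            t = AlleleFrequencyTable("L1", dict(zip(labels, raw.tolist())))
            g1 = g(*rng.choice(labels, 2).tolist())
            g2 = g(*rng.choice(labels, 2).tolist())
            p2 = genotype_prob_hwe(g2, t)

            def p_given_shared(shared, gt=g2, table=t):
                u, v = gt.alleles
                if u == v:
                    return table.freq(u) if shared == u else 0.0
                return (table.freq(v) if shared == u else 0.0) + (
                    table.freq(u) if shared == v else 0.0
                )

            p_ibd1 = 0.5 * (
                p_given_shared(g1.alleles[0]) + p_given_shared(g1.alleles[1])
            )
            kappa = 0.25 + 0.5 * p_ibd1 / p2 + 0.25 * (g1 == g2) / p2
            assert duo_si_locus(g1, g2, t).lr == pytest.approx(
                kappa, abs=1e-10, rel=1e-10
            )


class TestCombinedLR:
    def _profiles(self, genos):
        out = []
        for sid, gs in genos.items():
            out.append(make_profile(sid, gs))
        return out

    def test_single_locus_passthrough(self, simple_locus):
        profs = self._profiles(
            {
                "S1": [("L1", "A", "A")],
                "S2": [("L1", "A", "B")],
                "S3": [("L1", "A", "C")],
            }
        )
        res = combined_lr(profs, {"L1": simple_locus})
        assert res.combined == pytest.approx(1 / (8 * 0.1 + 8 * 0.01))

    def test_floor_applied_per_excluded_locus(self):
        t1 = AlleleFrequencyTable("L1", {"A": 0.1, "B": 0.2})
        t2 = AlleleFrequencyTable("L2", {"A": 0.1, "B": 0.2, "C": 0.2})
        profs = self._profiles(
            {
                "S1": [("L1", "A", "A"), ("L2", "A", "A")],
                "S2": [("L1", "B", "B"), ("L2", "B", "B")],
                "S3": [("L1", "A", "B"), ("L2", "A", "C")],  # L2 excludes
            }
        )
        res = combined_lr(profs, {"L1": t1, "L2": t2})
        lr1 = 1 / (4 * 0.1 * 0.2)
        assert res.n_excluded == 1
        assert res.combined == pytest.approx(lr1 * 0.001)
        # profile-scope switch floors the whole product once
        res_p = combined_lr(profs, {"L1": t1, "L2": t2}, floor_scope="profile")
        assert res_p.combined == pytest.approx(0.001)

    def test_floor_monotonicity(self):
        """Combined LR is non-increasing as the floor decreases."""
        t = AlleleFrequencyTable("L1", {"A": 0.1, "B": 0.2, "C": 0.2})
        profs = self._profiles(
            {
                "S1": [("L1", "A", "A")],
                "S2": [("L1", "B", "B")],
                "S3": [("L1", "A", "C")],
            }
        )
        floors = [0.1, 0.01, 0.001, 1e-6]
        values = [combined_lr(profs, {"L1": t}, floor=f).combined for f in floors]
        assert all(x >= y for x, y in zip(values, values[1:]))

    def test_amel_skipped_and_no_shared_loci_error(self, simple_locus):
        profs = self._profiles(
            {
                "S1": [("L1", "A", "A"), ("AMEL", "X", "Y")],
                "S2": [("L1", "A", "B"), ("AMEL", "X", "X")],
                "S3": [("L1", "A", "C"), ("AMEL", "X", "X")],
            }
        )
        res = combined_lr(profs, {"L1": simple_locus})
        assert [r.locus_name for r in res.per_locus] == ["L1"]
        amel_only = [
            make_profile(sid, [("AMEL", "X", "X")]) for sid in ("S1", "S2", "S3")
        ]
        with pytest.raises(ValueError, match="no autosomal loci"):
            combined_lr(amel_only, {"L1": simple_locus})

    def test_duo_combination(self, simple_locus):
        profs = self._profiles(
            {"S1": [("L1", "A", "A")], "S3": [("L1", "B", "C")]}
        )
        res = combined_lr(profs, {"L1": simple_locus})
        assert res.combined == pytest.approx(0.25)

    def test_log10_matches_combined(self, simple_locus):
        res = combine_locus_results(
            [trio_lr_locus(g("A", "A"), g("A", "B"), g("A", "C"), simple_locus)]
        )
        assert 10 ** res.log10_combined == pytest.approx(res.combined)
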
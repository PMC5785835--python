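import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iisnp.locus_stats import (
    UndefinedStatisticError,
    aaf_concordance,
    allele_frequencies,
    bh_adjust,
    call_rate,
    compute_locus_stats,
    heterozygosities,
    hwe_exact_test,
)

from _oracles import bh_oracle, hwe_exact_oracle
from conftest import gm_from_strings


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "column, aaf, maf",
        [
            (["0/0", "0/0", "0/1", "1/1"], 0.375, 0.375),
            (["0/1", "0/1", "0/1"], 0.5, 0.5),
            (["0/0", "./.", "1/1"], 0.5, 0.5),  # missing excluded both sides
            (["1/1", "1/1", "0/1"], 5 / 6, 1 / 6),
        ],
    )
    def test_counting(self, column, aaf, maf):
        gm = gm_from_strings([column])
        got = allele_frequencies(gm, gm.loci[0].key)
        assert got == pytest.approx((aaf, maf))

    def test_all_missing_is_an_error(self):
        gm = gm_from_strings([["./.", "./."]])
        with pytest.raises(UndefinedStatisticError):
            allele_frequencies(gm, gm.loci[0].key)


class TestCallRate:
    @pytest.mark.parametrize(
        "column, rate",
        [
            (["0/0"] * 9 + ["./."], 0.9),
            (["0/1"] * 4, 1.0),
            (["./."] * 3, 0.0),
        ],
    )
    def test_fraction_called(self, column, rate):
        gm = gm_from_strings([column])
        assert call_rate(gm, gm.loci[0].key) == pytest.approx(rate)


class TestHeterozygosities:
    @pytest.mark.parametrize(
        "column, ho, he, f",
        [
            (["0/1", "0/1", "0/0", "1/1"], 0.5, 0.5, 0.0),
            (["0/1", "0/1"], 1.0, 0.5, -1.0),
            (["0/0", "1/1"], 0.0, 0.5, 1.0),
        ],
    )
    def test_examples(self, column, ho, he, f):
        gm = gm_from_strings([column])
        assert heterozygosities(gm, gm.loci[0].key) == pytest.approx((ho, he, f))

    def test_monomorphic_f_flagged_not_crashed(self):
        gm = gm_from_strings([["0/0", "0/0"]])
        ho, he, f = heterozygosities(gm, gm.loci[0].key)
        assert ho == 0 and he == 0 and np.isnan(f)

    @given(
        st.lists(st.sampled_from(["0/0", "0/1", "1/1"]), min_size=2, max_size=40)
    )
    @settings(deadline=None, max_examples=60)
    def test_f_sign_matches_he_minus_ho(self, column):
        gm = gm_from_strings([column])
        ho, he, f = heterozygosities(gm, gm.loci[0].key)
        if he > 0:
            assert np.sign(f) == np.sign(he - ho)


class TestHweExactTest:
    def test_two_configuration_case(self):
        # allele counts 2/2: het in {0, 2} with probabilities 1/3 and 2/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_p_is_one(self):
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_balanced_case_matches_oracle_tightly(self):
        got = hwe_exact_test(25, 50, 25)
        assert got == pytest.approx(float(hwe_exact_oracle(25, 50, 25)), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_agrees_with_enumeration_oracle_small_totals(self):
        # exhaustive sweep over every genotype-count triple with total <= 12
        for n in range(1, 13):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact_test(n_aa, n_ab, n_bb)
                    want = float(hwe_exact_oracle(n_aa, n_ab, n_bb))
                    assert got == pytest.approx(want, abs=1e-10), (n_aa, n_ab, n_bb)

    def test_null_type_one_error_conservative(self, rng):
        # HWE-true loci: the exact test rejects at most at the nominal rate
        n, n_loci = 300, 600
        pvals = []
        for _ in range(n_loci):
            p = rng.uniform(0.2, 0.8)
            g = rng.choice(3, size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
            pvals.append(hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())))
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05):
            se = np.sqrt(alpha * (1 - alpha) / n_loci)
            assert (pvals < alpha).mean() <= alpha + 3 * se


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.01], [0.01]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.03, 0.03, 0.03], [0.03, 0.03, 0.03]),
        ],
    )
    def test_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_empty_list(self):
        assert len(bh_adjust([])) == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_matches_definition_and_dominates_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert adj == pytest.approx(bh_oracle(pvals))
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestAafConcordance:
    def test_identical_vectors(self):
        r, r2 = aaf_concordance([0.1, 0.4, 0.6], [0.1, 0.4, 0.6])
        assert (r, r2) == pytest.approx((1.0, 1.0))

    def test_mirrored_vectors(self):
        a = [0.1, 0.4, 0.6]
        r, _ = aaf_concordance(a, [1 - x for x in a])
        assert r == pytest.approx(-1.0)

    def test_linear_scaling_gives_r_one(self):
        r, r2 = aaf_concordance([0.1, 0.2, 0.3], [0.2, 0.4, 0.6])
        assert (r, r2) == pytest.approx((1.0, 1.0))

    def test_zero_variance_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            aaf_concordance([0.5, 0.5], [0.1, 0.9])


class TestComputeLocusStats:
    def test_table_fields_and_fdr(self):
        gm = gm_from_strings(
            [
                ["0/1", "0/1", "0/0", "1/1"],  # in HWE
                ["0/1", "0/1", "0/1", "0/1"],  # all het
                ["0/0", "./.", "1/1", "1/1"],
            ]
        )
        stats = compute_locus_stats(gm)
        keys = [l.key for l in gm.loci]
        assert stats[keys[0]].n_genotype_classes == 3
        assert stats[keys[1]].ho == 1.0
        assert stats[keys[2]].call_rate == 0.75
        qs = [stats[k].hwe_q for k in keys]
        ps = [stats[k].hwe_p for k in keys]
        assert np.all(np.asarray(qs) >= np.asarray(ps) - 1e-15)
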
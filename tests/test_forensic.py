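"""Forensic parameters, Hardy-Weinberg tests and panel aggregates."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from indelpanel import (
    AlleleFreqs,
    GenotypeCounts,
    GenotypeTable,
    Locus,
    UndefinedStatisticError,
    ValidationError,
    allele_frequencies,
    bonferroni_threshold,
    combined_power,
    discrimination_power,
    expected_het,
    hwe_chisq_pvalue,
    hwe_exact_pvalue,
    observed_het,
    pic,
    power_of_exclusion,
    summarize_panel,
    typical_paternity_index,
)
from indelpanel.forensic import hwe_exact_pvalues_batch

from conftest import round_half_up


def freqs(p, n_alleles=250):
    return AlleleFreqs(p_del=p, p_ins=1 - p, n_alleles=n_alleles)


class TestPerLocusParameters:
    @pytest.mark.parametrize(
        "counts,expected_p",
        [((4, 19, 102), 0.1080), ((0, 0, 10), 0.0), ((30, 49, 46), 0.4360)],
    )
    def test_allele_frequencies(self, counts, expected_p):
        assert allele_frequencies(GenotypeCounts(*counts)).p_del == expected_p

    @pytest.mark.parametrize(
        "counts,expected",
        [((4, 19, 102), 0.1520), ((0, 125, 0), 1.0), ((30, 49, 46), 0.3920)],
    )
    def test_observed_het(self, counts, expected):
        assert observed_het(GenotypeCounts(*counts)) == expected

    def test_expected_het_matches_published(self):
        assert round_half_up(expected_het(freqs(0.4880)), 4) == 0.4997
        assert expected_het(freqs(0.5)) == 0.5
        # small-sample correction factor 2N/(2N-1)
        assert round_half_up(expected_het(freqs(0.1080), corrected=True), 4) == 0.1934

    @pytest.mark.parametrize(
        "p,expected", [(0.4880, 0.3749), (0.5, 0.375), (0.0, 0.0)]
    )
    def test_pic(self, p, expected):
        assert round_half_up(pic(freqs(p)), 4) == expected

    def test_pic_equals_quadratic_form(self):
        for p in np.linspace(0, 1, 21):
            q = 1 - p
            assert pic(freqs(p)) == pytest.approx(2 * p * q - 2 * p * p * q * q)

    @pytest.mark.parametrize(
        "ho,expected", [(0.5680, 0.2542), (0.1520, 0.0181), (0.0, 0.0)]
    )
    def test_power_of_exclusion(self, ho, expected):
        assert round_half_up(power_of_exclusion(ho), 4) == expected

    @pytest.mark.parametrize(
        "ho,expected", [(0.5680, 1.1574), (0.5, 1.0), (0.1520, 0.5896)]
    )
    def test_typical_paternity_index(self, ho, expected):
        assert round_half_up(typical_paternity_index(ho), 4) == expected

    def test_tpi_undefined_at_full_heterozygosity(self):
        with pytest.raises(UndefinedStatisticError):
            typical_paternity_index(1.0)

    @pytest.mark.parametrize(
        "counts,expected",
        [((30, 49, 46), 0.6533), ((4, 19, 102), 0.3100), ((10, 0, 0), 0.0)],
    )
    def test_discrimination_power(self, counts, expected):
        assert round_half_up(discrimination_power(GenotypeCounts(*counts)), 4) == expected

    def test_dp_at_exact_hwe_proportions_closed_form(self):
        # counts exactly at p^2 : 2pq : q^2 give 1 - (p^4 + 4p^2q^2 + q^4)
        p, n = 0.4, 2500
        q = 1 - p
        counts = GenotypeCounts(
            int(n * p * p), int(n * 2 * p * q), int(n * q * q)
        )
        closed = 1 - (p**4 + 4 * p**2 * q**2 + q**4)
        assert discrimination_power(counts) == pytest.approx(closed)


class TestCombinedPower:
    def test_known_values(self):
        assert combined_power([]) == 0.0
        assert combined_power([0.5, 0.5]) == pytest.approx(0.75)

    @given(st.lists(st.floats(0, 0.99), max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_order_invariant_and_monotone(self, values):
        base = combined_power(values)
        assert combined_power(values[::-1]) == pytest.approx(base)
        assert 0.0 <= base < 1.0
        assert combined_power(values + [0.3]) >= base

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            combined_power([1.0])


def enumerate_hwe_null(n, n_del):
    """Brute-force exact-test null: weight of a heterozygote count h is
    n! / (d! h! i!) * 2^h, over all h with the right parity."""
    weights = {}
    for h in range(n_del % 2, min(n_del, 2 * n - n_del) + 1, 2):
        d = (n_del - h) // 2
        i = n - h - d
        weights[h] = (
            math.factorial(n)
            // (math.factorial(d) * math.factorial(h) * math.factorial(i))
            * 2**h
        )
    total = sum(weights.values())
    return {h: w / total for h, w in weights.items()}


class TestHWEExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 0, 1), 1 / 3), ((0, 2, 0), 1.0)],
    )
    def test_tiny_enumeration(self, counts, expected):
        assert hwe_exact_pvalue(GenotypeCounts(*counts)) == pytest.approx(expected)

    @pytest.mark.parametrize("n,n_del", [(2, 2), (10, 7), (25, 30), (125, 109)])
    def test_matches_enumeration_oracle(self, n, n_del):
        null = enumerate_hwe_null(n, n_del)
        assert sum(null.values()) == pytest.approx(1.0, abs=1e-12)
        for h_obs, p_obs in null.items():
            d = (n_del - h_obs) // 2
            counts = GenotypeCounts(d, h_obs, n - h_obs - d)
            expected = sum(p for p in null.values() if p <= p_obs * (1 + 1e-9))
            assert hwe_exact_pvalue(counts) == pytest.approx(min(1.0, expected))

    def test_published_deviant_locus_is_small(self):
        # the one panel locus flagged at nominal alpha=0.05
        p = hwe_exact_pvalue(GenotypeCounts(30, 49, 46))
        assert p < 0.05
        assert p == pytest.approx(0.0285, abs=5e-4)

    def test_monomorphic_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            hwe_exact_pvalue(GenotypeCounts(10, 0, 0))

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        n = 50
        d = rng.integers(1, 2 * n - 1, size=20)
        h = np.array(
            [rng.choice(list(enumerate_hwe_null(n, int(x)))) for x in d]
        )
        batch = hwe_exact_pvalues_batch(n, d, h)
        for x, hh, p in zip(d, h, batch):
            dd = (int(x) - int(hh)) // 2
            counts = GenotypeCounts(dd, int(hh), n - int(hh) - dd)
            assert p == pytest.approx(hwe_exact_pvalue(counts))


class TestHWEChiSquare:
    def test_known_value(self):
        # E = (23.762, 61.476, 39.762) at p_del = 0.436, N = 125
        observed = np.array([30, 49, 46])
        expected = np.array([125 * 0.436**2, 2 * 125 * 0.436 * 0.564, 125 * 0.564**2])
        stat = ((observed - expected) ** 2 / expected).sum()
        want = chi2.sf(stat, df=1)
        assert hwe_chisq_pvalue(GenotypeCounts(30, 49, 46)) == pytest.approx(want)
        assert want == pytest.approx(0.023, abs=5e-4)

    def test_exact_proportions_give_p_one(self):
        assert hwe_chisq_pvalue(GenotypeCounts(25, 50, 25)) == pytest.approx(1.0)

    def test_extreme_het_deficit(self):
        assert hwe_chisq_pvalue(GenotypeCounts(50, 0, 50)) < 1e-15


class TestBonferroni:
    def test_values(self):
        assert round_half_up(bonferroni_threshold(0.05, 30), 4) == 0.0017
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 10) == pytest.approx(0.001)

    def test_domain(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)


@given(p=st.floats(0.0, 1.0))
@settings(max_examples=200, deadline=None)
def test_pic_symmetry_and_bounds(p):
    """PIC is allele-label symmetric, below 0.5, and never exceeds He."""
    value = pic(freqs(p))
    assert value == pytest.approx(pic(freqs(1 - p)), abs=1e-12)
    assert 0.0 <= value < 0.5
    assert expected_het(freqs(p)) >= value - 1e-12


class TestSummarizePanel:
    def test_reconstructed_panel_matches_published(self, bai_table):
        """Recomputing the panel summary from reconstructed genotypes
        reproduces every published He/PIC/PE/TPI/DP cell at 4 dp."""
        from indelpanel.bai_panel import BAI_PANEL

        panel = summarize_panel(bai_table)
        by_name = {r.locus.name: r for r in panel.rows}
        for row in BAI_PANEL:
            got = by_name[row.name]
            assert round_half_up(got.he, 4) == row.he
            assert round_half_up(got.pic, 4) == row.pic
            assert round_half_up(got.pe, 4) == row.pe
            assert round_half_up(got.tpi, 4) == row.tpi
            assert round_half_up(got.dp, 4) == row.dp
            assert round_half_up(got.freqs.p_del, 4) == row.p_del
            assert round_half_up(got.ho, 4) == row.ho
        assert not any(r.hwe_significant_bonferroni for r in panel.rows)

    def test_monomorphic_locus_row(self):
        table = GenotypeTable(
            ["a", "b"], ["X"] * 2, [Locus("L")], np.array([[2.0], [2.0]])
        )
        panel = summarize_panel(table)
        row = panel.rows[0]
        assert row.he == row.pic == row.pe == row.dp == 0.0
        assert row.hwe_p is None and not row.hwe_significant_bonferroni

    def test_identical_columns_identical_rows(self):
        table = GenotypeTable(
            ["a", "b", "c"],
            ["X"] * 3,
            [Locus("L1"), Locus("L2")],
            np.array([[0, 0], [1, 1], [2, 2]], float),
        )
        panel = summarize_panel(table)
        r1, r2 = panel.rows
        assert (r1.he, r1.pic, r1.pe, r1.dp, r1.tpi, r1.hwe_p) == (
            r2.he, r2.pic, r2.pe, r2.dp, r2.tpi, r2.hwe_p
        )
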
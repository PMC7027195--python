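"""Sign tests, correlations and the codon-conservation index."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from swingerscan import enumerate_transformations, parse_name
from swingerscan.stats import (
    ClassSummary,
    abundance_length_correlation,
    class_summaries,
    conservation_abundance_correlation,
    conservation_index,
    pearson,
    sign_test,
    standard_genetic_code,
)
from swingerscan.transforms import IDENTITY, apply_transformation

ALL = enumerate_transformations()

# In-table per-class abundances and mean aligned lengths for the five
# detected classes (A↔T, A↔C, C↔T, G↔T, A→T→C→G→A).
TABLE_SUMMARIES = [
    ClassSummary("A↔T", 219, 325.0, 96.95),
    ClassSummary("A↔C", 2, 225.0, 90.52),
    ClassSummary("C↔T", 1, 196.0, 96.42),
    ClassSummary("G↔T", 1, 152.0, 89.47),
    ClassSummary("A→T→C→G→A", 124, 308.0, 96.95),
]


class TestSignTest:
    def test_regional_bias_mitochondrial(self):
        # 38 of 43 mid+3' hits against a 2/3 null
        assert sign_test(38, 43).p == pytest.approx(1.0608e-3, rel=1e-3)

    def test_regional_bias_nuclear_closed_form(self):
        # all 33 of 33: upper tail collapses to (2/3)^33
        result = sign_test(33, 33)
        assert result.p == pytest.approx((2 / 3) ** 33, rel=1e-12)
        assert result.p == pytest.approx(1.545e-6, rel=1e-3)

    def test_degenerate_tails(self):
        assert sign_test(0, 10).p == 1.0
        assert sign_test(10, 10, Fraction(1, 2)).p == 2 ** -10

    def test_agrees_with_scipy_binomial_tail(self):
        """Exact-rational tail vs scipy's survival function for every
        (k, n <= 60)."""
        for n in range(1, 61):
            k = np.arange(0, n + 1)
            expected = sps.binom.sf(k - 1, n, 2 / 3)
            for ki, e in zip(k, expected):
                assert sign_test(int(ki), n).p == pytest.approx(
                    float(e), rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sign_test(5, 3)
        with pytest.raises(ValueError):
            sign_test(1, 3, 0.0)


class TestCorrelations:
    def test_abundance_length_matches_published_statistics(self):
        result = abundance_length_correlation(TABLE_SUMMARIES)
        assert result.r == pytest.approx(0.96, abs=5e-3)
        assert result.p == pytest.approx(0.00945, abs=2e-4)
        assert result.n == 5

    def test_log_base_invariance(self):
        natural = [ClassSummary(t.name, a, l, None) for t, a, l in
                   zip(ALL, [10, 100, 1000], [100.0, 200.0, 300.0])]
        r_log10 = abundance_length_correlation(natural).r
        # Pearson r is invariant under any affine rescaling of x, hence
        # under changing the base of the logarithm.
        x = [math.log(10), math.log(100), math.log(1000)]
        r_ln = pearson(x, [100.0, 200.0, 300.0]).r
        assert r_log10 == pytest.approx(r_ln, rel=1e-12)

    def test_exactly_linear_gives_r_one(self):
        summaries = [ClassSummary(t.name, a, l, None) for t, a, l in
                     zip(ALL, [10, 100, 1000], [50.0, 100.0, 150.0])]
        assert abundance_length_correlation(summaries).r == pytest.approx(1.0)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            abundance_length_correlation(TABLE_SUMMARIES[:2])

    def test_p_matches_t_distribution_closed_form(self):
        rng = np.random.default_rng(5)
        for n in (5, 23):
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            res = pearson(x, y, tails="two")
            t = res.r * math.sqrt((n - 2) / (1 - res.r ** 2))
            assert res.p == pytest.approx(
                2 * (1 - sps.t.cdf(abs(t), n - 2)), abs=1e-6)
            one = pearson(x, y, tails="one")
            assert one.p == pytest.approx(res.p / 2, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassSummaries:
    def test_from_triples(self):
        triples = [("A↔T", 100, 95.0), ("A↔T", 300, 97.0), ("C↔G", 50, 80.0)]
        out = {s.transformation: s for s in class_summaries(triples)}
        assert out["A↔T"].abundance == 2
        assert out["A↔T"].mean_aligned_length == 200.0
        assert out["C↔G"].mean_percent_identity == 80.0

    def test_include_zero_covers_all_23(self):
        out = class_summaries([("A↔T", 100, 95.0)], include_zero=True)
        assert len(out) == 23
        assert sum(s.abundance for s in out) == 1
        zero = [s for s in out if s.abundance == 0][0]
        assert zero.mean_aligned_length is None

    def test_empty_and_unknown(self):
        assert class_summaries([]) == []
        with pytest.raises(ValueError):
            class_summaries([("A↔Z", 1, 1.0)])


def brute_force_conservation(t):
    """Independent oracle: translate all 64 codons through Biopython's Seq
    machinery before and after the exchange."""
    from Bio.Seq import Seq

    conserved = 0
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                codon = a + b + c
                swapped = apply_transformation(t, codon)
                if str(Seq(codon).translate()) == str(Seq(swapped).translate()):
                    conserved += 1
    return conserved / 64


class TestConservation:
    def test_identity_is_fully_conserved(self):
        assert conservation_index(IDENTITY) == 1.0

    def test_matches_brute_force_oracle_for_all_23(self):
        for t in ALL:
            value = conservation_index(t)
            assert value == brute_force_conservation(t)
            assert 0 <= value < 1

    def test_transitions_more_conservative_than_transversions(self):
        # third-position C/T changes are predominantly synonymous
        assert (conservation_index(parse_name("C↔T"))
                > conservation_index(parse_name("C↔G")))

    def test_incomplete_code_rejected(self):
        code = standard_genetic_code()
        code.pop("ATG")
        with pytest.raises(ValueError):
            conservation_index(parse_name("A↔T"), code)

    def test_abundance_correlation_positive_for_observed_classes(self):
        abundances = {"A↔T": 219, "A↔C": 2, "C↔T": 1, "G↔T": 1,
                      "A→T→C→G→A": 124}
        xs = [abundances.get(t.name, 0) for t in ALL]
        ys = [conservation_index(t) for t in ALL]
        result = conservation_abundance_correlation(xs, ys)
        assert result.n == 23
        assert result.r > 0
        assert result.tails == "one"

    def test_requires_all_23_classes(self):
        with pytest.raises(ValueError):
            conservation_abundance_correlation([1.0] * 22, [0.5] * 22)

    def test_perfect_agreement(self):
        xs = list(range(23))
        result = conservation_abundance_correlation(xs, xs)
        assert result.r == pytest.approx(1.0)
        assert result.p == 0.0
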
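import math

import numpy as np
import pytest
from scipy.integrate import quad

from cblkit.core_io import ProteinRecord, records_to_block
from cblkit.evolution_stats import (
    TajimaDInput,
    TrioCounts,
    chi2_upper_tail,
    harmonic_numbers,
    pairwise_diversity,
    relative_rate_test,
    tajima_d,
    trio_counts,
    watterson_theta,
)
from cblkit.synthetic_data import AlignmentSpec, make_alignment


def block_of(rows):
    return records_to_block(
        [ProteinRecord(id=f"s{i}", sequence=r, aligned=True)
         for i, r in enumerate(rows)]
    )


class TestTrioCounts:
    def test_all_identical(self):
        c = trio_counts(block_of(["AAA", "AAA", "AAA"]))
        assert c.identical == 3 and c.total_sites == 3

    def test_unique_difference_assigned_to_odd_sequence(self):
        c = trio_counts(block_of(["DAG", "EAG", "DAG"]))
        assert c.unique_b == 1 and c.identical == 2

    def test_gapped_columns_dropped_by_complete_deletion(self):
        c = trio_counts(block_of(["D-G", "E-G", "DAG"]))
        assert c.total_sites == 2  # middle column removed
        assert c.unique_b == 1 and c.identical == 1

    def test_all_divergent_column(self):
        c = trio_counts(block_of(["D", "E", "G"]))
        assert c.divergent_all == 1

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="exactly 3"):
            trio_counts(block_of(["AA", "AA"]))


class TestRelativeRate:
    @pytest.mark.parametrize(
        "ua,ub,chi2_2dp,p_5dp",
        [(1, 10, 7.36, 0.00666), (4, 18, 8.91, 0.00284), (36, 16, 7.69, 0.00555)],
    )
    def test_chi2_and_p_from_unique_differences(self, ua, ub, chi2_2dp, p_5dp):
        res = relative_rate_test(TrioCounts(0, ua, ub, 0, 0))
        assert round(res.chi2, 2) == chi2_2dp
        assert round(res.p, 5) == p_5dp
        assert res.df == 1

    def test_equal_rates_give_zero_statistic(self):
        res = relative_rate_test(TrioCounts(10, 5, 5, 0, 0))
        assert res.chi2 == 0 and res.p == 1.0

    def test_symmetric_under_sequence_swap(self):
        a = relative_rate_test(TrioCounts(0, 3, 11, 0, 0))
        b = relative_rate_test(TrioCounts(0, 11, 3, 0, 0))
        assert a.chi2 == b.chi2 and a.p == b.p

    def test_undefined_without_unique_differences(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_rate_test(TrioCounts(10, 0, 0, 5, 0))


class TestChi2UpperTail:
    def test_printed_value(self):
        assert round(chi2_upper_tail(8.91), 5) == 0.00284

    def test_boundary_and_monotonicity(self):
        assert chi2_upper_tail(0.0) == 1.0
        xs = np.linspace(0, 10, 50)
        ps = [chi2_upper_tail(x) for x in xs]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_conventional_threshold(self):
        assert chi2_upper_tail(3.84) == pytest.approx(0.05, abs=5e-4)

    def test_matches_erfc_closed_form_and_density_integration(self):
        def density(t):
            return math.exp(-t / 2) / math.sqrt(2 * math.pi * t)

        for x in (0.5, 2.0, 7.36, 8.91):
            assert chi2_upper_tail(x) == pytest.approx(
                math.erfc(math.sqrt(x / 2)), abs=1e-12
            )
            integral, _ = quad(density, x, np.inf)
            assert chi2_upper_tail(x) == pytest.approx(integral, abs=1e-8)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chi2_upper_tail(-1.0)


class TestWattersonTheta:
    def test_family_scale_value(self):
        assert round(watterson_theta(327, 153, 153), 6) == 0.157093

    def test_no_segregation_gives_zero(self):
        assert watterson_theta(10, 0, 100) == 0.0

    def test_two_sequences_harmonic_base_case(self):
        assert watterson_theta(2, 7, 100) == pytest.approx(0.07)

    def test_segregating_exceeding_sites_rejected(self):
        with pytest.raises(ValueError):
            watterson_theta(5, 11, 10)

    def test_harmonic_sums_match_direct_summation(self):
        for m in (2, 5, 17, 100, 1234, 10_000):
            a1, a2 = harmonic_numbers(m)
            i = np.arange(1, m)
            assert a1 == pytest.approx(float(np.sum(1.0 / i)), rel=1e-14)
            assert a2 == pytest.approx(float(np.sum(1.0 / i**2)), rel=1e-14)


def tajima_d_oracle(m, n, S, pi):
    """From-scratch restatement of the neutrality-test formulas."""
    a1 = sum(1 / i for i in range(1, m))
    a2 = sum(1 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3 * (m - 1))
    b2 = 2 * (m**2 + m + 3) / (9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi * n - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimaD:
    def test_family_scale_value(self):
        res = tajima_d(TajimaDInput(m=327, n=153, S=153, pi=0.385669))
        assert res.D == pytest.approx(4.4137, abs=1e-3)
        assert round(res.theta_per_site, 6) == 0.157093
        assert res.ps == 1.0

    def test_zero_when_diversity_equals_watterson_expectation(self):
        m, n, S = 12, 100, 30
        a1, _ = harmonic_numbers(m)
        pi = S / a1 / n
        res = tajima_d(TajimaDInput(m=m, n=n, S=S, pi=pi))
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_oracle_on_synthetic_alignment(self):
        block, truth = make_alignment(AlignmentSpec(m=20, n=100, S=40, seed=9))
        pi, S, n = pairwise_diversity(block)
        res = tajima_d(TajimaDInput(m=20, n=n, S=S, pi=pi))
        assert res.D == pytest.approx(tajima_d_oracle(20, n, S, pi), abs=1e-12)

    def test_d_strictly_increasing_in_pi(self):
        ds = [
            tajima_d(TajimaDInput(m=20, n=100, S=40, pi=pi)).D
            for pi in (0.05, 0.10, 0.20, 0.40)
        ]
        assert all(d1 < d2 for d1, d2 in zip(ds, ds[1:]))

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            TajimaDInput(m=3, n=10, S=5, pi=0.1)

    def test_zero_segregating_sites_rejected(self):
        with pytest.raises(ValueError, match="S = 0"):
            tajima_d(TajimaDInput(m=5, n=10, S=0, pi=0.0))


class TestPairwiseDiversity:
    def test_identical_sequences(self):
        pi, S, n = pairwise_diversity(block_of(["MKR", "MKR"]))
        assert pi == 0.0 and S == 0 and n == 3

    def test_single_difference_over_two_sites(self):
        pi, S, n = pairwise_diversity(block_of(["AD", "AE"]))
        assert pi == 0.5 and S == 1 and n == 2

    def test_matches_exhaustive_pair_loop(self):
        rng = np.random.default_rng(17)
        letters = list("ACDEFGHIKL")
        rows = ["".join(rng.choice(letters, size=50)) for _ in range(10)]
        pi, S, n = pairwise_diversity(block_of(rows))
        total = pairs = 0
        for i in range(10):
            for j in range(i + 1, 10):
                total += sum(a != b for a, b in zip(rows[i], rows[j])) / 50
                pairs += 1
        assert pi == pytest.approx(total / pairs, abs=1e-12)

    def test_low_coverage_columns_removed(self):
        # second column has 2/4 = 50% coverage: below the 95% threshold
        rows = ["A-C", "A-C", "ADC", "AEC"]
        pi, S, n = pairwise_diversity(block_of(rows))
        assert n == 2 and S == 0 and pi == 0.0

    def test_all_columns_filtered_rejected(self):
        rows = ["A-", "-A", "A-", "-A"]
        with pytest.raises(ValueError, match="coverage"):
            pairwise_diversity(block_of(rows))
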
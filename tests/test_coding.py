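"""Pulse coding, interval extraction and renewal-CLT count reconstruction."""

import numpy as np
import pytest

from twoldm import (
    BinaryCode,
    CountSeries,
    InsufficientDataError,
    IPISequence,
    LikelihoodSeries,
    binarize,
    extract_ipi,
    infomax_threshold,
    rate,
    reconstruct_counts,
    renewal_pulse_code,
)


class TestBinarize:
    def test_strict_threshold(self):
        code = binarize(np.array([0.2, 0.8, 0.3]), 0.5)
        np.testing.assert_array_equal(code.bits, [0, 1, 0])

    def test_tie_is_no_pulse(self):
        code = binarize(np.full(10, 0.5), 0.5)
        assert code.bits.sum() == 0

    def test_count_against_direct_median_count(self, rng):
        y = rng.random(10_000)
        med = float(np.median(y))
        code = binarize(y, med)
        assert code.bits.sum() == int(np.sum(y > med))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([]), 0.5)


class TestExtractIPI:
    def test_hand_counted_example(self):
        code = BinaryCode(bits=[0, 0, 1, 0, 0, 0, 1, 1, 0], threshold=0.5)
        # adjacent pulses give a zero gap (dropped); trailing run is censored
        np.testing.assert_array_equal(extract_ipi(code).intervals, [2, 3])

    def test_all_ones_insufficient(self):
        with pytest.raises(InsufficientDataError):
            extract_ipi(BinaryCode(bits=np.ones(10, dtype=int), threshold=0.0))

    def test_round_trip_known_gaps(self):
        gaps = [3, 1, 4, 2, 5]
        bits = []
        for g in gaps:
            bits.extend([0] * g + [1])
        code = BinaryCode(bits=np.array(bits), threshold=0.0)
        np.testing.assert_array_equal(extract_ipi(code).intervals, gaps)

    def test_geometric_renewal_against_gap_counting_oracle(self, rng):
        # pulses at iid geometric(p) gaps; compare with a direct scan
        bits = (rng.random(100_000) < 0.2).astype(int)
        code = BinaryCode(bits=bits, threshold=0.0)
        ipi = extract_ipi(code)
        # independent oracle: scalar scan counting zero-run lengths
        expected = []
        run = 0
        for b in bits:
            if b == 1:
                if run >= 1:
                    expected.append(run)
                run = 0
            else:
                run += 1
        np.testing.assert_array_equal(ipi.intervals, expected)
        # conditional on gap >= 1, mean of geometric gap is 1/p (support 0,1,2,...)
        se = np.std(expected, ddof=1) / np.sqrt(len(expected))
        assert ipi.mu == pytest.approx(np.mean(expected), abs=1e-12)
        assert ipi.mu == pytest.approx(1.0 / 0.2, abs=3 * se)


class TestInfomaxThreshold:
    def test_small_examples(self):
        assert infomax_threshold(np.array([0.4, 0.6])) == pytest.approx(0.5)
        assert infomax_threshold(np.full(5, 0.37)) == pytest.approx(0.37)

    def test_near_maximal_entropy_for_symmetric_series(self, rng):
        def bernoulli_entropy(q):
            if q in (0.0, 1.0):
                return 0.0
            return -q * np.log2(q) - (1 - q) * np.log2(1 - q)

        y = np.clip(0.5 + 0.1 * rng.standard_normal(5000), 0, 1)
        h_mean = bernoulli_entropy(binarize(y, infomax_threshold(y)).bits.mean())
        h_median = bernoulli_entropy(binarize(y, float(np.median(y))).bits.mean())
        assert h_mean >= 0.95 * h_median


class TestReconstructCounts:
    def test_degenerate_sigma_zero_is_deterministic(self):
        N = reconstruct_counts((4.0, 0.0), horizon=50, n_pop=10, seed=0)
        t = np.arange(1, 51)
        np.testing.assert_allclose(N.values, t / 4.0)

    def test_clt_moments_across_seeds(self):
        # mean t/mu and variance t sigma^2 / mu^3 / n_pop of the average
        mu, sigma, horizon, n_pop, reps = 4.0, 2.0, 100, 50, 200
        finals = np.array(
            [
                reconstruct_counts((mu, sigma), horizon, n_pop, seed=s).values[-1]
                for s in range(reps)
            ]
        )
        true_mean = horizon / mu
        true_var = horizon * sigma**2 / mu**3 / n_pop
        assert finals.mean() == pytest.approx(true_mean, abs=3 * np.sqrt(true_var / reps))
        # chi-square spread of a variance estimate: ~3*sqrt(2/(reps-1)) relative
        assert finals.var(ddof=1) == pytest.approx(true_var, rel=3 * np.sqrt(2 / (reps - 1)))

    def test_seed_determinism(self):
        a = reconstruct_counts((3.0, 1.0), 40, 20, seed=5)
        b = reconstruct_counts((3.0, 1.0), 40, 20, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_moments_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_counts((0.0, 1.0), 10, 5, seed=0)
        with pytest.raises(ValueError):
            reconstruct_counts((1.0, -1.0), 10, 5, seed=0)


class TestRateAndRenewalCode:
    def test_rate_of_deterministic_count_is_inverse_mu(self):
        N = reconstruct_counts((4.0, 0.0), horizon=30, n_pop=1, seed=0)
        np.testing.assert_allclose(rate(N), 0.25)

    def test_rate_identity_series(self):
        N = CountSeries(values=np.arange(1.0, 21.0), mu_src=1.0, sigma_src=0.0)
        np.testing.assert_allclose(rate(N), 1.0)
        assert rate(N)[0] == N.values[0]

    def test_unit_increments_pulse_every_theta(self):
        N = CountSeries(values=np.arange(1.0, 13.0), mu_src=1.0, sigma_src=0.0)
        code = renewal_pulse_code(N, 3.0)
        np.testing.assert_array_equal(code.bits, [0, 0, 1, 0, 0, 1, 0, 0, 1, 0, 0, 1])

    def test_unreachable_threshold_all_zero(self):
        N = CountSeries(values=np.arange(1.0, 13.0), mu_src=1.0, sigma_src=0.0)
        assert renewal_pulse_code(N, 100.0).bits.sum() == 0

    def test_random_increments_match_scalar_oracle(self, rng):
        values = np.cumsum(rng.normal(0.5, 1.0, size=500))
        N = CountSeries(values=values, mu_src=2.0, sigma_src=1.0)
        code = renewal_pulse_code(N, 5.0)
        # independent step-by-step oracle
        acc, prev, expected = 0.0, 0.0, []
        for v in values:
            acc += v - prev
            prev = v
            if acc >= 5.0:
                expected.append(1)
                acc = 0.0
            else:
                expected.append(0)
        np.testing.assert_array_equal(code.bits, expected)

    def test_nonpositive_threshold_rejected(self):
        N = CountSeries(values=np.arange(1.0, 5.0), mu_src=1.0, sigma_src=0.0)
        with pytest.raises(ValueError):
            renewal_pulse_code(N, 0.0)


class TestContainers:
    def test_likelihood_bounds_enforced(self):
        with pytest.raises(ValueError):
            LikelihoodSeries(values=np.array([0.5, 1.2]))

    def test_ipi_moments_recomputed_from_intervals(self):
        ipi = IPISequence(intervals=[2, 4, 6])
        assert ipi.mu == pytest.approx(4.0)
        assert ipi.sigma == pytest.approx(2.0)

    def test_zero_or_negative_intervals_rejected(self):
        with pytest.raises(ValueError):
            IPISequence(intervals=[2, 0, 3])
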
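"""Luria–Delbrück pmf, likelihood, MLE, intervals and pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from helpers_oracles import (
    brute_min_groups,
    grid_lr_interval,
    grid_mle,
    lc_pmf_fft,
    mc_mutant_counts,
)
from errorthreshold.fluctuation import (
    ConvergenceError,
    CultureSet,
    RateEstimate,
    _mss_pmf,
    _thinned_pmf_conv,
    _thinned_pmf_series,
    ld_pmf,
    log_likelihood,
    lr_interval,
    mle_m,
    pool_experiments,
)


class TestLdPmf:
    def test_no_mutations_is_degenerate_at_zero(self):
        assert ld_pmf(0.0, 5, 1.0).tolist() == [1, 0, 0, 0, 0, 0]

    def test_zero_class_is_exp_minus_m(self):
        assert ld_pmf(1.0, 0, 1.0)[0] == pytest.approx(math.exp(-1), rel=1e-12)
        for m in (0.3, 2.7, 9.0):
            assert ld_pmf(m, 3)[0] == pytest.approx(math.exp(-m), rel=1e-12)

    @pytest.mark.parametrize("m", [0.3, 1.0, 3.0])
    def test_matches_pgf_inversion_oracle(self, m):
        # independent route: FFT inversion of exp(m (1-s)/s ln(1-s))
        got = ld_pmf(m, 40)
        want = lc_pmf_fft(m, 40)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_first_entries_frozen_values(self):
        # frozen from the pgf-inversion oracle and 2e6-rep mechanistic MC
        p = ld_pmf(1.0, 3)
        assert p[1] == pytest.approx(0.183940, abs=5e-7)
        assert p[2] == pytest.approx(0.107298, abs=5e-7)
        assert p[3] == pytest.approx(0.068977, abs=5e-7)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            ld_pmf(-0.5, 5)
        with pytest.raises(ValueError):
            ld_pmf(1.0, -1)
        with pytest.raises(ValueError):
            ld_pmf(1.0, 5, 0.0)
        with pytest.raises(ValueError):
            ld_pmf(1.0, 5, 1.2)

    @pytest.mark.parametrize("m", [0.5, 2.0, 10.0])
    def test_normalization_with_adaptive_horizon(self, m):
        # heavy 1/n^2 tail: partial sums approach 1 slowly but surely
        n_max = int(3000 * max(m, 1.0))
        assert _mss_pmf(m, n_max).sum() >= 0.999

    def test_p0_strictly_decreasing_in_m(self):
        ms = np.linspace(0.0, 8.0, 30)
        p0 = [ld_pmf(m, 0)[0] for m in ms]
        assert all(a > b for a, b in zip(p0, p0[1:]))

    @given(m=st.floats(0.1, 8.0), z=st.floats(0.05, 1.0), n=st.integers(0, 30))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_probability_vector_properties(self, m, z, n):
        p = ld_pmf(m, n, z)
        assert p.shape == (n + 1,)
        assert (p >= -1e-14).all()
        assert p.sum() <= 1.0 + 1e-9


class TestThinning:
    @pytest.mark.parametrize("z", [0.1, 0.25, 0.4, 0.5])
    def test_series_equals_binomial_thinning_convolution(self, z):
        a = _thinned_pmf_series(2.0, 25, z)
        b = _thinned_pmf_conv(2.0, 25, z)
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-13)

    def test_thinned_zero_class_matches_pgf_closed_form(self):
        # P(0) = G(1-z) with G the Lea-Coulson pgf
        for m, z in [(1.0, 0.2), (3.0, 0.7), (0.5, 0.05)]:
            u = 1.0 - z
            want = math.exp(m * ((1 - u) / u) * math.log(1 - u))
            assert ld_pmf(m, 0, z)[0] == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize("z", [0.2, 0.7])
    def test_matches_monte_carlo_frequencies(self, z, rng):
        m, reps = 1.0, 100_000
        counts = mc_mutant_counts(m, reps, rng, plating_fraction=z)
        p = ld_pmf(m, 4, z)
        for k in range(5):
            freq = float((counts == k).mean())
            se = math.sqrt(p[k] * (1 - p[k]) / reps)
            assert abs(freq - p[k]) < 3 * se + 1e-12


class TestLikelihood:
    def test_all_zero_counts(self):
        cs = CultureSet(counts=(0,) * 7, n_total=1e6)
        assert log_likelihood(cs, 1.0) == pytest.approx(-7.0, rel=1e-12)

    def test_two_culture_decomposition(self):
        cs = CultureSet(counts=(0, 1), n_total=1e6)
        want = math.log(0.36787944117144233) + math.log(0.18393972058572117)
        assert log_likelihood(cs, 1.0) == pytest.approx(want, rel=1e-10)

    def test_impossible_outcome_is_minus_inf(self):
        cs = CultureSet(counts=(0, 3), n_total=1e6)
        assert log_likelihood(cs, 0.0) == -math.inf

    def test_extends_to_largest_count(self):
        cs = CultureSet(counts=(250,), n_total=1e6)
        assert math.isfinite(log_likelihood(cs, 2.0))


class TestMle:
    def test_all_zero_counts_boundary(self):
        cs = CultureSet(counts=(0,) * 9, n_total=1e7)
        est = mle_m(cs)
        assert est.m_hat == 0.0
        assert est.rate == 0.0

    def test_matches_grid_oracle(self, mle_fixtures):
        for cs in mle_fixtures:
            m_hat = mle_m(cs).m_hat
            m_grid = grid_mle(cs)
            assert m_hat == pytest.approx(m_grid, rel=1e-4), cs.label

    def test_rate_is_m_over_nt(self, mle_fixtures):
        cs = mle_fixtures[0]
        est = mle_m(cs)
        assert est.rate == pytest.approx(est.m_hat / cs.n_total, rel=1e-12)

    def test_single_culture_allowed(self):
        est = mle_m(CultureSet(counts=(4,), n_total=1e6))
        assert est.m_hat > 0

    def test_rate_scaling_with_divisions(self, mle_fixtures):
        cs = mle_fixtures[2]
        a = mle_m(cs)
        scaled = CultureSet(counts=cs.counts, n_total=cs.n_total * 10,
                            plating_fraction=cs.plating_fraction)
        b = mle_m(scaled)
        assert b.m_hat == pytest.approx(a.m_hat, rel=1e-9)
        assert b.rate == pytest.approx(a.rate / 10, rel=1e-9)


class TestLrInterval:
    def test_all_zero_counts_lower_boundary(self):
        cs = CultureSet(counts=(0,) * 9, n_total=1e7)
        lo, hi = lr_interval(cs)
        assert lo == 0.0
        # closed form: loglik(m) = -9m, so hi solves 18 m = chi2_1(0.95)
        assert hi == pytest.approx(chi2.ppf(0.95, 1) / 18.0, rel=1e-6)

    def test_brackets_the_mle(self, mle_fixtures):
        for cs in mle_fixtures[:4]:
            m_hat = mle_m(cs).m_hat
            lo, hi = lr_interval(cs, m_hat=m_hat)
            assert lo <= m_hat <= hi

    def test_matches_profile_scan_oracle(self, mle_fixtures):
        halfcrit = chi2.ppf(0.95, 1) / 2
        for cs in mle_fixtures[:4]:
            m_hat = mle_m(cs).m_hat
            lo, hi = lr_interval(cs, m_hat=m_hat)
            glo, ghi = grid_lr_interval(cs, m_hat, halfcrit)
            if glo > 0:
                assert lo == pytest.approx(glo, rel=1e-3)
            assert hi == pytest.approx(ghi, rel=1e-3)

    def test_level_widens_interval(self, mle_fixtures):
        cs = mle_fixtures[0]
        m_hat = mle_m(cs).m_hat
        lo95, hi95 = lr_interval(cs, level=0.95, m_hat=m_hat)
        lo99, hi99 = lr_interval(cs, level=0.99, m_hat=m_hat)
        assert lo99 <= lo95 and hi99 >= hi95

    def test_ci_rate_scaled_by_nt(self, mle_fixtures):
        from errorthreshold.fluctuation import estimate_rate

        cs = mle_fixtures[0]
        est = estimate_rate(cs)
        assert est.ci_rate[0] == pytest.approx(est.ci_m[0] / cs.n_total, rel=1e-12)
        assert est.ci_rate[1] == pytest.approx(est.ci_m[1] / cs.n_total, rel=1e-12)


class TestPooling:
    def test_compatible_sets_merge(self):
        a = CultureSet(counts=(0, 1), n_total=1.0e6, label="a")
        b = CultureSet(counts=(2, 3), n_total=1.5e6, label="b")
        out = pool_experiments([a, b])
        assert len(out) == 1
        assert sorted(out[0].counts) == [0, 1, 2, 3]
        assert out[0].n_total == pytest.approx(1.25e6)
        assert not out[0].flagged

    def test_discordant_sets_kept_and_flagged(self):
        a = CultureSet(counts=(0, 1), n_total=1.0e6, label="a")
        b = CultureSet(counts=(2, 3), n_total=2.5e6, label="b")
        out = pool_experiments([a, b])
        assert len(out) == 2
        assert all(s.flagged for s in out)

    def test_chain_of_three_merges_into_one(self):
        sets = [CultureSet(counts=(i,), n_total=nt * 1e6, label=str(i))
                for i, nt in enumerate((1.0, 1.4, 1.9))]
        out = pool_experiments(sets)
        assert len(out) == 1
        assert len(out[0].counts) == 3

    @pytest.mark.parametrize("nts", [
        (1.0, 1.4, 1.9), (1.0, 2.5), (1.0, 1.9, 3.5, 6.0, 6.5),
        (1.0,), (1.0, 1.0, 1.0), (1.0, 1.99, 3.9, 7.7),
    ])
    def test_greedy_grouping_is_minimal(self, nts):
        sets = [CultureSet(counts=(1,), n_total=nt * 1e6, label=str(i))
                for i, nt in enumerate(nts)]
        out = pool_experiments(sets)
        assert len(out) == brute_min_groups([nt * 1e6 for nt in nts])
        # every merged group is internally compatible
        total = sum(len(s.counts) for s in out)
        assert total == len(nts)

    def test_different_plating_fractions_not_merged(self):
        a = CultureSet(counts=(0, 1), n_total=1.0e6, plating_fraction=1.0)
        b = CultureSet(counts=(2, 3), n_total=1.1e6, plating_fraction=0.1)
        assert len(pool_experiments([a, b])) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_experiments([])


class TestValidation:
    def test_culture_set_invariants(self):
        with pytest.raises(ValueError):
            CultureSet(counts=(), n_total=1e6)
        with pytest.raises(ValueError):
            CultureSet(counts=(-1,), n_total=1e6)
        with pytest.raises(ValueError):
            CultureSet(counts=(0,), n_total=0.0)
        with pytest.raises(ValueError):
            CultureSet(counts=(0,), n_total=1e6, plating_fraction=0.0)
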
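import itertools
import time

import numpy as np
import pytest

from synquant import (
    Dataset,
    ModelParams,
    SpikeTrain,
    Sweep,
    amplitude_log_density,
    brute_force_loglik,
    joint_release_probability,
    loglik_correlated,
    loglik_dataset,
    loglik_uncorrelated,
    release_pmf,
    restock_pmf,
    schedule,
)
from synquant.likelihood import (
    final_observation_vector,
    loglik_correlated_reference,
    observation_matrix,
    site_release_history_pmf,
)

from _util import FIG1, random_instance, random_params, random_spikes


class TestReleasePmf:
    def test_empty_occupancy(self):
        assert release_pmf(0, 0, 0.3) == 1.0
        assert release_pmf(1, 0, 0.3) == 0.0

    def test_certain_full_release(self):
        assert release_pmf(3, 3, 1.0) == 1.0

    def test_hand_value(self):
        assert release_pmf(1, 2, 0.5) == pytest.approx(0.5)

    def test_sums_to_one(self):
        for y in range(5):
            total = sum(release_pmf(k, y, 0.37) for k in range(y + 1))
            assert total == pytest.approx(1.0, abs=1e-14)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            release_pmf(-1, 2, 0.5)


class TestRestockPmf:
    def test_no_restock(self):
        assert restock_pmf(1, 1, 2, 0.0, 3) == 1.0  # y_next = y - k
        assert restock_pmf(2, 1, 2, 0.0, 3) == 0.0

    def test_full_restock(self):
        assert restock_pmf(3, 1, 2, 1.0, 3) == 1.0
        assert restock_pmf(2, 1, 2, 1.0, 3) == 0.0

    def test_hand_value(self):
        # n=2, y=1, k=1, g=0.5: both sites empty, one refills
        assert restock_pmf(1, 1, 1, 0.5, 2) == pytest.approx(0.5)

    def test_impossible_drop(self):
        assert restock_pmf(0, 0, 2, 0.5, 3) == 0.0  # y_next < y - k

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            restock_pmf(1, 3, 2, 0.5, 3)  # k > y

    def test_column_stochastic(self):
        for y in range(4):
            for k in range(y + 1):
                total = sum(restock_pmf(y2, k, y, 0.42, 3) for y2 in range(4))
                assert total == pytest.approx(1.0, abs=1e-14)


class TestObservationMatrix:
    def test_unit_density_columns_sum_to_one(self, fig1_params):
        n = fig1_params.n
        Q = observation_matrix(0.5, 0.6, 0.3, fig1_params, dens_row=np.ones(n + 1))
        np.testing.assert_allclose(Q.sum(axis=0), 1.0, atol=1e-13)

    def test_column_sums_match_mixture(self, fig1_params):
        n = fig1_params.n
        A, u, g = 0.4, 0.55, 0.3
        Q = observation_matrix(A, u, g, fig1_params)
        dens = np.array([np.exp(amplitude_log_density(A, k, fig1_params)) for k in range(n + 1)])
        for y in range(n + 1):
            expect = sum(dens[k] * release_pmf(k, y, u) for k in range(y + 1))
            assert Q[:, y].sum() == pytest.approx(expect, rel=1e-12)

    def test_n1_hand_expansion(self):
        p = ModelParams(**{**FIG1, "n": 1})
        A, u, g = 0.2, 0.6, 0.25
        d0 = np.exp(amplitude_log_density(A, 0, p))
        d1 = np.exp(amplitude_log_density(A, 1, p))
        Q = observation_matrix(A, u, g, p)
        # y=0: no release, k=0; restock with prob g
        assert Q[0, 0] == pytest.approx(d0 * (1 - g), rel=1e-12)
        assert Q[1, 0] == pytest.approx(d0 * g, rel=1e-12)
        # y=1: k=0 keeps site stocked; k=1 empties then maybe restocks
        assert Q[0, 1] == pytest.approx(u * d1 * (1 - g), rel=1e-12)
        assert Q[1, 1] == pytest.approx((1 - u) * d0 + u * d1 * g, rel=1e-12)

    def test_final_vector_n1(self):
        p = ModelParams(**{**FIG1, "n": 1})
        A, u = 0.3, 0.7
        d0 = np.exp(amplitude_log_density(A, 0, p))
        d1 = np.exp(amplitude_log_density(A, 1, p))
        L = final_observation_vector(A, u, p)
        np.testing.assert_allclose(L, [d0, (1 - u) * d0 + u * d1], rtol=1e-12)

    def test_final_vector_no_release(self, fig1_params):
        L = final_observation_vector(0.1, 0.0, fig1_params)
        d0 = np.exp(amplitude_log_density(0.1, 0, fig1_params))
        np.testing.assert_allclose(L, d0, rtol=1e-12)


class TestCorrelatedLoglik:
    def test_single_spike_mixture(self):
        p = ModelParams(**{**FIG1, "n": 1})
        A = 0.22
        sw = Sweep(spikes=SpikeTrain([0.0]), amplitudes=[A])
        d0 = np.exp(amplitude_log_density(A, 0, p))
        d1 = np.exp(amplitude_log_density(A, 1, p))
        expect = np.log((1 - p.p0) * d0 + p.p0 * d1)
        assert loglik_correlated(sw, p) == pytest.approx(expect, rel=1e-12)

    def test_matches_brute_force_randomized(self, rng):
        for _ in range(20):
            params, sweep = random_instance(rng)
            a = loglik_correlated(sweep, params)
            b = brute_force_loglik(sweep, params)
            assert a == pytest.approx(b, rel=1e-10)

    def test_matches_reference_matrix_product(self, rng):
        for _ in range(5):
            params, sweep = random_instance(rng, n_max=6, M_max=8)
            assert loglik_correlated(sweep, params) == pytest.approx(
                loglik_correlated_reference(sweep, params), rel=1e-10
            )

    def test_independence_limit_full_restock(self, rng):
        for _ in range(5):
            params, _ = random_instance(rng)
            params = params.replace(tau_D=1e-3)  # g > 1 - 1e-10 at 30 Hz
            spikes = SpikeTrain(np.arange(10) / 30.0)
            from synquant import simulate_sweep

            sweep = simulate_sweep(params, spikes, rng)
            a = loglik_correlated(sweep, params)
            b = loglik_uncorrelated(sweep, params)
            assert a == pytest.approx(b, abs=1e-8)

    def test_long_train_finite_and_linear(self, fig1_params, rng):
        timings = {}
        for M in (10, 100, 1000):
            spikes = SpikeTrain(np.arange(M) / 30.0)
            amps = rng.normal(0.5, 0.3, M)
            sweep = Sweep(spikes=spikes, amplitudes=amps)
            t0 = time.perf_counter()
            ll = loglik_correlated(sweep, fig1_params)
            timings[M] = time.perf_counter() - t0
            assert np.isfinite(ll)
        # loose linearity check: 10x more spikes should not cost ~100x
        assert timings[1000] < 30 * timings[100] + 0.05

    def test_m1_likelihood_normalizes(self, fig1_params):
        grid = np.linspace(-0.6, 4.0, 1200)
        vals = [
            np.exp(loglik_correlated(Sweep(spikes=SpikeTrain([0.0]), amplitudes=[a]), fig1_params))
            for a in grid
        ]
        assert np.trapezoid(vals, grid) == pytest.approx(1.0, abs=1e-5)


class TestUncorrelatedLoglik:
    def test_m1_equals_correlated(self, fig1_params, rng):
        sw = Sweep(spikes=SpikeTrain([0.0]), amplitudes=[0.9])
        assert loglik_uncorrelated(sw, fig1_params) == pytest.approx(
            loglik_correlated(sw, fig1_params), rel=1e-12
        )

    def test_differs_for_depressing_synapse(self, rng):
        p = ModelParams(
            n=2, tau_D=5.0, tau_F=0.2, p0=0.9, p1=None, mu_a=0.25,
            sigma_a=0.1, sigma_b=0.05, variant="depression_only",
        )
        spikes = SpikeTrain(np.arange(3) / 30.0)
        sw = Sweep(spikes=spikes, amplitudes=[0.5, 0.45, 0.4])
        a = loglik_correlated(sw, p)
        b = loglik_uncorrelated(sw, p)
        assert abs(a - b) > 1e-3

    def test_meanfield_option_runs(self, fig1_params, rng):
        _, sweep = random_instance(rng, n_max=4, M_max=5)
        exact = loglik_uncorrelated(sweep, fig1_params)
        mf = loglik_uncorrelated(sweep, fig1_params, marginal="meanfield")
        assert np.isfinite(exact) and np.isfinite(mf)

    def test_unknown_marginal_rejected(self, fig1_params):
        sw = Sweep(spikes=SpikeTrain([0.0]), amplitudes=[0.1])
        with pytest.raises(ValueError):
            loglik_uncorrelated(sw, fig1_params, marginal="bogus")


class TestJointReleaseProbability:
    def test_n1_two_spikes_hand_value(self):
        p = ModelParams(**{**FIG1, "n": 1})
        spikes = SpikeTrain([0.0, 1 / 30])
        sched = schedule(p, spikes)
        expect = sched.u_pre[0] * sched.g[0] * sched.u_pre[1]
        assert joint_release_probability([1, 1], p, spikes) == pytest.approx(expect, rel=1e-12)

    def test_no_restock_blocks_double_release(self):
        p = ModelParams(**{**FIG1, "n": 1, "tau_D": 1e15})
        spikes = SpikeTrain([0.0, 1 / 30])
        assert joint_release_probability([1, 1], p, spikes) == pytest.approx(0.0, abs=1e-15)

    def test_sums_to_one(self, rng):
        for _ in range(5):
            params = random_params(rng, n_max=3)
            M = int(rng.integers(2, 5))
            spikes = random_spikes(rng, M)
            total = sum(
                joint_release_probability(ks, params, spikes)
                for ks in itertools.product(range(params.n + 1), repeat=M)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self, fig1_params, regular_30hz):
        with pytest.raises(ValueError):
            joint_release_probability([8] * 5, fig1_params, regular_30hz)

    def test_matches_site_history_enumeration(self, rng):
        params = random_params(rng, n_max=3)
        spikes = random_spikes(rng, 3)
        sched = schedule(params, spikes)
        site = site_release_history_pmf(sched.u_pre, sched.g)
        assert sum(site.values()) == pytest.approx(1.0, abs=1e-14)
        # convolve site pmfs and compare a few joint probabilities
        from synquant.likelihood import _joint_count_pmf_enumerated

        dist = _joint_count_pmf_enumerated(params, spikes)
        for ks in itertools.product(range(params.n + 1), repeat=3):
            assert joint_release_probability(list(ks), params, spikes) == pytest.approx(
                dist.get(ks, 0.0), abs=1e-12
            )


class TestBruteForce:
    def test_m1_matches_mixture(self, fig1_params):
        sw = Sweep(spikes=SpikeTrain([0.0]), amplitudes=[0.8])
        assert brute_force_loglik(sw, fig1_params) == pytest.approx(
            loglik_correlated(sw, fig1_params), rel=1e-10
        )

    def test_guard(self):
        p = ModelParams(**FIG1)  # n = 7
        spikes = SpikeTrain(np.arange(8) / 30.0)
        sw = Sweep(spikes=spikes, amplitudes=np.full(8, 0.5))
        with pytest.raises(ValueError):
            brute_force_loglik(sw, p)  # 8^8 > 1e6


class TestDataset:
    def test_single_sweep_dataset(self, fig1_params, rng):
        _, sweep = random_instance(rng)
        ds = Dataset(sweeps=(sweep,))
        assert loglik_dataset(ds, fig1_params) == pytest.approx(
            loglik_correlated(sweep, fig1_params), rel=1e-12
        )

    def test_permutation_invariance(self, fig1_params, rng):
        sweeps = [random_instance(rng)[1] for _ in range(3)]
        a = loglik_dataset(Dataset(sweeps=tuple(sweeps)), fig1_params)
        b = loglik_dataset(Dataset(sweeps=tuple(reversed(sweeps))), fig1_params)
        assert a == pytest.approx(b, rel=1e-12)

    def test_duplicate_sweep_doubles(self, fig1_params, rng):
        _, sweep = random_instance(rng)
        single = loglik_dataset(Dataset(sweeps=(sweep,)), fig1_params)
        double = loglik_dataset(Dataset(sweeps=(sweep, sweep)), fig1_params)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            Dataset(sweeps=())

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            Sweep(spikes=SpikeTrain([0.0, 0.1]), amplitudes=[0.5])
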
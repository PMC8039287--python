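"""Phase, synchronization, surrogate, and graph-metric unit tests."""

import numpy as np
import pytest

from microtrauma.netmetrics import (
    SpikeTrainSet,
    aaft_surrogate,
    compute_network_metrics,
    connectivity,
    instantaneous_phase,
    modularity,
    pairwise_sync,
    participation_index,
    surrogate_sync_matrices,
    sync_indices,
)


class TestInstantaneousPhase:
    def test_phase_at_spike_times_is_2pi_n(self):
        train = np.array([0.0, 1.0, 2.0, 4.0])
        phi = instantaneous_phase(train, np.array([0.0, 1.0, 2.0]))
        assert np.allclose(phi, [0.0, 2 * np.pi, 4 * np.pi])

    def test_linear_interpolation_between_spikes(self):
        train = np.array([0.0, 1.0, 2.0])
        # midpoint of the first interval: 2*pi*0 + pi
        assert np.isclose(instantaneous_phase(train, 0.5)[()], np.pi)
        # quarter point: pi/2
        assert np.isclose(instantaneous_phase(train, 0.25)[()], np.pi / 2)

    def test_undefined_outside_support(self):
        train = np.array([1.0, 2.0])
        phi = instantaneous_phase(train, np.array([0.5, 1.5, 2.0, 3.0]))
        assert np.isnan(phi[0]) and np.isnan(phi[2]) and np.isnan(phi[3])
        assert np.isfinite(phi[1])

    def test_requires_two_spikes(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.array([1.0]), 1.0)


class TestPairwiseSync:
    def test_identical_trains_fully_synchronized(self, periodic_trains):
        s = pairwise_sync(periodic_trains)
        assert np.allclose(s, 1.0)

    def test_constant_phase_offset_still_unit_sync(self):
        a = np.arange(1.0, 59.0, 2.0)
        sts = SpikeTrainSet([a, a + 0.5], duration=60.0)
        s = pairwise_sync(sts)
        assert s[0, 1] > 0.999

    def test_drifting_phase_difference_near_zero(self):
        # incommensurate periods sweep the phase difference uniformly
        a = np.arange(0.5, 600.0, 1.0)
        b = np.arange(0.5, 600.0, 1.07)
        sts = SpikeTrainSet([a, b], duration=600.0)
        s = pairwise_sync(sts)
        n_samples = 600 * 10
        assert s[0, 1] < 5.0 / np.sqrt(n_samples)

    def test_insufficient_common_support_is_missing(self):
        a = np.array([0.0, 1.0, 2.0])          # support ends at 2 s
        b = np.array([55.0, 56.0, 57.0])       # support starts at 55 s
        s = pairwise_sync(SpikeTrainSet([a, b], duration=60.0))
        assert np.isnan(s[0, 1])


class TestAAFT:
    def test_sorted_amplitudes_preserved_exactly(self, rng):
        x = rng.lognormal(size=256)
        surr = aaft_surrogate(x, rng)
        assert np.array_equal(np.sort(surr), np.sort(x))

    def test_lag1_autocorrelation_approximately_preserved(self, rng):
        t = np.arange(1024)
        x = np.sin(2 * np.pi * t / 50) + 0.3 * rng.standard_normal(1024)

        def ac1(v):
            v = v - v.mean()
            return float(np.dot(v[:-1], v[1:]) / np.dot(v, v))

        surr = aaft_surrogate(x, rng)
        assert abs(ac1(surr) - ac1(x)) < 0.1

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            aaft_surrogate(np.arange(5.0), rng)

    def test_surrogates_abolish_cross_neuron_sync(self, periodic_trains, rng):
        surr = surrogate_sync_matrices(periodic_trains, n_surrogates=50, rng=rng)
        off = np.stack(surr)[:, ~np.eye(20, dtype=bool)]
        assert np.nanmean(off) < 0.3  # original S_jk all equal 1


class TestSyncIndices:
    def _surrogate_identities(self, m, n=20):
        return [np.eye(m) for _ in range(n)]

    def test_direct_formula_substitution(self):
        # S with eigenvalues {0, 1, 2}; identity surrogates give
        # lam'_mean = 1, SD = 0: SynIndex = (2-1)/(3-1) = 0.5
        s = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        summary, syn, gsi = sync_indices(s, self._surrogate_identities(3))
        assert np.isclose(gsi, 0.5)
        assert np.isclose(syn.max(), 0.5)

    def test_insignificant_eigenvalue_gives_zero_index(self, rng):
        s = np.eye(4)  # all eigenvalues 1, equal to surrogate mean
        _, syn, gsi = sync_indices(s, self._surrogate_identities(4))
        assert np.all(syn == 0.0) and gsi == 0.0

    def test_fully_synchronized_gives_si_of_one(self, periodic_trains, rng):
        s = pairwise_sync(periodic_trains)
        surr = surrogate_sync_matrices(periodic_trains, 50, rng)
        _, _, gsi = sync_indices(s, surr)
        assert np.isclose(gsi, 1.0)

    def test_requires_19_surrogates(self):
        with pytest.raises(ValueError):
            sync_indices(np.eye(3), self._surrogate_identities(3, n=10))

    def test_eigenvalue_sum_equals_neuron_count(self, rng):
        for m in (3, 7, 12):
            phases = rng.uniform(0, 2 * np.pi, (m, 200))
            z = np.exp(1j * phases)
            s = np.abs(z @ z.conj().T) / 200
            np.fill_diagonal(s, 1.0)
            lam = np.linalg.eigvalsh(s)
            assert np.isclose(lam.sum(), m, atol=1e-10)


class TestParticipation:
    def test_fully_synchronized_all_pi_one(self, rng):
        t = np.arange(1.0, 59.0, 2.0)
        sts = SpikeTrainSet([t.copy() for _ in range(10)], 60.0)
        s = pairwise_sync(sts)
        surr = surrogate_sync_matrices(sts, 25, rng)
        summary, syn, _ = sync_indices(s, surr)
        pi = participation_index(summary, syn)
        assert np.allclose(pi, 1.0)

    def test_no_significant_cluster_all_pi_zero(self):
        s = np.eye(5)
        summary, syn, _ = sync_indices(s, [np.eye(5)] * 20)
        pi = participation_index(summary, syn)
        assert np.all(pi == 0.0)

    def test_synchronized_group_outranks_independent_group(self):
        t = np.arange(1.0, 59.0, 2.0)
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            indep = [np.sort(rng.uniform(0, 60, rng.poisson(21)))
                     for _ in range(5)]
            indep = [np.unique(x) for x in indep]
            sts = SpikeTrainSet([t.copy() for _ in range(5)] + indep, 60.0)
            nm = compute_network_metrics(sts, n_surrogates=25, seed=seed)
            diffs.append(np.nanmean(nm.pi[:5]) - np.nanmean(nm.pi[5:]))
        assert np.mean(diffs) > 0.2


def _poisson_train(rng, rate=0.35, duration=60.0):
    n = rng.poisson(rate * duration)
    return np.unique(np.sort(rng.uniform(0.0, duration, n)))


class TestConnectivity:
    def test_two_identical_trains_fully_connected(self, rng):
        t = _poisson_train(rng)
        sts = SpikeTrainSet([t.copy(), t.copy()], 60.0)
        _, ci = connectivity(sts, rng=rng)
        assert np.allclose(ci, [1.0, 1.0])

    def test_hub_neuron_has_unit_ci(self, rng):
        t = _poisson_train(rng)
        sts = SpikeTrainSet([t.copy() for _ in range(10)], 60.0)
        _, ci = connectivity(sts, rng=rng)
        assert np.allclose(ci, 1.0)

    def test_independent_neuron_has_low_ci(self):
        # independent same-rate trains: false-edge rate bounded near alpha
        cis = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            trains = [_poisson_train(rng) for _ in range(6)]
            sts = SpikeTrainSet(trains, 60.0)
            _, ci = connectivity(sts, alpha=0.05, rng=rng)
            cis.append(ci.mean())
        assert np.mean(cis) < 0.25


class TestModularity:
    def test_complete_graph_single_community_zero(self):
        edges = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        q = modularity(edges, 10, partition=[set(range(10))])
        assert q == 0.0

    def test_two_disjoint_cliques_half(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
        q = modularity(edges, 10, partition=[set(range(5)), set(range(5, 10))])
        # brute force: e_cc = 0.5 each, a_c = 0.5 -> Q = 2*(0.5 - 0.25)
        assert np.isclose(q, 0.5, atol=1e-12)

    def test_many_disconnected_modules_near_one(self):
        edges = [(2 * i, 2 * i + 1) for i in range(20)]
        q = modularity(edges, 40)
        assert q > 0.9

    def test_empty_graph_undefined(self):
        assert np.isnan(modularity([], 5))


class TestFullStack:
    def test_metrics_invariant_under_relabeling(self, rng):
        t = np.arange(1.0, 59.0, 2.0)
        trains = [t.copy(), t.copy() + 0.3, np.unique(np.sort(rng.uniform(0, 60, 21))),
                  t.copy() + 0.1, np.unique(np.sort(rng.uniform(0, 60, 18)))]
        sts = SpikeTrainSet([x.copy() for x in trains], 60.0)
        nm = compute_network_metrics(sts, n_surrogates=25, seed=9)
        perm = [3, 0, 4, 1, 2]
        sts_p = SpikeTrainSet([trains[i].copy() for i in perm], 60.0)
        nm_p = compute_network_metrics(sts_p, n_surrogates=25, seed=9)
        assert np.isclose(nm.global_si, nm_p.global_si, atol=0.05)
        # CI follows the permutation (surrogate noise allows small slack)
        assert np.allclose(nm.ci[perm], nm_p.ci, atol=0.15)

    def test_si_monotone_in_generator_sync_level(self):
        from microtrauma.synth import SynthNetworkSpec, generate_spike_trains
        sis = {0.0: [], 0.5: [], 1.0: []}
        for seed in range(8):
            for level in sis:
                spec = SynthNetworkSpec(
                    n_neurons=12, duration=120.0, sync_level=level,
                    jitter_sd=0.02, seed=seed,
                )
                trains, _ = generate_spike_trains(spec)
                nm = compute_network_metrics(trains, n_surrogates=25, seed=seed)
                sis[level].append(nm.global_si)
        means = [np.mean(sis[k]) for k in (0.0, 0.5, 1.0)]
        assert means[0] <= means[1] <= means[2]
        assert means[2] - means[0] > 0.3
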
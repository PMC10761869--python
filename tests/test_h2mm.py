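"""Photon-by-photon HMM: exact oracles, EM behaviour, rates, dwells."""

from itertools import product

import numpy as np
import pytest

from getfret.h2mm import (
    BurstPhotonData,
    H2MMError,
    H2MMModel,
    conformational_rates,
    fit_h2mm,
    icl,
    identify_states,
    k_closing,
    loglikelihood,
    subset_uncertainty,
    viterbi_dwells,
    viterbi_states,
)

CLOCK = 1e-7


def brute_force_ll_and_path(model, colors, deltas):
    """Exhaustive path sum and argmax with exact matrix-power operators."""
    k = model.n_states
    n = len(colors)
    powers = {int(d): np.linalg.matrix_power(model.trans, int(d)) for d in set(deltas[1:])}
    total, best_p, best_path = 0.0, -1.0, None
    for path in product(range(k), repeat=n):
        p = model.pi[path[0]] * model.obs[path[0], colors[0]]
        for t in range(1, n):
            p *= powers[int(deltas[t])][path[t - 1], path[t]] * model.obs[path[t], colors[t]]
        total += p
        if p > best_p:
            best_p, best_path = p, path
    return np.log(total), list(best_path)


def random_instance(rng, k=None, n=None):
    k = k or int(rng.integers(1, 4))
    n = n or int(rng.integers(2, 9))
    model = H2MMModel(
        rng.dirichlet(np.ones(k)),
        rng.dirichlet(np.ones(k) * 2, k),
        rng.dirichlet(np.ones(3), k),
        CLOCK,
    )
    colors = rng.integers(0, 3, n)
    deltas = np.concatenate([[0], rng.integers(1, 30, n - 1)])
    return model, colors, deltas


class TestLikelihoodOracle:
    def test_forward_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            model, colors, deltas = random_instance(rng)
            data = BurstPhotonData.from_sequences([(colors, deltas)], CLOCK)
            ll = loglikelihood(model, data)
            bl, _ = brute_force_ll_and_path(model, colors, deltas)
            assert ll == pytest.approx(bl, rel=1e-10)

    def test_viterbi_matches_brute_force_argmax(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            model, colors, deltas = random_instance(rng, k=2)
            data = BurstPhotonData.from_sequences([(colors, deltas)], CLOCK)
            _, best = brute_force_ll_and_path(model, colors, deltas)
            assert list(viterbi_states(model, data)) == best

    def test_single_state_is_iid_categorical(self):
        rng = np.random.default_rng(44)
        model, colors, deltas = random_instance(rng, k=1, n=50)
        data = BurstPhotonData.from_sequences([(colors, deltas)], CLOCK)
        expect = np.sum(np.log(model.obs[0, colors]))
        assert loglikelihood(model, data) == pytest.approx(expect, rel=1e-12)

    def test_identity_transitions_give_mixture_likelihood(self):
        rng = np.random.default_rng(45)
        k = 3
        model = H2MMModel(
            rng.dirichlet(np.ones(k)), np.eye(k), rng.dirichlet(np.ones(3), k), CLOCK
        )
        seqs = [
            (rng.integers(0, 3, 12), np.concatenate([[0], rng.integers(1, 9, 11)]))
            for _ in range(5)
        ]
        data = BurstPhotonData.from_sequences(seqs, CLOCK)
        expect = sum(
            np.log(np.sum(model.pi * np.prod(model.obs[:, c], axis=1)))
            for c, _ in seqs
        )
        assert loglikelihood(model, data) == pytest.approx(expect, rel=1e-10)


def two_state_data(rng, n_bursts=200, n_photons=40):
    """Bursts drawn from a known 2-state per-tick chain."""
    a = np.array([[0.999, 0.001], [0.002, 0.998]])
    b = np.array([[0.45, 0.05, 0.5], [0.1, 0.4, 0.5]])
    pi = np.array([2 / 3, 1 / 3])
    truth = H2MMModel(pi, a, b, CLOCK)
    seqs = []
    for _ in range(n_bursts):
        s = rng.choice(2, p=pi)
        colors, deltas = [], [0]
        for t in range(n_photons):
            if t:
                d = int(rng.integers(5, 50))
                deltas.append(d)
                a_d = np.linalg.matrix_power(a, d)
                s = rng.choice(2, p=a_d[s])
            colors.append(rng.choice(3, p=b[s]))
        seqs.append((np.array(colors), np.array(deltas)))
    return truth, BurstPhotonData.from_sequences(seqs, CLOCK)


class TestEM:
    def test_monotone_and_improves_from_truth(self):
        rng = np.random.default_rng(50)
        truth, data = two_state_data(rng)
        ll0 = loglikelihood(truth, data)
        fitted, ll = fit_h2mm(data, 2, init=truth, max_iter=100, max_rate=None)
        assert ll >= ll0 - 1e-6  # internal per-iteration assert also active

    def test_k1_mstep_gives_pooled_colour_frequencies(self):
        rng = np.random.default_rng(51)
        _, data = two_state_data(rng, n_bursts=50)
        model, _ = fit_h2mm(data, 1, restarts=1, max_iter=50)
        freq = np.bincount(data.colors, minlength=3) / data.n_photons
        assert np.allclose(model.obs[0], freq, atol=1e-6)

    def test_two_state_parameter_recovery(self):
        rng = np.random.default_rng(52)
        truth, data = two_state_data(rng, n_bursts=400)
        model, _ = fit_h2mm(data, 2, restarts=2, seed=0, max_iter=300, max_rate=None)
        e_true = np.sort(truth.state_e_star())
        e_fit = np.sort(model.state_e_star())
        assert np.allclose(e_fit, e_true, atol=0.03)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(53)
        truth, data = two_state_data(rng, n_bursts=60)
        perm = [1, 0]
        permuted = H2MMModel(
            truth.pi[perm], truth.trans[np.ix_(perm, perm)], truth.obs[perm], CLOCK
        )
        assert loglikelihood(permuted, data) == pytest.approx(
            loglikelihood(truth, data), rel=1e-12
        )
        assert icl(permuted, data) == pytest.approx(icl(truth, data), rel=1e-10)
        # open/closed identified by E* ordering, so K_closing is label-free
        m3 = three_state_model(0.5)
        m3p = H2MMModel(
            m3.pi[[1, 0, 2]], m3.trans[np.ix_([1, 0, 2], [1, 0, 2])],
            m3.obs[[1, 0, 2]], m3.clock_period,
        )
        assert k_closing(m3p) == pytest.approx(k_closing(m3), rel=1e-9)


def three_state_model(k_ratio, k_co=100.0, clock=CLOCK):
    """Open/closed/dark model with k_open->closed = k_ratio * k_co."""
    from scipy.linalg import expm

    q = np.array(
        [[0.0, k_ratio * k_co, 20.0], [k_co, 0.0, 20.0], [200.0, 200.0, 0.0]]
    )
    np.fill_diagonal(q, -q.sum(axis=1))
    a = expm(q * clock)
    b = np.array([[0.4, 0.1, 0.5], [0.1, 0.4, 0.5], [0.93, 0.05, 0.02]])
    return H2MMModel(np.array([0.6, 0.3, 0.1]), a, b, clock)


class TestRatesAndKClosing:
    def test_state_identification_by_emission_signature(self):
        m = three_state_model(0.5)
        o, c, d = identify_states(m)
        assert (o, c, d) == (0, 1, 2)

    @pytest.mark.parametrize("ratio", [1.0, 0.5])
    def test_k_closing_ratio(self, ratio):
        m = three_state_model(ratio)
        assert k_closing(m) == pytest.approx(ratio, rel=1e-6)
        k_oc, k_co = conformational_rates(m)
        assert k_co == pytest.approx(100.0, rel=1e-6)

    def test_zero_closing_rate_rejected(self):
        from scipy.linalg import expm

        q = np.array([[0.0, 50.0], [0.0, 0.0]])
        np.fill_diagonal(q, -q.sum(axis=1))
        m = H2MMModel(
            np.array([0.5, 0.5]), expm(q * CLOCK),
            np.array([[0.4, 0.1, 0.5], [0.1, 0.4, 0.5]]), CLOCK,
        )
        with pytest.raises(H2MMError):
            k_closing(m)


class TestDwells:
    def test_dwell_counts_conserve_burst_counts(self):
        rng = np.random.default_rng(54)
        truth, data = two_state_data(rng, n_bursts=30)
        dwells = viterbi_dwells(truth, data)
        for bi in range(data.n_bursts):
            mine = [d for d in dwells if d.burst_index == bi]
            c = data.colors[data.ptr[bi]:data.ptr[bi + 1]]
            assert sum(d.n_dd for d in mine) == np.sum(c == 0)
            assert sum(d.n_da for d in mine) == np.sum(c == 1)
            assert sum(d.n_aa for d in mine) == np.sum(c == 2)
            for a, b in zip(mine[:-1], mine[1:]):
                assert a.state != b.state

    def test_dwell_es_arithmetic(self):
        d = next(
            d for d in viterbi_dwells(*_single_burst_fixture()) if d.n_dd + d.n_da > 0
        )
        assert d.e_star == pytest.approx(d.n_da / (d.n_dd + d.n_da))


def _single_burst_fixture():
    rng = np.random.default_rng(55)
    truth, data = two_state_data(rng, n_bursts=1, n_photons=30)
    return truth, data


class TestSubsets:
    def test_duplicated_data_zero_variance(self):
        rng = np.random.default_rng(56)
        truth, data = two_state_data(rng, n_bursts=40, n_photons=30)
        doubled = BurstPhotonData(
            np.concatenate([data.colors] * 2),
            np.concatenate([data.deltas] * 2),
            np.concatenate([data.ptr, data.ptr[1:] + data.ptr[-1]]),
            CLOCK,
        )
        res = subset_uncertainty(
            doubled, subset_size=40, k=2, init=truth, restarts=1, max_iter=40,
            max_rate=None,
        )
        assert res["n_subsets"] == 2
        assert res["sigma_K_closing"] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_bursts_rejected(self):
        rng = np.random.default_rng(57)
        _, data = two_state_data(rng, n_bursts=10)
        with pytest.raises(H2MMError, match="more data"):
            subset_uncertainty(data, subset_size=100)
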
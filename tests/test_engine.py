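"""Likelihood engine vs exhaustive partition-sum oracles."""

import itertools
import math

import numpy as np
import pytest

from bass import (
    Dictionary,
    LikelihoodEngine,
    NoiseParams,
    ZeroLikelihoodError,
    hard_label_rho,
    motif_likelihood,
)

from conftest import delta_rho


def brute_force_partition_sum(rho, dic, noise, mtrunc):
    """Exact Z by dynamic programming over all partitionings (oracle)."""
    L = rho.shape[0]
    def qmarg(s, e):
        if e - s > mtrunc:
            return 0.0
        return sum(
            p * motif_likelihood(rho[s:e], m, noise)
            for m, p in zip(dic.motifs, dic.p)
        )
    Z = np.zeros(L + 1)
    Z[0] = 1.0
    for i in range(1, L + 1):
        Z[i] = sum(qmarg(s, i) * Z[s] for s in range(max(0, i - mtrunc), i))
    return Z


def brute_force_counts(rho, dic, noise, mtrunc):
    """Posterior-weighted motif counts by explicit enumeration of windows."""
    L = rho.shape[0]
    Zf = brute_force_partition_sum(rho, dic, noise, mtrunc)
    def qmarg(s, e):
        if e - s > mtrunc:
            return 0.0
        return sum(
            p * motif_likelihood(rho[s:e], m, noise)
            for m, p in zip(dic.motifs, dic.p)
        )
    Zb = np.zeros(L + 1)
    Zb[L] = 1.0
    for s in range(L - 1, -1, -1):
        Zb[s] = sum(qmarg(s, e) * Zb[e] for e in range(s + 1, min(L, s + mtrunc) + 1))
    counts = np.zeros(len(dic))
    for mi, m in enumerate(dic.motifs):
        for s in range(L):
            for e in range(s + 1, min(L, s + mtrunc) + 1):
                q = motif_likelihood(rho[s:e], m, noise)
                counts[mi] += dic.p[mi] * q * Zf[s] * Zb[e] / Zf[L]
    return counts


@pytest.fixture
def small_problem(rng):
    K, L = 3, 10
    rho = rng.random((L, K)) + 0.05
    dic = Dictionary(
        K,
        [(0,), (1,), (2,), (0, 1), (1, 2), (2, 2, 0)],
        np.array([0.2, 0.2, 0.2, 0.15, 0.15, 0.1]),
    )
    return rho, dic


class TestFreeEnergy:
    def test_three_event_explicit_enumeration(self, rng):
        # L=3 has exactly four partitionings: |1|2|3|, |1|23|, |12|3|, |123|.
        K = 2
        rho = rng.random((3, K)) + 0.1
        dic = Dictionary(K, [(0,), (1,), (0, 1), (0, 1, 1)],
                         np.array([0.3, 0.3, 0.2, 0.2]))
        noise = NoiseParams(eps_p=0.0)
        def qm(s, e):
            return sum(
                p * motif_likelihood(rho[s:e], m, noise)
                for m, p in zip(dic.motifs, dic.p)
            )
        Z = (
            qm(0, 1) * qm(1, 2) * qm(2, 3)
            + qm(0, 1) * qm(1, 3)
            + qm(0, 2) * qm(2, 3)
            + qm(0, 3)
        )
        eng = LikelihoodEngine([rho], dic, noise)
        assert eng.free_energy() == pytest.approx(-math.log(Z), rel=1e-12)

    @pytest.mark.parametrize("eps_p", [0.0, 0.2])
    def test_matches_brute_force(self, small_problem, eps_p):
        rho, dic = small_problem
        noise = NoiseParams(eps_p=eps_p, p_d=0.5)
        eng = LikelihoodEngine([rho], dic, noise)
        Z = brute_force_partition_sum(rho, dic, noise, eng.mtrunc)
        assert eng.free_energy() == pytest.approx(-math.log(Z[-1]), rel=1e-10)

    def test_unigram_dictionary_closed_form(self, rng):
        K = 4
        rho = rng.random((30, K)) + 0.01
        dic = Dictionary.unigrams(K, np.array([0.4, 0.3, 0.2, 0.1]))
        eng = LikelihoodEngine([rho], dic, NoiseParams(eps_p=0.0))
        expected = -float(np.log(rho @ dic.p).sum())
        assert eng.free_energy() == pytest.approx(expected, rel=1e-12)

    def test_multiple_sequences_sum(self, small_problem):
        rho, dic = small_problem
        noise = NoiseParams(eps_p=0.0)
        both = LikelihoodEngine([rho, rho[:6]], dic, noise)
        single1 = LikelihoodEngine([rho], dic, noise)
        single2 = LikelihoodEngine([rho[:6]], dic, noise)
        assert both.free_energy() == pytest.approx(
            single1.free_energy() + single2.free_energy(), rel=1e-12
        )

    def test_zero_likelihood_reports_event(self):
        rho = delta_rho([0, 1, 0])
        rho[1] = 0.0  # this event has zero density under every character
        dic = Dictionary.unigrams(3)
        with pytest.raises(ZeroLikelihoodError) as err:
            LikelihoodEngine([rho], dic, NoiseParams()).free_energy()
        assert err.value.event_index == 1


class TestForwardBackward:
    @pytest.mark.parametrize("eps_p", [0.0, 0.15])
    def test_log_likelihood_consistency(self, small_problem, eps_p):
        rho, dic = small_problem
        eng = LikelihoodEngine([rho], dic, NoiseParams(eps_p=eps_p, p_d=0.5))
        for lnZ_f, lnZ_b in eng.log_likelihood_forward_backward():
            assert lnZ_f == pytest.approx(lnZ_b, abs=1e-6)

    @staticmethod
    def _total_mass(dic, n):
        # Exhaustive sum of the unnormalized likelihood over all delta
        # sequences of length n.
        total = 0.0
        for labels in itertools.product(range(dic.K), repeat=n):
            eng = LikelihoodEngine([delta_rho(labels, dic.K)], dic,
                                   NoiseParams(eps_p=0.0))
            total += math.exp(-eng.free_energy())
        return total

    def test_normalization_close_to_unity_for_weak_motifs(self):
        # The unnormalized likelihood sums to ~1 over all sequences of a
        # fixed length when multi-character templates carry little mass
        # (the regime where dropping the normalization constant is exact).
        dic = Dictionary(2, [(0,), (1,), (0, 1)], np.array([0.7, 0.29, 0.01]))
        for n in (7, 8):
            assert 0.99 <= self._total_mass(dic, n) <= 1.0 + 1e-9

    def test_total_mass_follows_renewal_recursion(self):
        # In general the summed mass u(n) obeys the renewal recursion
        # u(n) = sum_m p_m u(n - l_m) and tends to 1 / mean template length;
        # the engine must reproduce it exactly (delta emissions, no noise).
        dic = Dictionary(2, [(0,), (1,), (0, 1)], np.array([0.4, 0.35, 0.25]))
        u = {0: 1.0}
        for n in range(1, 9):
            u[n] = sum(
                p * u[n - len(m)]
                for m, p in zip(dic.motifs, dic.p)
                if n - len(m) >= 0
            )
        for n in (1, 4, 8):
            assert self._total_mass(dic, n) == pytest.approx(u[n], rel=1e-10)
        assert abs(u[8] - 1.0 / dic.mean_length) < 0.01


class TestGradientAndCounts:
    def test_gradient_matches_finite_differences(self, rng):
        K, L = 3, 200
        labels = rng.integers(0, K, size=L)
        rho = rng.random((L, K)) * 0.2
        rho[np.arange(L), labels] += 1.0
        dic = Dictionary(
            K, [(0,), (1,), (2,), (0, 1), (2, 1)],
            np.array([0.25, 0.25, 0.2, 0.15, 0.15]),
        )
        eng = LikelihoodEngine([rho], dic, NoiseParams(eps_p=0.1, p_d=0.5))
        grad, _ = eng.gradient_and_counts()
        h = 1e-6
        for mi in range(len(dic)):
            p_hi, p_lo = dic.p.copy(), dic.p.copy()
            p_hi[mi] += h
            p_lo[mi] -= h
            fd = (eng.free_energy(p_hi) - eng.free_energy(p_lo)) / (2 * h)
            assert grad[mi] == pytest.approx(fd, abs=1e-5)

    def test_unigram_counts_are_label_counts(self):
        labels = [0, 1, 1, 2, 0, 0]
        rho = delta_rho(labels)
        dic = Dictionary.unigrams(3, np.array([0.5, 0.3, 0.2]))
        eng = LikelihoodEngine([rho], dic, NoiseParams())
        _, counts = eng.gradient_and_counts()
        assert counts == pytest.approx([3, 2, 1], abs=1e-12)

    @pytest.mark.parametrize("eps_p", [0.0, 0.2])
    def test_counts_match_enumeration_oracle(self, small_problem, eps_p):
        rho, dic = small_problem
        noise = NoiseParams(eps_p=eps_p, p_d=0.5)
        eng = LikelihoodEngine([rho], dic, noise)
        _, counts = eng.gradient_and_counts()
        oracle = brute_force_counts(rho, dic, noise, eng.mtrunc)
        assert counts == pytest.approx(oracle, abs=1e-9)

    def test_counts_conservation_without_pattern_noise(self, small_problem):
        # With eps_p=0 every partitioning uses exactly L symbols, so the
        # length-weighted expected counts equal L.
        rho, dic = small_problem
        eng = LikelihoodEngine([rho], dic, NoiseParams(eps_p=0.0))
        _, counts = eng.gradient_and_counts()
        weighted = sum(len(m) * c for m, c in zip(dic.motifs, counts))
        assert weighted == pytest.approx(rho.shape[0], rel=1e-10)


class TestWindowTable:
    def test_noiseless_windows_have_motif_length(self, small_problem):
        rho, dic = small_problem
        eng = LikelihoodEngine([rho], dic, NoiseParams(eps_p=0.0))
        table = eng.tables[0]
        for e in range(table.entry_len.shape[0]):
            assert table.entry_len[e] == len(dic.motifs[table.entry_motif[e]])

    def test_zero_prune_threshold_is_noop(self, small_problem):
        rho, dic = small_problem
        noise = NoiseParams(eps_p=0.1, p_d=0.5)
        base = LikelihoodEngine([rho], dic, noise, prune_threshold=0.0)
        same = LikelihoodEngine([rho], dic, noise, prune_threshold=0.0)
        assert base.free_energy() == same.free_energy()

    def test_pruning_changes_free_energy_negligibly(self, rng):
        K, L = 3, 400
        labels = rng.integers(0, K, size=L)
        rho = rng.random((L, K)) * 0.1
        rho[np.arange(L), labels] += 1.0
        dic = Dictionary(
            K, [(0,), (1,), (2,), (0, 1)], np.array([0.3, 0.3, 0.2, 0.2])
        )
        noise = NoiseParams(eps_p=0.1, p_d=0.5)
        full = LikelihoodEngine([rho], dic, noise).free_energy()
        pruned = LikelihoodEngine(
            [rho], dic, noise, prune_threshold=1e-12
        ).free_energy()
        assert abs(full - pruned) / L < 1e-6
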
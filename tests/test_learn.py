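"""Dictionary learning: zeta, MLE, expansion test, pruning, full loop."""

import itertools
import math

import numpy as np
import pytest

from bass import (
    Dictionary,
    LearnConfig,
    LikelihoodEngine,
    NoiseParams,
    hard_label_rho,
    js_distance,
    learn_dictionary,
    mle_probabilities,
    propose_expansions,
    truncate_dictionary,
    zeta,
)
from bass.emissions import EmissionModel

from conftest import delta_rho


class TestZeta:
    def test_printed_example(self):
        # dict {a, b, ab}: zeta(abab) = (p_a p_b + p_ab)^2
        dic = Dictionary(2, [(0,), (1,), (0, 1)], np.array([0.5, 0.3, 0.2]))
        assert zeta((0, 1, 0, 1), dic) == pytest.approx(0.1225, abs=1e-12)

    def test_single_character(self):
        dic = Dictionary(2, [(0,), (1,)], np.array([0.6, 0.4]))
        assert zeta((0,), dic) == pytest.approx(0.6)

    def test_matches_exhaustive_compositions(self, rng):
        # Enumerate all ways of composing the string from dictionary motifs.
        dic = Dictionary(
            2,
            [(0,), (1,), (0, 1), (1, 1, 0)],
            rng.dirichlet(np.ones(4)) + 0.01,
        )
        by_str = list(zip(dic.motifs, dic.p))

        def compositions(s):
            if not s:
                return 1.0
            total = 0.0
            for m, p in by_str:
                if len(m) <= len(s) and s[: len(m)] == m:
                    total += p * compositions(s[len(m) :])
            return total

        for n in range(1, 7):
            for s in itertools.product(range(2), repeat=n):
                assert zeta(s, dic) == pytest.approx(compositions(s), abs=1e-12)


class TestMLE:
    def test_unigram_mle_is_empirical_frequencies(self):
        labels = [0] * 50 + [1] * 30 + [2] * 20
        rho = hard_label_rho(labels, 3)
        eng = LikelihoodEngine([rho], Dictionary.unigrams(3), NoiseParams())
        dic, _ = mle_probabilities(eng)
        assert dic.p == pytest.approx([0.5, 0.3, 0.2], abs=1e-6)

    def test_matches_grid_search_on_two_motif_dictionary(self):
        # Dictionary {a, aa} on a short run of a's: compare the gradient
        # optimum with a 1-D brute-force grid over p_aa.
        labels = [0] * 12
        rho = hard_label_rho(labels, 1, floor=0.0)
        noise = NoiseParams(eps_p=0.0)
        dic0 = Dictionary(1, [(0,), (0, 0)], np.array([0.5, 0.5]))
        eng = LikelihoodEngine([rho], dic0, noise)
        fitted, _ = mle_probabilities(eng)

        grid = np.linspace(1e-4, 1 - 1e-4, 4001)
        best = min(
            grid, key=lambda q: eng.free_energy(np.array([1 - q, q]))
        )
        assert fitted.p[1] == pytest.approx(best, abs=1e-3)

    def test_fixed_point_identity_at_optimum(self, rng):
        K, L = 3, 400
        labels = rng.integers(0, K, size=L)
        rho = rng.random((L, K)) * 0.2
        rho[np.arange(L), labels] += 1.0
        dic = Dictionary(
            K, [(0,), (1,), (2,), (0, 1)], np.array([0.3, 0.3, 0.2, 0.2])
        )
        eng = LikelihoodEngine([rho], dic, NoiseParams(eps_p=0.1, p_d=0.5))
        fitted, _ = mle_probabilities(eng)
        target = fitted.counts / fitted.counts.sum()
        resid = np.max(np.abs(fitted.p - target) / fitted.p)
        assert resid < 1e-4


class TestExpansion:
    def test_planted_motif_is_accepted(self, rng):
        K = 3
        syms = []
        while len(syms) < 4000:
            if rng.random() < 0.3:
                syms.extend([0, 1])
            else:
                syms.append(int(rng.integers(K)))
        rho = hard_label_rho(syms[:4000], K)
        eng = LikelihoodEngine([rho], Dictionary.unigrams(K), NoiseParams())
        mle_probabilities(eng)
        cands = propose_expansions(eng)
        by_motif = {c.motif: c for c in cands}
        assert (0, 1) in by_motif
        assert by_motif[(0, 1)].p_value < 1e-10
        assert by_motif[(0, 1)].expected_counts > by_motif[(0, 1)].null_counts

    def test_iid_data_rarely_accepts(self):
        accept = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rho = hard_label_rho(rng.integers(0, 3, size=2000), 3)
            eng = LikelihoodEngine([rho], Dictionary.unigrams(3), NoiseParams())
            mle_probabilities(eng)
            if propose_expansions(eng):
                accept += 1
        assert accept <= 1

    def test_acceptance_rate_near_test_level(self):
        # On iid two-character data the per-pair acceptance rate at level
        # alpha should be near alpha (Poisson LR calibration).
        alpha = 0.05
        config = LearnConfig(p_expand=alpha)
        hits = trials = 0
        for seed in range(120):
            rng = np.random.default_rng(10_000 + seed)
            rho = hard_label_rho(rng.integers(0, 2, size=400), 2)
            eng = LikelihoodEngine([rho], Dictionary.unigrams(2), NoiseParams())
            mle_probabilities(eng)
            hits += len(propose_expansions(eng, config))
            trials += 4  # ordered pairs of 2 unigrams
        rate = hits / trials
        se = math.sqrt(alpha * (1 - alpha) / trials)
        assert rate < alpha + 4 * se + 0.01

    def test_permutation_equivariance(self, rng):
        # Relabeling the alphabet must permute the accepted candidates.
        syms = []
        while len(syms) < 1500:
            if rng.random() < 0.35:
                syms.extend([0, 2])
            else:
                syms.append(int(rng.integers(3)))
        syms = syms[:1500]
        perm = {0: 1, 1: 2, 2: 0}
        config = LearnConfig(p_expand=1e-3)

        def accepted(labels):
            rho = hard_label_rho(labels, 3)
            eng = LikelihoodEngine([rho], Dictionary.unigrams(3), NoiseParams())
            mle_probabilities(eng)
            return {c.motif for c in propose_expansions(eng, config)}

        base = accepted(syms)
        permuted = accepted([perm[s] for s in syms])
        assert permuted == {tuple(perm[c] for c in m) for m in base}


class TestJSDistance:
    def test_identical_motifs_have_zero_distance(self, rng):
        noise = NoiseParams(eps_p=0.2, p_d=0.5)
        d = js_distance((0, 1), (0, 1), noise, n_samples=200, rng=rng)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_different_lengths_without_noise_distance_one(self, rng):
        noise = NoiseParams(eps_p=0.0)
        d = js_distance((0, 1), (0, 1, 1), noise, n_samples=200, rng=rng)
        assert d == pytest.approx(1.0)

    def test_matches_quadrature_for_gaussian_emissions(self, rng):
        # Two single-character motifs with overlapping 1-D Gaussian emissions:
        # JS distance from Monte Carlo vs numerical integration.
        mu = 1.5
        model = EmissionModel(
            means=np.array([[0.0], [mu]]),
            covariances=np.array([[[1.0]], [[1.0]]]),
            weights=[np.array([0.5, 0.5])],
        )
        noise = NoiseParams(eps_p=0.0)
        d_mc = js_distance((0,), (1,), noise, emission_model=model,
                           n_samples=4000, rng=rng)

        xs = np.linspace(-8, 8 + mu, 4001)
        q1 = np.exp(-0.5 * xs**2) / np.sqrt(2 * np.pi)
        q2 = np.exp(-0.5 * (xs - mu) ** 2) / np.sqrt(2 * np.pi)
        qb = 0.5 * (q1 + q2)
        kl1 = np.trapezoid(q1 * np.log(q1 / qb), xs)
        kl2 = np.trapezoid(q2 * np.log(q2 / qb), xs)
        d_quad = (kl1 + kl2) / (2 * math.log(2))
        assert d_mc == pytest.approx(d_quad, abs=0.02)


class TestTruncation:
    def test_low_count_motifs_removed_unigrams_kept(self, rng):
        labels = rng.integers(0, 3, size=500)
        rho = hard_label_rho(labels, 3)
        dic = Dictionary(
            3, [(0,), (1,), (2,), (0, 1, 2, 0, 1)],
            np.array([0.33, 0.33, 0.33, 0.01]),
        )
        eng = LikelihoodEngine([rho], dic, NoiseParams())
        fitted, _ = mle_probabilities(eng)
        eng.rebuild_probabilities(fitted)
        pruned, removed = truncate_dictionary(eng)
        assert (0, 1, 2, 0, 1) in removed
        assert all((c,) in pruned for c in range(3))

    def test_similar_motifs_collapse_under_pattern_noise(self, rng):
        # 'aab' and 'ab' are one deletion apart; with heavy pattern noise
        # their generated-data distributions overlap below J_thr.
        noise = NoiseParams(eps_p=0.45, p_d=0.9)
        labels = rng.integers(0, 2, size=300)
        rho = hard_label_rho(labels, 2)
        dic = Dictionary(
            2, [(0,), (1,), (0, 0, 1), (0, 1)],
            np.array([0.3, 0.3, 0.2, 0.2]),
        )
        eng = LikelihoodEngine([rho], dic, noise)
        fitted, _ = mle_probabilities(eng)
        eng.rebuild_probabilities(fitted)
        d = js_distance((0, 0, 1), (0, 1), noise, n_samples=3000,
                        rng=np.random.default_rng(0))
        pruned, removed = truncate_dictionary(
            eng, LearnConfig(J_thr=0.5, min_count=0.0), np.random.default_rng(0)
        )
        assert d < 0.5
        assert len(pruned.multi) == 1  # one of the two collapsed into the other


class TestHyperparameterSelection:
    @staticmethod
    def _noisy_planted_data(rng, eps_p, n_seqs=8, length=400):
        from bass.learn import NoiseParams
        from bass.pattern import sample_instantiation

        gen_noise = NoiseParams(eps_p=eps_p, p_d=0.5)
        motifs = [(0, 1, 2, 0), (2, 2, 1), (1, 0, 0, 1)]
        data = []
        for _ in range(n_seqs):
            syms = []
            while len(syms) < length:
                if rng.random() < 0.5:
                    m = motifs[int(rng.integers(3))]
                    syms.extend(sample_instantiation(m, gen_noise, rng))
                else:
                    syms.append(int(rng.integers(3)))
            data.append(hard_label_rho(syms[:length], 3))
        return data

    def test_held_out_f_prefers_nonzero_eps_p_on_noisy_data(self):
        from bass import select_hyperparameters

        rng = np.random.default_rng(5)
        data = self._noisy_planted_data(rng, eps_p=0.15)
        grid = [(0.0, 0.5, 0.15), (0.1, 0.5, 0.15), (0.2, 0.5, 0.15)]
        best, results = select_hyperparameters(
            data, 3, grid, config=LearnConfig(seed=0), seed=2
        )
        assert best[0] > 0.0
        assert min(results[g] for g in grid[1:]) < results[grid[0]]

    def test_single_point_grid_degenerates(self, rng):
        from bass import select_hyperparameters

        data = [hard_label_rho(rng.integers(0, 3, size=300), 3)
                for _ in range(4)]
        grid = [(0.0, 0.5, 0.15)]
        best, results = select_hyperparameters(
            data, 3, grid, config=LearnConfig(seed=0), seed=1
        )
        assert best == grid[0]
        assert set(results) == set(grid)

    def test_empty_grid_rejected(self, rng):
        from bass import select_hyperparameters

        data = [hard_label_rho(rng.integers(0, 3, size=50), 3)]
        with pytest.raises(ValueError):
            select_hyperparameters(data, 3, [], config=LearnConfig())


class TestLearnLoop:
    def test_pure_background_returns_unigrams(self, rng):
        rho = hard_label_rho(rng.integers(0, 4, size=3000), 4)
        state = learn_dictionary([rho], 4, NoiseParams(), LearnConfig(seed=0))
        assert state.dic.multi == []
        assert state.converged

    def test_planted_motif_recovered_and_trace_decreases(self, rng):
        syms = []
        while len(syms) < 5000:
            if rng.random() < 0.35:
                syms.extend([0, 1, 2])
            else:
                syms.append(int(rng.integers(3)))
        rho = hard_label_rho(syms[:5000], 3)
        state = learn_dictionary([rho], 3, NoiseParams(), LearnConfig(seed=0))
        assert (0, 1, 2) in state.dic.motifs or (
            (0, 1) in state.dic.motifs and (1, 2) in state.dic.motifs
        )
        diffs = np.diff(state.F_trace)
        assert np.all(diffs <= 1e-6)

    def test_calibration_under_null_over_seeds(self):
        # On iid data at most ~10% of runs should produce any motif.
        runs_with_motifs = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rho = hard_label_rho(rng.integers(0, 3, size=2000), 3)
            state = learn_dictionary([rho], 3, NoiseParams(),
                                     LearnConfig(seed=seed))
            runs_with_motifs += bool(state.dic.multi)
        assert runs_with_motifs <= 2
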
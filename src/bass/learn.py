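"""The outer BASS loop: grow, refit and prune a motif dictionary.

Starting from the K single characters, each iteration

1. proposes every ordered concatenation of two dictionary templates and keeps
   those whose expected count exceeds the chance-concatenation prediction
   ``N_bar * zeta(mm')`` by a significant margin (one-sided likelihood-ratio
   test at ``p < p_expand``),
2. re-estimates all template probabilities by maximum likelihood (L-BFGS-B on
   softmax-reparameterised probabilities, polished by the EM fixed point
   ``p_m = <N_m> / N_bar``), and
3. prunes near-duplicate motifs (Jensen-Shannon distance between their
   generated-data distributions below ``J_thr``; only meaningful when pattern
   noise is present) and motifs with expected counts below ``min_count``.

The loop stops when the free energy per symbol changes by less than 0.1%
(relative) for two consecutive iterations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .engine import Dictionary, LikelihoodEngine, ZeroLikelihoodError, as_rho_list
from .pattern import Motif, NoiseParams, motif_likelihood, sample_instantiation


# --------------------------------------------------------------------- config
@dataclass
class LearnConfig:
    """Tunable knobs of the learning loop (defaults follow the method)."""

    p_expand: float = 1e-3  # LR-test threshold for adding a concatenation
    min_count: float = 5.0  # motifs with <N_m> below this are discarded
    J_thr: float = 0.15  # JS-distance threshold for near-duplicate pruning
    conv_rel: float = 1e-3  # stop when relative dF < this twice in a row
    max_iter: int = 30
    prune_threshold: float = 0.0  # window-table pruning (absolute)
    js_samples: int = 2000  # Monte Carlo sample size for JS distances
    seed: int = 0
    mle_maxiter: int = 1000
    mle_gtol: float = 1e-5
    fixed_point_tol: float = 1e-5  # relative residual of p_m = <N_m>/N_bar
    drop_rare_unigrams_at_end: bool = True
    lr_test: str = "poisson"  # distributional form of the expansion test
    emission_model: object | None = None  # used for JS sampling when given


@dataclass
class CandidateMotif:
    """A proposed concatenation m·m' with its over-representation evidence."""

    motif: Motif
    pair: Tuple[Motif, Motif]
    expected_counts: float  # <N_{mm'}> via the gradient machinery
    null_prob: float  # zeta(mm'): chance-concatenation probability
    null_counts: float  # N_bar * zeta(mm')
    p_value: float


@dataclass
class LearnState:
    """Result of :func:`learn_dictionary`."""

    dic: Dictionary
    F_trace: List[float]  # free energy per symbol after each iteration
    iteration: int
    converged: bool
    n_symbols: int


# ----------------------------------------------------------------------- zeta
def zeta(motif: Motif, dic: Dictionary) -> float:
    """Probability of composing ``motif`` exactly from dictionary templates.

    Linear prefix recursion: z_k = sum over templates t matching the suffix
    of the first k characters of p_t * z_{k-|t|}, with z_0 = 1.  This is the
    null model for dictionary expansion: how often the string would occur by
    chance concatenation of existing templates.
    """
    by_len: Dict[int, Dict[Motif, float]] = {}
    for m, pm in zip(dic.motifs, dic.p):
        by_len.setdefault(len(m), {})[m] = float(pm)
    n = len(motif)
    z = np.zeros(n + 1)
    z[0] = 1.0
    for k in range(1, n + 1):
        acc = 0.0
        for l, table in by_len.items():
            if l <= k:
                pm = table.get(motif[k - l : k])
                if pm is not None:
                    acc += pm * z[k - l]
        z[k] = acc
    return float(z[n])


# ------------------------------------------------------------------------ MLE
def _softmax_neg(beta: np.ndarray) -> np.ndarray:
    w = np.exp(-(beta - beta.min()))
    return w / w.sum()


def mle_probabilities(
    engine: LikelihoodEngine,
    config: LearnConfig | None = None,
) -> Tuple[Dictionary, float]:
    """Maximum-likelihood template probabilities for the engine's dictionary.

    Optimizes ``F`` over the softmax reparameterisation ``p_m = e^{-beta_m} /
    sum e^{-beta}`` (one beta pinned to zero) with L-BFGS-B, then polishes
    with the EM fixed point ``p_m <- <N_m> / N_bar`` until the relative
    residual drops below ``config.fixed_point_tol``.  Returns the updated
    dictionary (with expected counts attached) and the final free energy.
    """
    config = config or LearnConfig()
    dic = engine.dic
    p0 = np.clip(dic.p / dic.p.sum(), 1e-12, None)
    beta0 = -np.log(p0)
    beta0 -= beta0[0]

    def objective(beta_free: np.ndarray):
        beta = np.concatenate(([0.0], beta_free))
        p = _softmax_neg(beta)
        res = engine.evaluate(p)
        grad_beta = res.counts - p * res.n_bar
        return res.F, grad_beta[1:]

    res = optimize.minimize(
        objective,
        beta0[1:],
        jac=True,
        method="L-BFGS-B",
        bounds=[(-60.0, 60.0)] * (len(dic) - 1),
        options={"maxiter": config.mle_maxiter, "gtol": config.mle_gtol,
                 "ftol": 1e-14},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        warnings.warn(f"L-BFGS-B did not converge cleanly: {res.message}")
    beta = np.concatenate(([0.0], res.x))
    p = _softmax_neg(beta)

    # EM polish: p <- <N>/N_bar is the exact M-step for template probabilities.
    ev = engine.evaluate(p)
    F = ev.F
    for _ in range(200):
        target = ev.counts / ev.n_bar
        resid = np.max(np.abs(p - target) / np.maximum(p, 1e-300))
        if resid < config.fixed_point_tol:
            break
        p = np.clip(target, 1e-300, None)
        ev = engine.evaluate(p)
        F = ev.F

    new_dic = Dictionary(dic.K, list(dic.motifs), np.clip(p, 1e-300, None),
                         counts=ev.counts)
    engine.rebuild_probabilities(new_dic)
    return new_dic, F


# ------------------------------------------------------------------ expansion
def _lr_pvalue_poisson(observed: float, expected: float) -> float:
    """One-sided Poisson likelihood-ratio p-value for over-representation."""
    if not (observed > expected) or expected <= 0:
        return 1.0
    stat = 2.0 * (observed * math.log(observed / expected) - (observed - expected))
    return 0.5 * float(stats.chi2.sf(stat, df=1))


def propose_expansions(
    engine: LikelihoodEngine,
    config: LearnConfig | None = None,
) -> List[CandidateMotif]:
    """Candidate concatenations m·m' that beat the chance-composition null.

    For every ordered pair of dictionary templates the expected count of the
    concatenation is ``<N_{mm'}> = zeta(mm') * sum_windows G * Q^{mm'}``; it
    is compared with the null prediction ``N_bar * zeta(mm')`` by a one-sided
    likelihood-ratio test.  Candidates with ``p < p_expand`` (and observed
    above expected) are returned, duplicates merged to their best p-value.
    """
    config = config or LearnConfig()
    dic = engine.dic
    ev = engine.evaluate()
    n_bar = ev.n_bar
    if n_bar <= 0:
        raise ValueError("degenerate model: expected number of templates is 0")
    PC = engine.pair_counts()
    out: Dict[Motif, CandidateMotif] = {}
    for i, m1 in enumerate(dic.motifs):
        for j, m2 in enumerate(dic.motifs):
            concat = m1 + m2
            if concat in dic:
                continue
            z = zeta(concat, dic)
            observed = z * PC[i, j]
            expected = n_bar * z
            pval = _lr_pvalue_poisson(observed, expected)
            if pval < config.p_expand:
                cand = CandidateMotif(
                    motif=concat,
                    pair=(m1, m2),
                    expected_counts=observed,
                    null_prob=z,
                    null_counts=expected,
                    p_value=pval,
                )
                prev = out.get(concat)
                if prev is None or cand.p_value < prev.p_value:
                    out[concat] = cand
    return sorted(out.values(), key=lambda c: (c.p_value, c.motif))


# ----------------------------------------------------------------- JS pruning
def js_distance(
    m1: Motif,
    m2: Motif,
    noise: NoiseParams,
    emission_model=None,
    n_samples: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Jensen-Shannon distance between the data distributions of two motifs.

    Monte Carlo estimate of ``[KL(Q1 || Qbar) + KL(Q2 || Qbar)] / (2 ln 2)``
    with ``Qbar = (Q1 + Q2) / 2``, sampling instantiations (and, when an
    emission model is given, continuous observations) from each motif.  With
    no emission model, samples are the discrete instantiation strings
    themselves (delta emissions).  Bounded to [0, 1].
    """
    rng = rng or np.random.default_rng()

    def sample_and_score(m_from: Motif) -> float:
        total = 0.0
        for _ in range(n_samples):
            inst = sample_instantiation(m_from, noise, rng)
            if emission_model is None:
                rho = np.zeros((len(inst), max(max(m1), max(m2), max(inst, default=0)) + 1))
                for t, c in enumerate(inst):
                    rho[t, c] = 1.0
            else:
                y = emission_model.sample_sequence(inst, rng)
                rho = emission_model.densities(y)
            q_own = motif_likelihood(rho, m_from, noise)
            q1 = q_own if m_from is m1 else motif_likelihood(rho, m1, noise)
            q2 = q_own if m_from is m2 else motif_likelihood(rho, m2, noise)
            qbar = 0.5 * (q1 + q2)
            if q_own <= 0.0 or qbar <= 0.0:
                continue  # measure-zero sample under its own model: skip
            total += math.log(q_own / qbar)
        return total / n_samples

    d = (sample_and_score(m1) + sample_and_score(m2)) / (2.0 * math.log(2.0))
    return float(min(max(d, 0.0), 1.0))


def _js_clusters(
    motifs: List[Motif],
    noise: NoiseParams,
    J_thr: float,
    emission_model,
    n_samples: int,
    rng: np.random.Generator,
    max_len_diff: int = 2,
) -> List[List[int]]:
    """Union-find clusters of motifs with pairwise JS distance < J_thr."""
    n = len(motifs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(len(motifs[i]) - len(motifs[j])) > max_len_diff:
                continue
            if find(i) == find(j):
                continue
            d = js_distance(motifs[i], motifs[j], noise, emission_model,
                            n_samples, rng)
            if d < J_thr:
                parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def truncate_dictionary(
    engine: LikelihoodEngine,
    config: LearnConfig | None = None,
    rng: np.random.Generator | None = None,
    final: bool = False,
) -> Tuple[Dictionary, List[Motif]]:
    """Prune near-duplicate and rare motifs from the engine's dictionary.

    Near-duplicate pruning (JS distance < ``J_thr``) is only performed when
    pattern noise is present — without it, distinct motifs generate disjoint
    data and the distance is always 1.  Probabilities of removed cluster
    members are added to the representative (the highest re-weighted
    probability; ties broken toward shorter, then lexicographically smaller
    motifs).  Motifs with expected counts below ``min_count`` are discarded;
    single characters are exempt unless ``final`` is set.  Returns the pruned
    dictionary and the list of removed motifs.
    """
    config = config or LearnConfig()
    rng = rng or np.random.default_rng(config.seed)
    dic = engine.dic
    counts = dic.counts
    if counts is None:
        counts = engine.evaluate().counts
    keep = np.ones(len(dic), dtype=bool)
    p = dic.p.copy()
    removed: List[Motif] = []

    if engine.noise.eps_p > 0 and config.J_thr > 0:
        multi_idx = [i for i, m in enumerate(dic.motifs) if len(m) > 1]
        clusters = _js_clusters(
            [dic.motifs[i] for i in multi_idx],
            engine.noise,
            config.J_thr,
            config.emission_model,
            config.js_samples,
            rng,
        )
        for group in clusters:
            if len(group) < 2:
                continue
            idx = [multi_idx[g] for g in group]
            total = float(p[idx].sum())
            # representative: highest re-weighted probability, then shortest,
            # then lexicographic
            rep = min(idx, key=lambda i: (-p[i], len(dic.motifs[i]), dic.motifs[i]))
            for i in idx:
                if i != rep:
                    keep[i] = False
                    removed.append(dic.motifs[i])
            p[rep] = total

    for i, m in enumerate(dic.motifs):
        if not keep[i]:
            continue
        if len(m) == 1 and not final:
            continue
        if counts[i] < config.min_count:
            keep[i] = False
            removed.append(m)

    if not removed:
        return dic, []
    motifs = [m for i, m in enumerate(dic.motifs) if keep[i]]
    new_p = p[keep]
    new_dic = Dictionary(dic.K, motifs, new_p / new_p.sum())
    return new_dic, removed


# ------------------------------------------------------------------ main loop
def learn_dictionary(
    data,
    K: int,
    noise: NoiseParams,
    config: LearnConfig | None = None,
) -> LearnState:
    """Learn a motif dictionary from emission-density sequences.

    ``data`` is a list of ``(L, K)`` arrays (or objects with a ``rho``
    attribute).  Returns a :class:`LearnState` with the converged dictionary
    (expected counts attached), the free-energy-per-symbol trace and
    convergence information.
    """
    config = config or LearnConfig()
    rng = np.random.default_rng(config.seed)
    rho_list = as_rho_list(data)
    if any(r.shape[1] != K for r in rho_list):
        raise ValueError("all sequences must have K density columns")

    dic = Dictionary.unigrams(K)
    engine = LikelihoodEngine(rho_list, dic, noise,
                              prune_threshold=config.prune_threshold)
    dic, F = mle_probabilities(engine, config)
    n = engine.n_symbols
    F_trace = [F / n]
    converged = False
    iteration = 0

    for iteration in range(1, config.max_iter + 1):
        changed = False
        cands = propose_expansions(engine, config)
        new = [c for c in cands if c.motif not in dic]
        if new:
            changed = True
            n_bar = float(dic.counts.sum())
            motifs = list(dic.motifs) + [c.motif for c in new]
            p_new = np.array([max(c.expected_counts, 1e-3) / max(n_bar, 1.0)
                              for c in new])
            p = np.concatenate([dic.p, p_new])
            dic = Dictionary(dic.K, motifs, p / p.sum())
            engine.rebuild(dic)
            dic, F = mle_probabilities(engine, config)

        pruned_dic, removed = truncate_dictionary(engine, config, rng)
        if removed:
            changed = True
            dic = pruned_dic
            engine.rebuild(dic)
            dic, F = mle_probabilities(engine, config)

        F_trace.append(F / n)
        if F_trace[-1] > F_trace[-2] + 1e-6:
            warnings.warn(
                f"free energy per symbol increased at iteration {iteration}: "
                f"{F_trace[-2]:.6f} -> {F_trace[-1]:.6f}"
            )
        if len(F_trace) >= 3:
            d1 = abs(F_trace[-1] - F_trace[-2]) / max(abs(F_trace[-2]), 1e-12)
            d2 = abs(F_trace[-2] - F_trace[-3]) / max(abs(F_trace[-3]), 1e-12)
            if d1 < config.conv_rel and d2 < config.conv_rel:
                converged = True
                break
        if not changed:
            converged = True
            break

    if config.drop_rare_unigrams_at_end:
        final_dic, removed = truncate_dictionary(engine, config, rng, final=True)
        if removed:
            try:
                engine.rebuild(final_dic)
                final_dic, F = mle_probabilities(engine, config)
                F_trace.append(F / n)
                dic = final_dic
            except ZeroLikelihoodError:
                # some symbols are only explainable by a rare unigram: keep it
                engine.rebuild(dic)

    return LearnState(dic=dic, F_trace=F_trace, iteration=iteration,
                      converged=converged, n_symbols=n)


# -------------------------------------------------- hyperparameter selection
def select_hyperparameters(
    data,
    K: int,
    grid: Sequence[Tuple[float, float, float]],
    config: LearnConfig | None = None,
    held_out_fraction: float = 0.25,
    n_trials: int = 1,
    seed: int = 0,
):
    """Pick (eps_p, p_d, J_thr) by free energy per symbol on held-out data.

    For each grid triple a dictionary is learned on a training split and the
    free energy per symbol is evaluated on the held-out split (averaged over
    ``n_trials`` random splits).  Sequences are the split unit; a single long
    sequence is split into contiguous blocks.  Returns ``(best_triple,
    results)`` where results maps each triple to its mean held-out F.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    config = config or LearnConfig()
    rho_list = as_rho_list(data)
    results: Dict[Tuple[float, float, float], float] = {}
    for eps_p, p_d, J_thr in grid:
        noise = NoiseParams(eps_p=eps_p, p_d=p_d)
        trial_F = []
        for t in range(n_trials):
            rng = np.random.default_rng((seed, t))
            train, test = _split_held_out(rho_list, held_out_fraction, rng)
            cfg = replace(config, J_thr=J_thr, seed=int(rng.integers(2**31)))
            state = learn_dictionary(train, K, noise, cfg)
            test_engine = LikelihoodEngine(test, state.dic, noise,
                                           prune_threshold=config.prune_threshold)
            trial_F.append(test_engine.free_energy_per_symbol())
        results[(eps_p, p_d, J_thr)] = float(np.mean(trial_F))
    best = min(results, key=results.get)
    return best, results


def _split_held_out(rho_list, fraction: float, rng: np.random.Generator):
    if len(rho_list) == 1:
        rho = rho_list[0]
        cut = int(round(rho.shape[0] * (1 - fraction)))
        return [rho[:cut]], [rho[cut:]]
    idx = rng.permutation(len(rho_list))
    n_test = max(1, int(round(len(rho_list) * fraction)))
    test = [rho_list[i] for i in idx[:n_test]]
    train = [rho_list[i] for i in idx[n_test:]]
    return train, test
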
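"""Comparative motif-usage analysis between two behavioural conditions.

Dictionaries learned separately in two conditions (e.g. neutral vs aversive
environment) are merged; template probabilities are re-fit per condition on
the union, and each motif's expected counts are compared with a one-sided
likelihood-ratio test on the occurrence rates.  The working score is
``-log10 p``.  The decision threshold is calibrated on split halves of a
homogeneous dataset at a target false-positive rate, and flagged motifs must
clear the threshold in every one of ``n_subsamples`` random 80% subsamples of
the treatment data (a consistency filter against effects driven by a few
individuals).  A first-order Markov chain on hard labels provides a baseline
expectation for raw motif occurrence counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .engine import Dictionary, LikelihoodEngine, as_rho_list
from .learn import LearnConfig, learn_dictionary, mle_probabilities
from .pattern import Motif, NoiseParams
from .segment import Segmentation, viterbi_segment


@dataclass
class MotifComparison:
    """Comparison record for one motif of the union dictionary."""

    motif: Motif
    counts_A: float
    counts_B: float
    neg_log10_p: float  # over-representation in B (one-sided)
    flagged: bool
    pct_individuals: float = float("nan")  # % of B sequences using the motif
    coverage: float = float("nan")  # fraction of B symbols tiled by it


@dataclass
class MarkovBaseline:
    """First-order Markov chain fit plus per-motif expected counts."""

    initial: np.ndarray  # empirical character distribution
    transition: np.ndarray  # (K, K) row-stochastic
    expected: Dict[Motif, float]
    observed: Dict[Motif, float]
    p_values: Dict[Motif, float]  # one-sided LR p for over-representation


def _one_sided_lr_rate_p(nA: float, nB: float, expA: float, expB: float) -> float:
    """One-sided LR p-value that the rate in B exceeds the rate in A.

    Poisson model with per-dataset exposures ``expA``/``expB`` (total expected
    number of templates); the null pools the two rates.
    """
    if expA <= 0 or expB <= 0:
        return 1.0
    rateA, rateB = nA / expA, nB / expB
    if not (rateB > rateA):
        return 1.0
    pooled = (nA + nB) / (expA + expB)
    stat = 0.0
    for n, e in ((nA, expA), (nB, expB)):
        lam = n / e if n > 0 else 0.0
        if n > 0:
            stat += 2.0 * (n * math.log(lam / pooled) - (lam - pooled) * e)
        else:
            stat += 2.0 * pooled * e
    return 0.5 * float(stats.chi2.sf(stat, df=1))


def _union_dictionary(dic_A: Dictionary, dic_B: Dictionary) -> Dictionary:
    if dic_A.K != dic_B.K:
        raise ValueError("dictionaries have different alphabet sizes")
    motifs = list(dict.fromkeys(list(dic_A.motifs) + list(dic_B.motifs)))
    for c in range(dic_A.K):
        if (c,) not in motifs:
            motifs.append((c,))
    p = np.zeros(len(motifs))
    for dic in (dic_A, dic_B):
        for m, pm in zip(dic.motifs, dic.p):
            p[motifs.index(m)] += 0.5 * pm
    p = np.clip(p, 1e-9, None)
    return Dictionary(K=dic_A.K, motifs=motifs, p=p / p.sum())


def _fit_counts(
    rho_list, dic: Dictionary, noise: NoiseParams, config: LearnConfig
) -> Tuple[np.ndarray, float]:
    engine = LikelihoodEngine(rho_list, dic, noise,
                              prune_threshold=config.prune_threshold)
    fitted, _F = mle_probabilities(engine, config)
    return fitted.counts, float(fitted.counts.sum())


def _scores(
    counts_A: np.ndarray,
    nbar_A: float,
    counts_B: np.ndarray,
    nbar_B: float,
) -> np.ndarray:
    out = np.empty(len(counts_A))
    for i in range(len(counts_A)):
        p = _one_sided_lr_rate_p(counts_A[i], counts_B[i], nbar_A, nbar_B)
        out[i] = -math.log10(max(p, 1e-300))
    return out


def compare_conditions(
    data_A,
    data_B,
    K: int,
    noise: NoiseParams,
    threshold: float = 15.0,
    n_subsamples: int = 10,
    subsample_frac: float = 0.8,
    dic_A: Dictionary | None = None,
    dic_B: Dictionary | None = None,
    config: LearnConfig | None = None,
    decode: bool = False,
    seed: int = 0,
) -> List[MotifComparison]:
    """Find motifs over-represented in condition B relative to condition A.

    Dictionaries are learned per condition (unless supplied), merged, and
    probabilities re-optimized per condition over the union.  A motif is
    flagged iff its ``-log10 p`` clears ``threshold`` in *all*
    ``n_subsamples`` random subsamples of B at ``subsample_frac`` of its
    sequences.  With ``decode`` the per-motif prevalence (% of B sequences
    with a decoded instance) and coverage (fraction of B symbols tiled) are
    also reported.
    """
    config = config or LearnConfig()
    rng = np.random.default_rng(seed)
    rho_A, rho_B = as_rho_list(data_A), as_rho_list(data_B)
    if dic_A is None:
        dic_A = learn_dictionary(rho_A, K, noise, config).dic
    if dic_B is None:
        dic_B = learn_dictionary(rho_B, K, noise, config).dic
    union = _union_dictionary(dic_A, dic_B)

    counts_A, nbar_A = _fit_counts(rho_A, union, noise, config)
    counts_B, nbar_B = _fit_counts(rho_B, union, noise, config)
    full_scores = _scores(counts_A, nbar_A, counts_B, nbar_B)

    passes = np.ones(len(union), dtype=bool)
    if n_subsamples > 0:
        if len(rho_B) < 2:
            warnings.warn("single-sequence condition B: subsampling by blocks")
            blocks = np.array_split(rho_B[0], 10)
            rho_B_units = [b for b in blocks if b.shape[0] > 0]
        else:
            rho_B_units = rho_B
        n_take = max(1, int(round(subsample_frac * len(rho_B_units))))
        for _ in range(n_subsamples):
            take = rng.choice(len(rho_B_units), size=n_take, replace=False)
            sub = [rho_B_units[i] for i in take]
            c_sub, nbar_sub = _fit_counts(sub, union, noise, config)
            passes &= _scores(counts_A, nbar_A, c_sub, nbar_sub) >= threshold
    flagged = passes & (full_scores >= threshold)

    prevalence = np.full(len(union), float("nan"))
    coverage = np.full(len(union), float("nan"))
    if decode:
        segs = [viterbi_segment(r, union_with_counts(union, counts_B), noise)
                for r in rho_B]
        total = sum(r.shape[0] for r in rho_B)
        for i, m in enumerate(union.motifs):
            cov, prev = motif_coverage_and_prevalence(segs, m, total)
            coverage[i] = cov
            prevalence[i] = prev

    return [
        MotifComparison(
            motif=m,
            counts_A=float(counts_A[i]),
            counts_B=float(counts_B[i]),
            neg_log10_p=float(full_scores[i]),
            flagged=bool(flagged[i]),
            pct_individuals=float(prevalence[i]),
            coverage=float(coverage[i]),
        )
        for i, m in enumerate(union.motifs)
    ]


def union_with_counts(union: Dictionary, counts: np.ndarray) -> Dictionary:
    """Dictionary with probabilities proportional to fitted counts."""
    p = np.clip(counts, 1e-9, None)
    return Dictionary(union.K, list(union.motifs), p / p.sum())


def calibrate_threshold(
    data,
    K: int,
    noise: NoiseParams,
    target_fpr: float = 0.10,
    n_splits: int = 1,
    dictionary: Dictionary | None = None,
    config: LearnConfig | None = None,
    seed: int = 0,
) -> float:
    """Score threshold with the target false-positive rate on null splits.

    The dataset is split in half by sequence (both halves come from the same
    condition, so every above-threshold motif is a false positive); motif
    scores are computed exactly as in :func:`compare_conditions` and the
    ``1 - target_fpr`` quantile of the pooled multi-character motif scores is
    returned.  A dictionary may be supplied to avoid re-learning.
    """
    config = config or LearnConfig()
    rng = np.random.default_rng(seed)
    rho_list = as_rho_list(data)
    if len(rho_list) < 2:
        raise ValueError("need at least two sequences to split in half")
    if dictionary is None:
        dictionary = learn_dictionary(rho_list, K, noise, config).dic
    scores = null_split_scores(rho_list, dictionary, noise, config, rng, n_splits)
    if scores.size < 5:
        warnings.warn("few motifs available; calibrated threshold is unstable")
    if scores.size == 0:
        return float("inf")
    return float(np.quantile(scores, 1.0 - target_fpr))


def null_split_scores(
    rho_list,
    dictionary: Dictionary,
    noise: NoiseParams,
    config: LearnConfig,
    rng: np.random.Generator,
    n_splits: int = 1,
) -> np.ndarray:
    """Pooled multi-character motif scores over random half splits."""
    multi_mask = np.array([len(m) > 1 for m in dictionary.motifs])
    pooled: List[float] = []
    for _ in range(n_splits):
        idx = rng.permutation(len(rho_list))
        half = len(rho_list) // 2
        A = [rho_list[i] for i in idx[:half]]
        B = [rho_list[i] for i in idx[half:]]
        cA, nA = _fit_counts(A, dictionary, noise, config)
        cB, nB = _fit_counts(B, dictionary, noise, config)
        pooled.extend(_scores(cA, nA, cB, nB)[multi_mask])
    return np.array(pooled)


# ------------------------------------------------------------ Markov baseline
def markov_expected_counts(
    label_seqs: Sequence[Sequence[int]],
    motifs: Sequence[Motif],
    K: int | None = None,
    observed: Dict[Motif, float] | None = None,
) -> MarkovBaseline:
    """Expected motif occurrence counts under a first-order Markov chain.

    The chain is fit by MLE on hard-labelled sequences (additive smoothing of
    0.5 applied to unseen transitions, with a warning).  The expected count of
    string ``c_1..c_l`` is the summed window expectation ``sum_seq sum_pos
    pi(c_1) prod_i T(c_i, c_{i+1})``.  Observed counts default to raw
    (overlapping) substring occurrences; the p-value is a one-sided Poisson
    likelihood-ratio test for over-representation.
    """
    seqs = [np.asarray(s, dtype=int) for s in label_seqs]
    if K is None:
        K = int(max(s.max() for s in seqs)) + 1
    counts = np.zeros((K, K))
    init = np.zeros(K)
    for s in seqs:
        init += np.bincount(s, minlength=K)
        if s.shape[0] > 1:
            np.add.at(counts, (s[:-1], s[1:]), 1.0)
    pi = init / init.sum()
    if np.any((counts.sum(axis=1) > 0) & np.any(counts == 0, axis=1)):
        warnings.warn("unseen transitions: applying additive smoothing of 0.5")
        counts = counts + 0.5
    row = counts.sum(axis=1, keepdims=True)
    T = np.divide(counts, row, out=np.full_like(counts, 1.0 / K), where=row > 0)

    expected: Dict[Motif, float] = {}
    observed_out: Dict[Motif, float] = {}
    p_values: Dict[Motif, float] = {}
    for m in motifs:
        l = len(m)
        prob = pi[m[0]]
        for a, b in zip(m[:-1], m[1:]):
            prob *= T[a, b]
        n_windows = sum(max(s.shape[0] - l + 1, 0) for s in seqs)
        e = float(n_windows * prob)
        if observed is not None:
            o = float(observed.get(m, 0.0))
        else:
            o = float(sum(_count_overlapping(s, m) for s in seqs))
        expected[m] = e
        observed_out[m] = o
        if o > e and e > 0:
            stat = 2.0 * (o * math.log(o / e) - (o - e))
            p_values[m] = 0.5 * float(stats.chi2.sf(stat, df=1))
        else:
            p_values[m] = 1.0
    return MarkovBaseline(
        initial=pi, transition=T, expected=expected,
        observed=observed_out, p_values=p_values,
    )


def _count_overlapping(seq: np.ndarray, motif: Motif) -> int:
    l = len(motif)
    if seq.shape[0] < l:
        return 0
    hits = np.ones(seq.shape[0] - l + 1, dtype=bool)
    for k, c in enumerate(motif):
        hits &= seq[k : seq.shape[0] - l + 1 + k] == c
    return int(hits.sum())


# ------------------------------------------------------- usage in decodings
def motif_coverage_and_prevalence(
    segmentations: Sequence[Segmentation],
    motif: Motif,
    total_symbols: int | None = None,
) -> Tuple[float, float]:
    """(coverage, prevalence) of a motif in MAP decodings.

    Coverage is the fraction of all symbols lying inside decoded instances of
    the motif; prevalence is the percentage of sequences with at least one
    decoded instance.  A motif can have positive expected counts yet never
    appear in any most-likely partitioning.
    """
    if total_symbols is None:
        total_symbols = sum(s.L for s in segmentations)
    covered = 0
    n_with = 0
    for seg in segmentations:
        hits = [s for s in seg.segments if s.motif == motif]
        covered += sum(s.end - s.start for s in hits)
        n_with += bool(hits)
    pct = 100.0 * n_with / len(segmentations) if segmentations else 0.0
    return covered / total_symbols if total_symbols else 0.0, pct
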
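"""Synthetic benchmark: ground-truth dictionaries, noisy data, recovery scores.

The generator emulates soft-clustered behavioural recordings: a dictionary of
motif templates over a 7-character alphabet is drawn at random, templates are
sampled i.i.d., mutated by the pattern-noise model and emitted from 2-D
Gaussian clusters whose geometric separation sets how confusable characters
are.  Defaults reproduce the standard study conditions: 50 motifs with
Poisson(5) lengths, character frequencies from a symmetric Dirichlet(5),
motif probabilities from a symmetric Dirichlet(1) scaled by ``1 - eps_b``,
background fraction ``eps_b`` of lone characters, and cluster discriminability
``mu`` (nearest-neighbour distance over unit cluster s.d.).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .emissions import EmissionModel
from .engine import Dictionary
from .pattern import Motif, NoiseParams, sample_instantiation
from .segment import Segment, Segmentation


@dataclass
class BenchmarkSpec:
    """Generation parameters for one synthetic dataset."""

    K: int = 7  # alphabet size / number of emission clusters
    d: int = 2  # feature dimension
    n_motifs: int = 50
    mean_length: float = 5.0  # Poisson mean of motif lengths (zero resampled)
    alpha_chars: float = 5.0  # symmetric Dirichlet over character frequencies
    alpha_motifs: float = 1.0  # symmetric Dirichlet over motif probabilities
    eps_b: float = 0.5  # background fraction (lone characters)
    eps_p: float = 0.0  # pattern noise per character
    p_d: float = 0.5  # deletion share of pattern noise
    mu: float = 3.0  # nearest-neighbour cluster distance (unit s.d.)
    L: int = 40000  # symbols per sequence
    n_sequences: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps_b <= 1.0):
            raise ValueError("eps_b must be in [0, 1]")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.L < 1 or self.n_sequences < 1:
            raise ValueError("L and n_sequences must be >= 1")

    @property
    def noise(self) -> NoiseParams:
        return NoiseParams(eps_p=self.eps_p, p_d=self.p_d)


@dataclass
class BenchmarkTruth:
    """Everything the generator knows about one synthetic dataset."""

    dictionary: Dictionary  # unigrams + unique multi-character motifs
    segmentations: List[Segmentation]  # ground-truth tiling per sequence
    emission_model: EmissionModel
    char_freqs: np.ndarray
    template_draws: List[List[Motif]]  # i.i.d. template sequence per sequence
    labels: List[np.ndarray]  # emitted character sequence per sequence

    def occurrence_counts(self) -> Dict[Motif, int]:
        """Number of times each template was drawn across the dataset."""
        counts: Dict[Motif, int] = {}
        for draws in self.template_draws:
            for m in draws:
                counts[m] = counts.get(m, 0) + 1
        return counts


def cluster_centers(K: int, mu: float, d: int = 2) -> np.ndarray:
    """Unit-s.d. cluster centres: a centred hexagon ring plus centre (K=7).

    For other K the first K positions of the same layout (centre, then ring
    vertices at spacing ``mu``) are used; adjacent ring vertices and the
    centre-to-ring distances both equal ``mu``.
    """
    pts = [np.zeros(d)]
    for k in range(max(K - 1, 0)):
        ang = 2.0 * np.pi * k / 6.0
        p = np.zeros(d)
        p[0] = mu * np.cos(ang)
        p[1] = mu * np.sin(ang)
        pts.append(p)
    return np.array(pts[:K])


def _draw_true_motifs(spec: BenchmarkSpec, rng: np.random.Generator):
    freqs = rng.dirichlet(np.full(spec.K, spec.alpha_chars))
    motifs: List[Motif] = []
    for _ in range(spec.n_motifs):
        length = 0
        while length == 0:
            length = int(rng.poisson(spec.mean_length))
        motifs.append(tuple(rng.choice(spec.K, size=length, p=freqs)))
    p_motifs = rng.dirichlet(np.full(spec.n_motifs, spec.alpha_motifs))
    p_motifs = p_motifs * (1.0 - spec.eps_b)
    return freqs, motifs, p_motifs


def _merged_dictionary(
    spec: BenchmarkSpec,
    freqs: np.ndarray,
    motifs: List[Motif],
    p_motifs: np.ndarray,
) -> Dictionary:
    """Unigrams + unique multi-character motifs (duplicates merged)."""
    p_map: Dict[Motif, float] = {(c,): spec.eps_b * freqs[c] for c in range(spec.K)}
    for m, pm in zip(motifs, p_motifs):
        p_map[m] = p_map.get(m, 0.0) + float(pm)
    unigrams = [(c,) for c in range(spec.K)]
    # motifs with zero mass (eps_b = 1) can never occur; drop them
    multi = sorted(m for m in p_map if len(m) > 1 and p_map[m] > 0)
    ordered = unigrams + multi
    p = np.array([p_map[m] for m in ordered])
    return Dictionary(K=spec.K, motifs=ordered, p=p / p.sum())


def generate_benchmark(spec: BenchmarkSpec):
    """Generate a synthetic dataset and its ground truth.

    Returns ``(features, truth)`` where ``features`` is a list of ``(L, d)``
    arrays (one per sequence) and ``truth`` a :class:`BenchmarkTruth`.  The
    final template of each sequence is truncated at ``L`` symbols.
    """
    rng = np.random.default_rng(spec.seed)
    freqs, motifs, p_motifs = _draw_true_motifs(spec, rng)
    dictionary = _merged_dictionary(spec, freqs, motifs, p_motifs)
    centers = cluster_centers(spec.K, spec.mu, spec.d)
    covs = np.tile(np.eye(spec.d), (spec.K, 1, 1))
    model = EmissionModel(centers, covs, [freqs.copy()])
    noise = spec.noise

    # Template pool: the 50 drawn motifs plus the background unigrams.
    pool: List[Motif] = motifs + [(c,) for c in range(spec.K)]
    pool_p = np.concatenate([p_motifs, spec.eps_b * freqs])
    pool_p = pool_p / pool_p.sum()

    features: List[np.ndarray] = []
    segmentations: List[Segmentation] = []
    all_draws: List[List[Motif]] = []
    all_labels: List[np.ndarray] = []
    for _ in range(spec.n_sequences):
        labels: List[int] = []
        segments: List[Segment] = []
        draws: List[Motif] = []
        while len(labels) < spec.L:
            t = pool[int(rng.choice(len(pool), p=pool_p))]
            draws.append(t)
            inst = sample_instantiation(t, noise, rng) if noise.eps_p > 0 else t
            if not inst:
                continue  # fully deleted instantiation emits nothing
            start = len(labels)
            end = min(start + len(inst), spec.L)
            labels.extend(inst[: end - start])
            segments.append(Segment(motif=t, start=start, end=end))
        lab = np.array(labels[: spec.L], dtype=int)
        y = centers[lab] + rng.standard_normal((spec.L, spec.d))
        features.append(y)
        segmentations.append(Segmentation(segments=segments, L=spec.L))
        all_draws.append(draws)
        all_labels.append(lab)

    truth = BenchmarkTruth(
        dictionary=dictionary,
        segmentations=segmentations,
        emission_model=model,
        char_freqs=freqs,
        template_draws=all_draws,
        labels=all_labels,
    )
    return features, truth


def benchmark_rho(truth: BenchmarkTruth, features: List[np.ndarray]) -> List[np.ndarray]:
    """Emission-density sequences under the generating emission model."""
    return [truth.emission_model.densities(y) for y in features]


def shuffle_dataset(
    features: List[np.ndarray] | np.ndarray, seed: int = 0
) -> List[np.ndarray]:
    """Permute events uniformly within the whole dataset.

    Destroys all sequential structure while preserving the marginal emission
    distribution; the learned dictionary on shuffled data should contain no
    multi-character motifs.
    """
    rng = np.random.default_rng(seed)
    if isinstance(features, np.ndarray):
        features = [features]
    sizes = [y.shape[0] for y in features]
    pooled = np.vstack(features)
    pooled = pooled[rng.permutation(pooled.shape[0])]
    out, pos = [], 0
    for n in sizes:
        out.append(pooled[pos : pos + n])
        pos += n
    return out


@dataclass
class RecoveryReport:
    """Exact-string-match comparison of a learned dictionary with truth."""

    n_motifs: int  # learned multi-character motifs
    false_negatives: List[Motif]  # true motifs not recovered
    false_positives: List[Motif]  # learned motifs not in truth
    prob_pairs: List[Tuple[Motif, float, float]]  # (motif, true p, learned p)

    @property
    def n_false_negatives(self) -> int:
        return len(self.false_negatives)

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positives)

    def pearson_r(self) -> float:
        """Correlation between true and estimated probabilities of matches."""
        if len(self.prob_pairs) < 2:
            return float("nan")
        a = np.array([t for _, t, _ in self.prob_pairs])
        b = np.array([e for _, _, e in self.prob_pairs])
        return float(np.corrcoef(a, b)[0, 1])

    def rare_false_negatives(
        self, occurrence_counts: Dict[Motif, int], max_count: int = 25
    ) -> List[Motif]:
        """False negatives occurring fewer than ``max_count`` times in truth."""
        return [
            m
            for m in self.false_negatives
            if occurrence_counts.get(m, 0) < max_count
        ]


def evaluate_recovery(learned: Dictionary, truth: BenchmarkTruth) -> RecoveryReport:
    """Compare learned multi-character motifs with the generating dictionary."""
    true_multi = {
        m: float(p)
        for m, p in zip(truth.dictionary.motifs, truth.dictionary.p)
        if len(m) > 1
    }
    learned_multi = {
        m: float(p) for m, p in zip(learned.motifs, learned.p) if len(m) > 1
    }
    fn = sorted(m for m in true_multi if m not in learned_multi)
    fp = sorted(m for m in learned_multi if m not in true_multi)
    pairs = [
        (m, true_multi[m], learned_multi[m]) for m in sorted(true_multi)
        if m in learned_multi
    ]
    return RecoveryReport(
        n_motifs=len(learned_multi),
        false_negatives=fn,
        false_positives=fp,
        prob_pairs=pairs,
    )
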
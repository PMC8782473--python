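"""MAP segmentation of a sequence into motifs and segmentation scoring.

The most likely partitioning maximises ``P(Y | m_1, m_2, ...) * prod p_{m_i}``
over all ways of tiling the sequence with dictionary templates, computed with
a Viterbi-style value function over prefix lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from ._dp import viterbi_pass
from .engine import Dictionary
from .pattern import Motif, NoiseParams, window_likelihoods


@dataclass
class Segment:
    motif: Motif
    start: int  # 0-based, inclusive
    end: int  # exclusive
    log_likelihood: float = 0.0  # ln(p_m * Q(window | m))


@dataclass
class Segmentation:
    """An exact tiling of ``[0, L)`` by motif instances."""

    segments: List[Segment]
    L: int

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.end <= seg.start:
                raise ValueError("segments must tile [0, L) contiguously")
            pos = seg.end
        if self.segments and pos != self.L:
            raise ValueError("segments must cover the full sequence")

    def boundaries(self) -> set:
        """All cut points, including the endpoints 0 and L."""
        b = {0, self.L}
        for seg in self.segments:
            b.add(seg.start)
        return b

    def as_tuples(self) -> List[Tuple[Motif, int, int]]:
        return [(s.motif, s.start, s.end) for s in self.segments]

    def joint_log_score(self) -> float:
        return float(sum(s.log_likelihood for s in self.segments))


@dataclass
class SegmentationScore:
    pct_correct: float  # symbols in segments matching truth exactly
    pct_boundaries_correct: float  # recall of true cut points
    boundary_precision: float  # fraction of decoded cut points that are true


class UnsegmentableError(RuntimeError):
    def __init__(self, prefix: int):
        self.prefix = prefix
        super().__init__(
            f"no dictionary template can explain the sequence up to event "
            f"{prefix}; prefix has zero likelihood under every tiling"
        )


def viterbi_segment(
    rho: np.ndarray,
    dic: Dictionary,
    noise: NoiseParams,
    max_window: int | None = None,
) -> Segmentation:
    """Most likely partitioning of one sequence into dictionary motifs.

    Ties in the value function are broken toward a longer final segment, then
    a higher motif probability, then lexicographically smaller motif, making
    the decoding reproducible.
    """
    rho = np.asarray(rho, dtype=float)
    L = rho.shape[0]
    mtrunc = (2 * dic.l_max if noise.eps_p > 0 else dic.l_max)
    if max_window is not None:
        mtrunc = min(mtrunc, max_window)

    entries = []  # (window length, motif index, log p, values)
    for mi, m in enumerate(dic.motifs):
        tabs = window_likelihoods(rho, m, noise, max_len=mtrunc)
        for w, vals in tabs.items():
            entries.append((w, mi, float(np.log(dic.p[mi])), vals))
    # Tie-break order: longer window first, then higher p, then lexicographic.
    entries.sort(key=lambda e: (-e[0], -e[2], dic.motifs[e[1]]))

    if not entries:
        raise UnsegmentableError(1)
    entry_len = np.array([e[0] for e in entries], dtype=np.int64)
    entry_logp = np.array([e[2] for e in entries])
    W = np.vstack([e[3] for e in entries])
    with np.errstate(divide="ignore"):
        logw = np.log(W)
    V, best = viterbi_pass(logw, entry_len, entry_logp)

    if not np.isfinite(V[L]):
        bad = int(np.flatnonzero(~np.isfinite(V[1:]))[0]) + 1
        raise UnsegmentableError(bad)

    segments: List[Segment] = []
    i = L
    while i > 0:
        e = int(best[i])
        w = int(entry_len[e])
        mi = entries[e][1]
        s = i - w
        segments.append(
            Segment(
                motif=dic.motifs[mi],
                start=s,
                end=i,
                log_likelihood=float(logw[e, s] + entry_logp[e]),
            )
        )
        i = s
    segments.reverse()
    return Segmentation(segments=segments, L=L)


def score_segmentation(
    decoded: Segmentation,
    truth: Segmentation,
    require_state_match: bool = True,
) -> SegmentationScore:
    """Score a decoded segmentation against ground truth.

    With ``require_state_match`` a symbol counts as correct iff its enclosing
    decoded segment has the same motif identity and the same boundaries as the
    truth segment; without it only the boundary metrics are meaningful (the
    state metric is reported as the fraction of symbols inside
    boundary-matching segments regardless of identity).
    """
    if decoded.L != truth.L:
        raise ValueError("segmentations cover sequences of different lengths")
    if require_state_match:
        truth_set = {(s.motif, s.start, s.end) for s in truth.segments}
        correct = sum(
            s.end - s.start
            for s in decoded.segments
            if (s.motif, s.start, s.end) in truth_set
        )
    else:
        truth_spans = {(s.start, s.end) for s in truth.segments}
        correct = sum(
            s.end - s.start
            for s in decoded.segments
            if (s.start, s.end) in truth_spans
        )
    tb = truth.boundaries()
    db = decoded.boundaries()
    inter = len(tb & db)
    return SegmentationScore(
        pct_correct=100.0 * correct / truth.L,
        pct_boundaries_correct=100.0 * inter / len(tb),
        boundary_precision=100.0 * inter / len(db),
    )
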
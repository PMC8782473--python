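"""Numba kernels for the sequential ratio recursions and Viterbi decoding.

The forward/backward passes are intrinsically sequential in the symbol index,
so they are JIT-compiled; everything else in the engine is vectorised numpy.
A pure-Python fallback is provided in case numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def forward_ratios(qsum: np.ndarray) -> np.ndarray:
    """R_i = Z_{1:i} / Z_{1:i-1} from window marginals.

    ``qsum[w-1, s]`` is the marginal window likelihood sum_m p_m Q^m for the
    window of length ``w`` starting at ``s`` (0-based).  Returns R (length L).
    """
    mtrunc, L = qsum.shape
    R = np.zeros(L)
    for i in range(L):
        acc = qsum[0, i]
        prodinv = 1.0
        top = min(mtrunc, i + 1)
        for w in range(2, top + 1):
            prodinv /= R[i - w + 1]
            acc += qsum[w - 1, i - w + 1] * prodinv
            if prodinv != prodinv or prodinv == np.inf:  # NaN/inf guard
                break
        R[i] = acc
        if not (acc > 0.0) or acc == np.inf or acc != acc:
            # Leave the remainder zero; caller raises with the index.
            return R
    return R


@njit(cache=False)
def backward_ratios(qsum: np.ndarray) -> np.ndarray:
    """R'_i = Z_{i:L} / Z_{i+1:L}; mirror image of :func:`forward_ratios`."""
    mtrunc, L = qsum.shape
    Rp = np.zeros(L)
    for i in range(L - 1, -1, -1):
        acc = qsum[0, i]
        prodinv = 1.0
        top = min(mtrunc, L - i)
        for w in range(2, top + 1):
            prodinv /= Rp[i + w - 1]
            acc += qsum[w - 1, i] * prodinv
            if prodinv != prodinv or prodinv == np.inf:
                break
        Rp[i] = acc
        if not (acc > 0.0) or acc == np.inf or acc != acc:
            return Rp
    return Rp


@njit(cache=False)
def viterbi_pass(
    logw: np.ndarray, entry_len: np.ndarray, entry_logp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Value-function pass for the most likely motif partitioning.

    ``logw[e, s]`` is log Q of window ``s .. s+entry_len[e]-1`` for table entry
    ``e`` (-inf where undefined); ``entry_logp[e]`` is log p of its motif.
    Entries must be pre-sorted by the desired tie-break order; the first
    maximiser encountered wins.  Returns the value function over prefix
    lengths 0..L and the argmax entry index per prefix (-1 where unreachable).
    """
    n_entries, L = logw.shape
    V = np.full(L + 1, -np.inf)
    V[0] = 0.0
    best = np.full(L + 1, -1, dtype=np.int64)
    for i in range(1, L + 1):
        vbest = -np.inf
        ebest = -1
        for e in range(n_entries):
            s = i - entry_len[e]
            if s < 0:
                continue
            w = logw[e, s]
            if w == -np.inf or V[s] == -np.inf:
                continue
            v = V[s] + w + entry_logp[e]
            if v > vbest:
                vbest = v
                ebest = e
        V[i] = vbest
        best[i] = ebest
    return V, best
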
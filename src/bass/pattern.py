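"""Motif templates and the pattern-noise likelihood Q(Y | m).

A motif is a fixed string of cluster labels (characters).  When a motif is
instantiated in data, each character independently either

* survives unchanged (probability ``1 - eps_p``),
* is deleted (probability ``eps_p * p_d``), or
* is copied in place ``j`` extra times (probability ``eps_p * p_c[j]``),

so an instantiation of an ``l``-character motif can be anywhere between 0 and
``l * (1 + j_max)`` symbols long.  No transpositions and no insertions of
foreign characters are allowed.  The likelihood of a stretch of soft-clustered
data given a motif marginalises over all such mutation paths with a profile
HMM-style dynamic programme; :func:`mutation_distribution` provides a
brute-force enumeration oracle for testing it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

#: A motif is a tuple of integer cluster labels, e.g. ``(0, 3, 3, 1)``.
Motif = Tuple[int, ...]


def parse_motif(text: str) -> Motif:
    """Parse a motif from a string of whitespace-separated integer labels."""
    return tuple(int(tok) for tok in text.split())


def format_motif(motif: Motif, glyphs: Sequence[str] | None = None) -> str:
    """Render a motif as text, optionally mapping labels to glyphs."""
    if glyphs is not None:
        return "".join(glyphs[c] for c in motif)
    return " ".join(str(c) for c in motif)


@dataclass(frozen=True)
class NoiseParams:
    """Pattern-noise model: per-character mutation probabilities.

    Parameters
    ----------
    eps_p:
        Probability that a character of a motif instantiation mutates at all.
    p_d:
        Conditional probability (given a mutation) of a deletion.
    p_c:
        Conditional probabilities of copy-insertions; ``p_c[j-1]`` is the
        probability that the character is copied exactly ``j`` extra times.
        Must satisfy ``p_d + sum(p_c) == 1``.  By default only single copies
        are allowed: ``p_c = (1 - p_d,)``.
    """

    eps_p: float = 0.0
    p_d: float = 0.5
    p_c: Tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.p_c is None:
            object.__setattr__(self, "p_c", (1.0 - self.p_d,))
        object.__setattr__(self, "p_c", tuple(float(x) for x in self.p_c))
        if not (0.0 <= self.eps_p < 1.0):
            raise ValueError(f"eps_p must be in [0, 1), got {self.eps_p}")
        if self.p_d < 0 or any(x < 0 for x in self.p_c):
            raise ValueError("deletion/copy shares must be nonnegative")
        total = self.p_d + sum(self.p_c)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"p_d + sum(p_c) must equal 1, got {total}")

    @property
    def j_max(self) -> int:
        """Largest allowed number of extra copies of one character."""
        return len(self.p_c)

    @property
    def max_stretch(self) -> int:
        """Maximum instantiation length per template character."""
        return 1 + self.j_max

    def delete_all_prob(self, length: int) -> float:
        """Probability that an entire length-``length`` motif is deleted."""
        return float((self.eps_p * self.p_d) ** length)


def mutation_table(
    rho_window: np.ndarray, motif: Motif, noise: NoiseParams
) -> np.ndarray:
    """Partial-likelihood table M(k1, k2) = Q(y_1..y_k1 | c_1..c_k2).

    ``rho_window`` is an ``(n, K)`` array of emission densities for the data
    window; the returned table has shape ``(n + 1, len(motif) + 1)`` with
    ``M[0, 0] = 1`` and ``M[k1, 0] = 0`` for ``k1 > 0``.  ``M[0, k2]`` follows
    from the recursion as ``(eps_p * p_d) ** k2`` (every character deleted).
    """
    rho_window = np.asarray(rho_window, dtype=float)
    n = rho_window.shape[0]
    l = len(motif)
    eps, pd, pc = noise.eps_p, noise.p_d, noise.p_c
    M = np.zeros((n + 1, l + 1))
    M[0, 0] = 1.0
    for k2 in range(1, l + 1):
        c = motif[k2 - 1]
        q = rho_window[:, c] if n else np.empty(0)
        M[0, k2] = eps * pd * M[0, k2 - 1]
        for k1 in range(1, n + 1):
            val = (1.0 - eps) * q[k1 - 1] * M[k1 - 1, k2 - 1]
            val += eps * pd * M[k1, k2 - 1]
            run = q[k1 - 1]
            for j in range(1, len(pc) + 1):
                if k1 - j - 1 < 0:
                    break
                run *= q[k1 - 1 - j]
                if pc[j - 1]:
                    val += eps * pc[j - 1] * M[k1 - j - 1, k2 - 1] * run
            M[k1, k2] = val
    return M


def motif_likelihood(
    rho_window: np.ndarray, motif: Motif, noise: NoiseParams
) -> float:
    """Likelihood Q(Y | m) of a data window given a motif template.

    Marginalises over all mutated instantiations of ``motif`` that have the
    window's length.  Returns 0.0 when the window is longer than any reachable
    instantiation.  With ``eps_p == 0`` this reduces to the plain emission
    product when the window length equals the motif length, and 0 otherwise.
    """
    rho_window = np.asarray(rho_window, dtype=float)
    if rho_window.ndim != 2:
        raise ValueError("rho_window must be a 2-D (length, K) array")
    n = rho_window.shape[0]
    if n > len(motif) * noise.max_stretch:
        return 0.0
    M = mutation_table(rho_window, motif, noise)
    return float(M[n, len(motif)])


def window_likelihoods(
    rho: np.ndarray,
    motif: Motif,
    noise: NoiseParams,
    max_len: int | None = None,
) -> Dict[int, np.ndarray]:
    """Q(Y_{s:s+w-1} | m) for every start ``s`` and window length ``w``.

    Returns a mapping ``w -> values`` where ``values`` has length ``L`` and
    ``values[s]`` is the likelihood of the window of length ``w`` starting at
    ``s`` (zero-padded for starts where the window would run off the end).
    The dynamic programme of :func:`mutation_table` is vectorised over all
    start positions at once.
    """
    rho = np.asarray(rho, dtype=float)
    L, _K = rho.shape
    l = len(motif)
    eps, pd, pc = noise.eps_p, noise.p_d, noise.p_c
    T = l * noise.max_stretch
    if max_len is not None:
        T = min(T, max_len)
    T = min(T, L)
    if T <= 0:
        return {}

    if eps == 0.0:
        # Noiseless fast path: only windows of exactly the motif length.
        if l > min(T, L):
            return {}
        w = rho[: L - l + 1, motif[0]].copy()
        for k in range(1, l):
            w = w * rho[k : L - l + 1 + k, motif[k]]
        out = np.zeros(L)
        out[: L - l + 1] = w
        return {l: out}

    # M[s, k1]: table column for window starting at s, vectorised over s.
    jmax = len(pc)
    Mprev = np.zeros((L, T + 1))
    Mprev[:, 0] = 1.0
    Mnew = np.empty_like(Mprev)
    qpad = np.empty(L + T)
    for k2 in range(1, l + 1):
        c = motif[k2 - 1]
        qpad[:L] = rho[:, c]
        qpad[L:] = 0.0
        Mnew[:, 0] = eps * pd * Mprev[:, 0]
        for k1 in range(1, T + 1):
            q_k1 = qpad[k1 - 1 : k1 - 1 + L]
            val = (1.0 - eps) * q_k1 * Mprev[:, k1 - 1]
            val += eps * pd * Mprev[:, k1]
            run = q_k1.copy()
            for j in range(1, jmax + 1):
                if k1 - j - 1 < 0:
                    break
                run = run * qpad[k1 - 1 - j : k1 - 1 - j + L]
                if pc[j - 1]:
                    val += eps * pc[j - 1] * Mprev[:, k1 - j - 1] * run
            Mnew[:, k1] = val
        Mprev, Mnew = Mnew, Mprev

    out: Dict[int, np.ndarray] = {}
    for w in range(1, T + 1):
        vals = Mprev[:, w].copy()
        vals[L - w + 1 :] = 0.0  # windows running off the end are invalid
        if np.any(vals > 0.0):
            out[w] = vals
    return out


def mutation_distribution(
    motif: Motif, noise: NoiseParams, max_length: int = 12
) -> Dict[Motif, float]:
    """Exhaustive distribution over mutated instantiations of ``motif``.

    Enumeration oracle for :func:`motif_likelihood`: every per-character
    keep/delete/copy-``j`` outcome is enumerated and the probabilities of
    identical output strings are summed.  Refuses motifs longer than
    ``max_length`` (combinatorial blow-up).
    """
    if len(motif) > max_length:
        raise ValueError(
            f"motif of length {len(motif)} exceeds enumeration cap {max_length}"
        )
    eps, pd, pc = noise.eps_p, noise.p_d, noise.p_c
    # Per-character outcomes: (emitted copies, probability).
    outcomes = [(1, 1.0 - eps), (0, eps * pd)]
    outcomes += [(j + 1, eps * pc[j - 1]) for j in range(1, len(pc) + 1)]
    dist: Dict[Motif, float] = {}
    for combo in itertools.product(outcomes, repeat=len(motif)):
        prob = 1.0
        out: list[int] = []
        for char, (copies, p) in zip(motif, combo):
            prob *= p
            out.extend([char] * copies)
        if prob > 0.0:
            key = tuple(out)
            dist[key] = dist.get(key, 0.0) + prob
    return dist


def sample_instantiation(
    motif: Motif, noise: NoiseParams, rng: np.random.Generator
) -> Motif:
    """Draw one mutated instantiation of ``motif`` from the noise model."""
    out: list[int] = []
    jmax = noise.j_max
    probs = np.array(
        [1.0 - noise.eps_p, noise.eps_p * noise.p_d]
        + [noise.eps_p * noise.p_c[j] for j in range(jmax)]
    )
    choices = rng.choice(2 + jmax, size=len(motif), p=probs)
    for char, choice in zip(motif, choices):
        if choice == 0:
            out.append(char)
        elif choice == 1:
            pass  # deletion
        else:
            # choice == 2 + (j - 1) encodes j extra copies => j + 1 emissions
            out.extend([char] * choice)
    return tuple(out)
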
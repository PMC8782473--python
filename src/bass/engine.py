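"""Partition-sum likelihood engine: free energy, gradients, expected counts.

The lexical model assigns a dataset ``Y`` the likelihood

    P(Y; {p_m}) = sum over partitionings  prod over parts  Q(Y_part),

where the marginal ``Q(Y_part) = sum_m p_m Q(Y_part | m)`` mixes every
dictionary template through the pattern-noise likelihood.  The free energy is
``F = -ln P``.  Because the partition structure is Markovian in the symbol
index, ``F`` and its gradient are computed with forward/backward ratio
recursions (numerically stable replacements for the raw prefix likelihoods,
which underflow): ``R_i = Z_{1:i}/Z_{1:i-1}`` and ``R'_i = Z_{i:L}/Z_{i+1:L}``.
Expected motif counts follow from the gradient, ``<N_m> = -p_m dF/dp_m``.

Window likelihoods ``Q^m`` for every motif/length/start are precomputed once
per dictionary (the bottleneck) and reused across all optimizer evaluations.
Partition lengths are truncated at ``2 * l_max`` (at most one duplication per
character under the default noise model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from ._dp import backward_ratios, forward_ratios
from .pattern import Motif, NoiseParams, parse_motif, window_likelihoods


class ZeroLikelihoodError(RuntimeError):
    """Raised when some data prefix has zero likelihood under the model."""

    def __init__(self, seq_index: int, event_index: int):
        self.seq_index = seq_index
        self.event_index = event_index
        super().__init__(
            f"sequence {seq_index}: zero partition likelihood at event "
            f"{event_index}; check emission densities and motif probabilities"
        )


@dataclass
class Dictionary:
    """A motif dictionary: templates plus their draw probabilities.

    The dictionary always contains all ``K`` single characters (until an
    optional final truncation); probabilities live on the simplex.
    """

    K: int
    motifs: List[Motif]
    p: np.ndarray
    counts: np.ndarray | None = None  # expected counts <N_m> from last fit

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if len(self.motifs) != len(self.p):
            raise ValueError("motifs and p must have equal length")
        if np.any(self.p <= 0):
            raise ValueError("all motif probabilities must be positive")
        self._index = {m: i for i, m in enumerate(self.motifs)}
        if len(self._index) != len(self.motifs):
            raise ValueError("duplicate motifs in dictionary")

    @classmethod
    def unigrams(cls, K: int, p: np.ndarray | None = None) -> "Dictionary":
        """Dictionary of the K single characters (uniform by default)."""
        if p is None:
            p = np.full(K, 1.0 / K)
        return cls(K=K, motifs=[(c,) for c in range(K)], p=np.asarray(p, float))

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, m: Motif) -> bool:
        return m in self._index

    def index(self, m: Motif) -> int:
        return self._index[m]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(m) for m in self.motifs])

    @property
    def l_max(self) -> int:
        return max(len(m) for m in self.motifs)

    @property
    def mean_length(self) -> float:
        """Mean template length under p, l_bar = sum_m l_m p_m."""
        return float(self.lengths @ (self.p / self.p.sum()))

    @property
    def multi(self) -> List[Motif]:
        """Multi-character motifs (the learned lexicon proper)."""
        return [m for m in self.motifs if len(m) > 1]

    def normalized(self) -> "Dictionary":
        return Dictionary(self.K, list(self.motifs), self.p / self.p.sum(),
                          None if self.counts is None else self.counts.copy())

    def with_motifs(self, motifs: List[Motif], p: np.ndarray) -> "Dictionary":
        return Dictionary(self.K, motifs, p)

    def to_json(self, **metadata) -> dict:
        obj = {
            "schema": 1,
            "K": self.K,
            "motifs": [
                {
                    "motif": " ".join(map(str, m)),
                    "p": float(self.p[i]),
                    "length": len(m),
                    "count": None if self.counts is None else float(self.counts[i]),
                }
                for i, m in enumerate(self.motifs)
            ],
        }
        obj.update(metadata)
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "Dictionary":
        motifs = [parse_motif(rec["motif"]) for rec in obj["motifs"]]
        p = np.array([rec["p"] for rec in obj["motifs"]], float)
        counts = None
        if obj["motifs"] and obj["motifs"][0].get("count") is not None:
            counts = np.array([rec["count"] for rec in obj["motifs"]], float)
        return cls(K=obj["K"], motifs=motifs, p=p, counts=counts)


def as_rho_list(data) -> List[np.ndarray]:
    """Normalize input data to a list of (L, K) emission-density arrays."""
    if isinstance(data, np.ndarray):
        return [np.asarray(data, float)]
    out = []
    for item in data:
        rho = getattr(item, "rho", item)
        out.append(np.asarray(rho, float))
    return out


@dataclass
class _SeqTable:
    """Dense window-likelihood table for one sequence."""

    L: int
    entry_motif: np.ndarray  # (n_entries,) motif index
    entry_len: np.ndarray  # (n_entries,) window length
    W: np.ndarray  # (n_entries, L); W[e, s] = Q^m(window s..s+len-1)


@dataclass
class EngineResult:
    """One likelihood evaluation: free energy, counts, diagnostics."""

    F: float
    counts: np.ndarray

    @property
    def n_bar(self) -> float:
        """Expected total number of templates in the partitioning."""
        return float(self.counts.sum())


class LikelihoodEngine:
    """Cached window tables plus forward/backward machinery for one dataset.

    Parameters
    ----------
    data:
        List of ``(L, K)`` arrays of emission densities (one per sequence).
    dic:
        The current dictionary.  Window tables are cached per motif, so
        rebuilding the engine for a grown/pruned dictionary via
        :meth:`rebuild` only computes tables for new motifs.
    noise:
        Pattern-noise parameters.
    prune_threshold:
        Window likelihoods strictly below this absolute value are zeroed in
        the stored tables (0 disables pruning).
    """

    #: refuse to build window tables projected to exceed this many bytes
    max_table_bytes: float = 4e9

    def __init__(
        self,
        data,
        dic: Dictionary,
        noise: NoiseParams,
        prune_threshold: float = 0.0,
        max_window: int | None = None,
    ):
        self.data = as_rho_list(data)
        if not self.data:
            raise ValueError("data must contain at least one sequence")
        self.noise = noise
        self.prune_threshold = float(prune_threshold)
        self.max_window_cap = max_window
        self.n_symbols = int(sum(r.shape[0] for r in self.data))
        self._motif_cache: Dict[Motif, List[Dict[int, np.ndarray]]] = {}
        self._last: List[Tuple[np.ndarray, np.ndarray]] | None = None
        self.rebuild(dic)

    # ------------------------------------------------------------------ setup
    def rebuild(self, dic: Dictionary) -> None:
        """Point the engine at a (possibly updated) dictionary."""
        self.dic = dic
        self.mtrunc = 2 * dic.l_max if self.noise.eps_p > 0 else dic.l_max
        if self.max_window_cap is not None:
            self.mtrunc = min(self.mtrunc, self.max_window_cap)
        lengths_per_motif = (
            1 if self.noise.eps_p == 0 else
            min(self.mtrunc, self.noise.max_stretch * dic.l_max)
        )
        projected = 8.0 * len(dic) * lengths_per_motif * self.n_symbols
        if projected > self.max_table_bytes:
            raise MemoryError(
                f"window table projected at {projected / 1e9:.1f} GB exceeds "
                f"the {self.max_table_bytes / 1e9:.1f} GB cap; raise "
                f"max_table_bytes or prune the dictionary"
            )
        needed = set(dic.motifs)
        for m in list(self._motif_cache):
            if m not in needed:
                del self._motif_cache[m]
        for m in dic.motifs:
            if m not in self._motif_cache:
                self._motif_cache[m] = [
                    window_likelihoods(rho, m, self.noise, max_len=self.mtrunc)
                    for rho in self.data
                ]
        self.tables = [self._assemble(si) for si in range(len(self.data))]
        self._last = None

    def rebuild_probabilities(self, dic: Dictionary) -> None:
        """Swap in new probabilities for the same motif set (tables reused)."""
        if dic.motifs != self.dic.motifs:
            raise ValueError("motif set changed; use rebuild() instead")
        self.dic = dic

    def _assemble(self, si: int) -> _SeqTable:
        L = self.data[si].shape[0]
        motif_idx: List[int] = []
        lens: List[int] = []
        rows: List[np.ndarray] = []
        for mi, m in enumerate(self.dic.motifs):
            for w, vals in self._motif_cache[m][si].items():
                if w > self.mtrunc:
                    continue
                if self.prune_threshold > 0.0:
                    vals = np.where(vals >= self.prune_threshold, vals, 0.0)
                    if not np.any(vals):
                        continue
                motif_idx.append(mi)
                lens.append(w)
                rows.append(vals)
        W = np.vstack(rows) if rows else np.zeros((0, L))
        return _SeqTable(
            L=L,
            entry_motif=np.array(motif_idx, dtype=np.int64),
            entry_len=np.array(lens, dtype=np.int64),
            W=W,
        )

    # ------------------------------------------------------------- evaluation
    def _qsum(self, table: _SeqTable, p: np.ndarray) -> np.ndarray:
        qsum = np.zeros((self.mtrunc, table.L))
        pe = p[table.entry_motif]
        for w in np.unique(table.entry_len):
            sel = table.entry_len == w
            qsum[w - 1] = pe[sel] @ table.W[sel]
        return qsum

    def evaluate(self, p: np.ndarray | None = None, want_counts: bool = True) -> EngineResult:
        """Free energy (and expected counts) at motif probabilities ``p``.

        ``p`` need not be normalized; the engine evaluates the model exactly
        as given (useful for finite-difference checks).  Results for the
        ratio/boundary factors are cached for :meth:`pair_counts`.
        """
        p = self.dic.p if p is None else np.asarray(p, float)
        F = 0.0
        counts = np.zeros(len(self.dic))
        self._last = []
        for si, table in enumerate(self.tables):
            qsum = self._qsum(table, p)
            R = forward_ratios(qsum)
            bad = np.flatnonzero(~(R > 0.0) | ~np.isfinite(R))
            if bad.size:
                raise ZeroLikelihoodError(si, int(bad[0]))
            lnR = np.log(R)
            F -= float(lnR.sum())
            if not want_counts:
                self._last.append((np.cumsum(lnR), None))
                continue
            Rp = backward_ratios(qsum)
            badp = np.flatnonzero(~(Rp > 0.0) | ~np.isfinite(Rp))
            if badp.size:
                raise ZeroLikelihoodError(si, int(badp[0]))
            a = np.cumsum(lnR)
            b = np.cumsum(np.log(Rp))
            self._last.append((a, b))
            G = self._gmat(a, b, self.mtrunc)
            S = np.einsum("es,es->e", table.W, G[table.entry_len - 1])
            np.add.at(counts, table.entry_motif, S)
        counts *= p
        return EngineResult(F=F, counts=counts)

    @staticmethod
    def _gmat(a: np.ndarray, b: np.ndarray, max_len: int) -> np.ndarray:
        """Boundary factors G[w-1, s] = Z_{1:s-1} Z_{s+w:L} / Z_{1:L}."""
        L = a.shape[0]
        a_prev = np.concatenate(([0.0], a[:-1]))  # ln Z_{1:s-1}
        G = np.zeros((max_len, L))
        for w in range(1, max_len + 1):
            if w > L:
                break
            # ln G(s, s+w-1) = a[s-1] - b[s+w-1]; the exponent is capped so
            # that windows of vanishing likelihood (huge G, zero Q) cannot
            # produce inf * 0 in the count sums
            ln_g = a_prev[: L - w + 1] - b[w - 1 :]
            G[w - 1, : L - w + 1] = np.exp(np.minimum(ln_g, 700.0))
        return G

    def free_energy(self, p: np.ndarray | None = None) -> float:
        return self.evaluate(p, want_counts=False).F

    def free_energy_per_symbol(self, p: np.ndarray | None = None) -> float:
        return self.free_energy(p) / self.n_symbols

    def log_likelihood_forward_backward(self, p: np.ndarray | None = None):
        """(ln Z from R, ln Z from R') per sequence; consistency diagnostic."""
        p = self.dic.p if p is None else np.asarray(p, float)
        out = []
        for table in self.tables:
            qsum = self._qsum(table, p)
            R = forward_ratios(qsum)
            Rp = backward_ratios(qsum)
            out.append((float(np.log(R).sum()), float(np.log(Rp).sum())))
        return out

    def gradient_and_counts(self, p: np.ndarray | None = None):
        """(dF/dp_m, <N_m>) at ``p``; <N_m> = -p_m dF/dp_m."""
        p = self.dic.p if p is None else np.asarray(p, float)
        res = self.evaluate(p)
        grad = -res.counts / p
        return grad, res.counts

    # -------------------------------------------------------- expansion sums
    def pair_counts(self, p: np.ndarray | None = None) -> np.ndarray:
        """Posterior window sums for every ordered concatenation m m'.

        Returns ``PC`` with ``PC[i, j] = sum_s sum_w G(s, s+w-1) *
        Q^{m_i m_j}(window)``; the caller multiplies by the chance probability
        zeta(m_i m_j) to obtain expected counts of the concatenated motif.
        Uses the factorisation of the mutation process over the junction:
        ``Q^{mm'}(window) = sum_split Q^m(left) Q^{m'}(right)`` including the
        degenerate splits where one motif is entirely deleted.
        """
        p = self.dic.p if p is None else np.asarray(p, float)
        if self._last is None or self._last[0][1] is None:
            self.evaluate(p)
        D = len(self.dic)
        PC = np.zeros((D, D))
        lens = self.dic.lengths
        del_all = np.array(
            [self.noise.delete_all_prob(len(m)) for m in self.dic.motifs]
        )
        max_pair_len = 2 * int(lens.max()) * self.noise.max_stretch \
            if self.noise.eps_p > 0 else 2 * int(lens.max())
        S_single = np.zeros(D)  # sum_s G Q^m, for fully-deleted partners
        for si, table in enumerate(self.tables):
            a, b = self._last[si]
            L = table.L
            G = self._gmat(a, b, min(max_pair_len, L))
            wlens = np.unique(table.entry_len)
            S = np.einsum("es,es->e", table.W, G[table.entry_len - 1])
            np.add.at(S_single, table.entry_motif, S)
            for w1 in wlens:
                sel1 = table.entry_len == w1
                m1 = table.entry_motif[sel1]
                W1 = table.W[sel1]
                for w2 in wlens:
                    wt = int(w1 + w2)
                    if wt > G.shape[0]:
                        continue
                    sel2 = table.entry_len == w2
                    m2 = table.entry_motif[sel2]
                    # right windows shifted left by w1
                    W2s = np.zeros_like(table.W[sel2])
                    W2s[:, : L - w1] = table.W[sel2][:, w1:]
                    A = W1 * G[wt - 1][None, :]
                    block = A @ W2s.T
                    PC[np.ix_(m1, m2)] += block
        if self.noise.eps_p > 0:
            PC += np.outer(S_single, del_all)  # right motif fully deleted
            PC += np.outer(del_all, S_single)  # left motif fully deleted
        return PC
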
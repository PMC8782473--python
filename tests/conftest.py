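import numpy as np
import pytest

from bass import hard_label_rho


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def delta_rho(labels, K=3):
    """Exact one-hot density rows (delta emissions) for a label string."""
    labels = list(labels)
    rho = np.zeros((len(labels), K))
    rho[np.arange(len(labels)), labels] = 1.0
    return rho


@pytest.fixture
def make_delta_rho():
    return delta_rho


PLANTED_MOTIFS = [
    (0, 1), (1, 2, 0), (2, 2), (0, 2, 1),
    (3, 0), (1, 3, 3), (2, 0, 3), (3, 1),
]


def planted_motif_sequences(rng, n_seqs, length, K=4, motif_rate=0.32,
                            motifs=PLANTED_MOTIFS):
    """Hard-labelled sequences mixing iid background with planted motifs."""
    out = []
    for _ in range(n_seqs):
        syms = []
        while len(syms) < length:
            if rng.random() < motif_rate:
                syms.extend(motifs[int(rng.integers(len(motifs)))])
            else:
                syms.append(int(rng.integers(K)))
        out.append(hard_label_rho(syms[:length], K))
    return out
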
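# bass-motifs

Unsupervised discovery of recurring **action-sequence motifs** in behavioural
recordings, and segmentation of the recordings into those motifs (BASS:
Behavioural Action Sequence Segmentation).

## The problem

Animal behaviour unfolds as a sequence of discrete elementary episodes —
swim bouts in larval zebrafish, postural actions in a soaring glider — that
can be soft-clustered into `K` types. Behaviour is rarely a memoryless stream
of such "characters": animals deploy stereotyped multi-bout *motifs* (e.g. a
J-turn followed by pursuit and capture swims). This package learns, without
supervision, a **dictionary** of such motifs from the data, even when motifs
are rare, corrupted by deletions/duplications of their characters, and
embedded in a large background of isolated bouts.

## The model

Each event `y_i` carries emission densities `ρ_ij = q(y_i | j)` over the `K`
cluster labels (from a Gaussian mixture, or near-one-hot rows for hard
labels). A dictionary `D` holds templates `m` (strings over the alphabet,
including all single characters) with probabilities `p_m`. Data are generated
by drawing templates i.i.d. from `p_m`; each template character is deleted
with probability `ε_p·p_d`, copied in place `j` extra times with probability
`ε_p·p_c,j`, or kept (`1 − ε_p`); the mutated string is emitted
character-by-character from `q(y|c)`. The likelihood of a dataset sums over
all partitionings `π` into segments:

    P(Y; {p_m}) = Σ_π Π_α Q(Y_α),    Q(Y_α) = Σ_m p_m Q(Y_α | m),

with `Q(Y|m)` the insertion/deletion noise likelihood computed by a profile
HMM-style recursion. The free energy `F = −ln P` and its gradient (which
yields expected motif counts `⟨N_m⟩ = −p_m ∂F/∂p_m`) are computed by
forward/backward ratio recursions, so everything stays stable for long
recordings. Learning alternates:

1. **Expand** — test every concatenation `mm′` against the chance-composition
   null `N̄·ζ(mm′)` (likelihood-ratio test, `p < 10⁻³`);
2. **Refit** — maximum likelihood for `{p_m}` (L-BFGS-B on softmax
   parameters, polished by the EM fixed point `p_m = ⟨N_m⟩/N̄`);
3. **Prune** — collapse motifs whose generated-data distributions are nearly
   identical (Jensen-Shannon distance < 0.15, relevant when `ε_p > 0`) and
   drop motifs with fewer than 5 expected counts;

until the free energy per symbol changes by less than 0.1% twice in a row.
A Viterbi-style decoder returns the most likely segmentation, and a
comparison module finds motifs over-represented in one condition relative to
another (`−log₁₀ p` scores, split-half threshold calibration, subsample
consistency filtering, first-order-Markov baselines).

## Worked example

Plant a three-bout motif `2 0 1` in an i.i.d. background and recover it:

```python
import numpy as np
from bass import (NoiseParams, LearnConfig, learn_dictionary,
                  hard_label_rho, format_motif)

rng = np.random.default_rng(7)
motif = (2, 0, 1)                      # a recurring three-bout action sequence
symbols = []
while len(symbols) < 6000:
    if rng.random() < 0.25:
        symbols.extend(motif)
    else:
        symbols.append(int(rng.integers(3)))  # background bouts
rho = hard_label_rho(symbols[:6000], K=3)      # near-one-hot densities

state = learn_dictionary([rho], K=3, noise=NoiseParams(eps_p=0.0),
                         config=LearnConfig(seed=0))
for m, p, c in zip(state.dic.motifs, state.dic.p, state.dic.counts):
    print(f"motif {format_motif(m):7s}  p = {p:.4f}  expected count = {c:7.1f}")
print(f"free energy per symbol: {state.F_trace[-1]:.4f} nats "
      f"(converged in {state.iteration} iterations)")
```

prints

```
motif 0        p = 0.2648  expected count =  1035.9
motif 1        p = 0.2244  expected count =   878.0
motif 2        p = 0.2453  expected count =   959.8
motif 0 1      p = 0.0053  expected count =    20.6
motif 2 0 1    p = 0.2477  expected count =   968.9
motif 1 2 0 1  p = 0.0078  expected count =    30.6
motif 1 1 2    p = 0.0048  expected count =    18.6
free energy per symbol: 0.8821 nats (converged in 3 iterations)
```

The planted motif `2 0 1` is recovered with probability ≈ 0.25 (the planting
rate) and ≈ 970 expected occurrences; the remaining mass sits on the three
background characters, plus a few low-count chance motifs that sit right at
the pruning floor. On shuffled or i.i.d. data the dictionary contains no
multi-character motifs at all.

The same pipeline is available from the shell:

```sh
bass simulate --out-dir bench --length 40000 --seed 0   # synthetic benchmark
bass fit bench/events.csv --mode features --model bench/emission_model.json \
    --out dict.json --seed 0
bass segment bench/events.csv --mode features --model bench/emission_model.json \
    --dictionary dict.json --out segments.tsv
```

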
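"""Numba kernel for skip-gram training with negative sampling.

This is the classic word2vec SGNS update loop: for each center token a
dynamic window is drawn, and for every (context, center) pair one positive
and ``negative`` sampled targets are pushed through a logistic loss with a
linearly decaying learning rate. Negative targets are drawn from a
unigram^0.75 table. All randomness comes from an inlined xorshift64*
generator seeded by the caller, and the loop is strictly serial, so a run
is a deterministic function of (corpus, parameters, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_EXP = 6.0


@njit(cache=False)
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    return state * np.uint64(0x2545F4914F6CDD1D)


@njit(cache=False)
def train_sgns(
    corpus,  # int32[:] token ids, all sentences concatenated
    offsets,  # int64[:] sentence boundaries, len = n_sentences + 1
    syn0,  # float32[:, :] input vectors (the embedding), updated in place
    syn1,  # float32[:, :] output vectors, updated in place
    table,  # int32[:] negative-sampling table (unigram^0.75)
    window: int,
    epochs: int,
    negative: int,
    alpha0: float,
    min_alpha: float,
    seed: int,
) -> None:
    dim = syn0.shape[1]
    table_size = table.shape[0]
    total = epochs * corpus.shape[0]
    if total == 0:
        return
    done = 0
    state = np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(1)
    neu1e = np.zeros(dim, dtype=np.float32)

    for _ep in range(epochs):
        for s in range(offsets.shape[0] - 1):
            start = offsets[s]
            end = offsets[s + 1]
            for i in range(start, end):
                center = corpus[i]
                alpha = alpha0 - (alpha0 - min_alpha) * (done / total)
                done += 1
                state = _xorshift(state)
                b = int((state >> np.uint64(33)) % np.uint64(window))
                lo = i - (window - b)
                hi = i + (window - b)
                if lo < start:
                    lo = start
                if hi > end - 1:
                    hi = end - 1
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    ctx = corpus[j]
                    for d in range(dim):
                        neu1e[d] = 0.0
                    for n in range(negative + 1):
                        if n == 0:
                            target = center
                            label = 1.0
                        else:
                            state = _xorshift(state)
                            target = table[
                                int((state >> np.uint64(33)) % np.uint64(table_size))
                            ]
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for d in range(dim):
                            f += syn0[ctx, d] * syn1[target, d]
                        if f > _MAX_EXP:
                            g = (label - 1.0) * alpha
                        elif f < -_MAX_EXP:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                        for d in range(dim):
                            neu1e[d] += g * syn1[target, d]
                        for d in range(dim):
                            syn1[target, d] += g * syn0[ctx, d]
                    for d in range(dim):
                        syn0[ctx, d] += neu1e[d]
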
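"""Exact bipartite degree-preserving randomization (curveball trades).

Uniform sampling over binary matrices with both margins fixed, by the
curveball Markov chain: repeatedly pick two columns and randomly re-deal
the rows that belong to exactly one of them.  Each trade preserves both
column sums and row sums; the chain's stationary law is uniform over the
margin-constrained ensemble.

The trade loop is JIT-compiled with numba when available; a pure-python
fallback produces the identical chain (same random stream, same trades).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True)
def _run_trades(support, lengths, pairs, uniforms, mark, pool):
    """Execute curveball trades in place on the column-support table.

    ``support[j, :lengths[j]]`` holds the row indices of column j.
    ``pairs`` is the pre-drawn sequence of column pairs, ``uniforms`` the
    pre-drawn variates for the partial Fisher-Yates re-deal, ``mark`` a
    row-indexed scratch flag array and ``pool`` a scratch buffer.
    """
    for t in range(pairs.shape[0]):
        a = pairs[t, 0]
        b = pairs[t, 1]
        if a == b:
            continue
        ka = lengths[a]
        kb = lengths[b]
        for i in range(kb):
            mark[support[b, i]] = True
        # Compact a's shared members to the front; pool a's exclusives.
        n_only_a = 0
        n_inter = 0
        for i in range(ka):
            v = support[a, i]
            if mark[v]:
                support[a, n_inter] = v
                n_inter += 1
            else:
                pool[n_only_a] = v
                n_only_a += 1
        for i in range(kb):
            mark[support[b, i]] = False
        if n_only_a == 0:
            continue
        # Same for b, against the shared members just found.
        for i in range(n_inter):
            mark[support[a, i]] = True
        n_pool = n_only_a
        kept_b = 0
        for i in range(kb):
            v = support[b, i]
            if mark[v]:
                support[b, kept_b] = v
                kept_b += 1
            else:
                pool[n_pool] = v
                n_pool += 1
        for i in range(n_inter):
            mark[support[a, i]] = False
        if n_pool == n_only_a:
            # b has no exclusive members: restore a's and skip.
            for i in range(n_only_a):
                support[a, n_inter + i] = pool[i]
            continue
        # Re-deal the pooled exclusives: a random n_only_a of them go back
        # to column a, the rest to column b (partial Fisher-Yates).
        for i in range(n_only_a):
            j = i + int(uniforms[t, i] * (n_pool - i))
            if j >= n_pool:
                j = n_pool - 1
            tmp = pool[i]
            pool[i] = pool[j]
            pool[j] = tmp
        for i in range(n_only_a):
            support[a, n_inter + i] = pool[i]
        for i in range(n_pool - n_only_a):
            support[b, n_inter + i] = pool[n_only_a + i]


def _support_table(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_in, n_out = B.shape
    lengths = B.sum(axis=0).astype(np.int64)
    kmax = int(lengths.max(initial=0))
    support = np.zeros((n_out, max(kmax, 1)), dtype=np.int64)
    for j in range(n_out):
        rows = np.flatnonzero(B[:, j])
        support[j, : len(rows)] = rows
    return support, lengths


def curveball_shuffle(
    B: np.ndarray, rng: np.random.Generator, n_sweeps: int = 5
) -> np.ndarray:
    """One degree-preserving shuffle of a binary matrix.

    Runs ``n_sweeps * n_columns`` curveball trades from the observed
    matrix; five sweeps is the conventional mixing budget for matrices of
    this density.
    """
    n_in, n_out = B.shape
    support, lengths = _support_table(B)
    n_trades = n_sweeps * n_out
    kmax = support.shape[1]
    pairs = rng.integers(0, n_out, size=(n_trades, 2))
    uniforms = rng.random(size=(n_trades, kmax))
    mark = np.zeros(n_in, dtype=np.bool_)
    pool = np.zeros(4 * kmax + 4, dtype=np.int64)
    _run_trades(support, lengths, pairs, uniforms, mark, pool)
    S = np.zeros_like(B, dtype=float)
    for j in range(n_out):
        S[support[j, : lengths[j]], j] = 1.0
    return S
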
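"""Shuffle null models for bipartite connectivity.

The randomness machinery used throughout the analysis: marginal-preserving
shuffles, a PCA eigenvalue-spectrum test against an ensemble of such
shuffles, and a bilateral identical-input-pattern stereotypy test.

Two shuffle laws are provided.  The default, ``method="exact"``, holds the
input connection frequencies and per-output in-degrees *exactly* fixed and
samples uniformly over the binary matrices with those margins (curveball
randomization).  ``method="weighted"`` keeps each output's in-degree and
re-draws its inputs without replacement with probability proportional to
each input's observed marginal connection count; this is the sampling
description often given in the literature, but because the observed
marginals are themselves noisy it produces a null ensemble slightly more
heterogeneous than a matched random generator, so the exact law is the
default for calibrated hypothesis tests.

The preserved quantities — input connection probabilities and the number of
inputs per output — are defined on binary connectivity, so shuffles always
operate on binarized matrices; weighted matrices are binarized with a
logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._curveball import curveball_shuffle
from .model import ConnectivityMatrix, TypeMap, aggregate_by_type

logger = logging.getLogger(__name__)

SHUFFLE_METHODS = ("exact", "weighted")


@dataclass(frozen=True)
class ShuffleConfig:
    """Ensemble size, seed and bilateral null mode."""

    n_shuffles: int = 1000
    seed: int = 0
    mode: str = "independent"
    method: str = "exact"

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.mode not in ("independent", "mirrored"):
            raise ValueError("mode must be 'independent' or 'mirrored'")
        if self.method not in SHUFFLE_METHODS:
            raise ValueError(f"method must be one of {SHUFFLE_METHODS}")


def _binary_matrix(m: ConnectivityMatrix) -> ConnectivityMatrix:
    if not m.binarized:
        logger.info("binarizing weighted matrix for marginal-preserving shuffle")
        return m.binarize()
    return m


def _weighted_shuffle(
    B: np.ndarray, rng: np.random.Generator, marginals: np.ndarray | None = None
) -> np.ndarray:
    """One weighted-sampling shuffle of a binary matrix.

    Per column, the exact in-degree k is kept and k distinct rows are
    re-drawn sequentially without replacement with probability proportional
    to each row's marginal count.  Implemented with the exponential-keys
    (Efraimidis-Spirakis) equivalence: taking the top-k rows by
    Gumbel(0,1) + log(weight) reproduces sequential weighted sampling
    without replacement, which vectorizes across columns.
    """
    n_in, n_out = B.shape
    w = B.sum(axis=1) if marginals is None else marginals
    k = B.sum(axis=0).astype(int)
    support = int((w > 0).sum())
    if k.max(initial=0) > support:
        raise ValueError(
            f"an output demands {k.max()} inputs but only {support} inputs "
            "have nonzero marginal connection count"
        )
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    keys = logw[:, None] + rng.gumbel(size=(n_in, n_out))
    # Rank rows per column by key; the top-k per column become the edges.
    ranks = np.argsort(np.argsort(-keys, axis=0, kind="stable"), axis=0, kind="stable")
    return (ranks < k[None, :]).astype(float)


def _shuffle_binary(
    B: np.ndarray,
    rng: np.random.Generator,
    marginals: np.ndarray | None = None,
    method: str = "exact",
) -> np.ndarray:
    if method == "exact":
        return curveball_shuffle(B, rng)
    return _weighted_shuffle(B, rng, marginals=marginals)


def shuffle_preserving_marginals(
    m: ConnectivityMatrix,
    seed: int | np.random.Generator = 0,
    method: str = "exact",
) -> ConnectivityMatrix:
    """Return one marginal-preserving shuffle of ``m``.

    Column sums (per-output in-degrees) and total edge count are conserved
    exactly by both methods; ``method="exact"`` additionally conserves row
    sums exactly (uniform law over the margin-constrained ensemble), while
    ``method="weighted"`` conserves them only in expectation under the
    weighted-sampling law.  Outputs with in-degree zero stay empty.
    """
    if method not in SHUFFLE_METHODS:
        raise ValueError(f"method must be one of {SHUFFLE_METHODS}")
    b = _binary_matrix(m)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = _shuffle_binary(b.W, rng, method=method)
    return ConnectivityMatrix(
        list(b.input_ids), list(b.output_ids), W, threshold=b.threshold, binarized=True
    )


def _eigfractions(X: np.ndarray) -> np.ndarray:
    """Variance fractions of the input-channel covariance spectrum.

    ``X`` has inputs as rows (variables) and outputs as columns
    (observations); the covariance is taken over input channels with
    per-input means subtracted across outputs.
    """
    C = np.cov(X)
    C = np.atleast_2d(C)
    mu = np.linalg.eigvalsh(C)[::-1]
    mu = np.clip(mu, 0.0, None)
    total = mu.sum()
    if total <= 0:
        raise ValueError("covariance spectrum is identically zero")
    return mu / total


@dataclass
class SpectrumResult:
    """Observed PCA variance fractions with shuffle-null bands."""

    observed_fractions: np.ndarray
    null_mean: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    components_outside: np.ndarray
    n_shuffles: int
    weighted: bool = False

    @property
    def components_above(self) -> np.ndarray:
        return np.where(self.observed_fractions > self.null_hi)[0]


def pca_spectrum_test(
    m: ConnectivityMatrix, cfg: ShuffleConfig, weighted: bool = False
) -> SpectrumResult:
    """Compare the observed covariance spectrum with the shuffle ensemble.

    Fractions of variance explained by each principal component of the
    input-channel covariance are computed for the observed matrix and for
    ``cfg.n_shuffles`` marginal-preserving shuffles; the null band is the
    empirical 2.5-97.5 percentile interval per component.  Components whose
    observed fraction falls outside the band are flagged.

    By default everything runs on binarized connectivity.  With
    ``weighted=True`` the observed spectrum uses synapse counts and each
    shuffle re-places the observed per-output synapse-count multiset onto
    its re-drawn edges.
    """
    b = _binary_matrix(m)
    if (b.W.sum(axis=0) > 0).sum() < 2:
        raise ValueError("spectrum test needs at least 2 outputs with inputs")
    if len(m.input_ids) == 1:
        logger.warning("single input channel: spectrum is degenerate (fraction 1.0)")
    logger.info(
        "pca_spectrum_test on %s connectivity", "weighted" if weighted else "binarized"
    )
    X_obs = m.W if weighted else b.W
    observed = _eigfractions(X_obs)

    rng = np.random.default_rng(cfg.seed)
    marginals = b.W.sum(axis=1)
    null = np.empty((cfg.n_shuffles, len(observed)))
    for s in range(cfg.n_shuffles):
        S = _shuffle_binary(b.W, rng, marginals=marginals, method=cfg.method)
        if weighted:
            S = _replace_weights(S, m.W, rng)
        null[s] = _eigfractions(S)
    lo, hi = np.percentile(null, [2.5, 97.5], axis=0)
    mean = null.mean(axis=0)
    outside = np.where((observed > hi) | (observed < lo))[0]
    return SpectrumResult(
        observed_fractions=observed,
        null_mean=mean,
        null_lo=lo,
        null_hi=hi,
        components_outside=outside,
        n_shuffles=cfg.n_shuffles,
        weighted=weighted,
    )


def _replace_weights(
    S: np.ndarray, W: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Scatter each column's observed synapse counts onto shuffled edges."""
    out = np.zeros_like(S)
    for j in range(S.shape[1]):
        rows = np.flatnonzero(S[:, j])
        weights = W[W[:, j] > 0, j]
        if len(rows):
            out[rows, j] = rng.permutation(weights)
    return out


@dataclass
class BilateralMatchResult:
    """Identical-input-pattern match count against its shuffle null."""

    observed_count: int
    null_counts: np.ndarray
    p_value: float
    n_eligible: int


def _patterns(B: np.ndarray) -> list[tuple[int, ...]]:
    return [tuple(np.flatnonzero(B[:, j])) for j in range(B.shape[1])]


def _match_count(left_B: np.ndarray, right_B: np.ndarray) -> tuple[int, int]:
    """Left outputs with >= 1 input whose input-type set appears on the right."""
    right_set = {p for p in _patterns(right_B) if p}
    count = 0
    eligible = 0
    for p in _patterns(left_B):
        if not p:
            continue
        eligible += 1
        if p in right_set:
            count += 1
    return count, eligible


def bilateral_identity_test(
    left: ConnectivityMatrix,
    right: ConnectivityMatrix,
    tmap: TypeMap,
    cfg: ShuffleConfig,
) -> BilateralMatchResult:
    """Count left outputs whose exact binary input-type pattern recurs on
    the right, against a shuffle null.

    Both matrices are binarized and aggregated by the cross-hemisphere type
    map; only type labels present on both sides are compared (outputs with
    zero inputs from the shared types are not eligible and never counted).
    The null shuffles both sides independently (``mode='independent'``) or
    shuffles one side and copies it to the other (``mode='mirrored'``, the
    bilaterally stereotyped model).  The p-value is the +1-corrected
    fraction of null counts >= observed.
    """
    left_t = aggregate_by_type(left.binarize(), TypeMap(tmap.labels, mode="sum"))
    right_t = aggregate_by_type(right.binarize(), TypeMap(tmap.labels, mode="sum"))
    shared = sorted(set(left_t.input_ids) & set(right_t.input_ids))
    if not shared:
        raise ValueError("no shared input types between hemispheres after mapping")
    li = [left_t.input_ids.index(t) for t in shared]
    ri = [right_t.input_ids.index(t) for t in shared]
    LB = (left_t.W[li] > 0).astype(float)
    RB = (right_t.W[ri] > 0).astype(float)

    observed, eligible = _match_count(LB, RB)
    rng = np.random.default_rng(cfg.seed)
    lw = LB.sum(axis=1)
    rw = RB.sum(axis=1)
    null_counts = np.empty(cfg.n_shuffles, dtype=int)
    for s in range(cfg.n_shuffles):
        if cfg.mode == "independent":
            Ls = _shuffle_binary(LB, rng, marginals=lw, method=cfg.method)
            Rs = _shuffle_binary(RB, rng, marginals=rw, method=cfg.method)
        else:
            Ls = _shuffle_binary(LB, rng, marginals=lw, method=cfg.method)
            Rs = Ls
        null_counts[s], _ = _match_count(Ls, Rs)
    r = int((null_counts >= observed).sum())
    p = (r + 1) / (cfg.n_shuffles + 1)
    return BilateralMatchResult(
        observed_count=observed,
        null_counts=null_counts,
        p_value=p,
        n_eligible=eligible,
    )
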
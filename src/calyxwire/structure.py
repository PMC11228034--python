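"""Dimensionality and input-composition statistics.

Three families of statistics over a thresholded connectivity matrix:

* the participation ratio, PR(C) = (tr C)^2 / tr(C^2), an effective
  dimensionality of the input covariance spectrum — a population of
  outputs whose input currents are dominated by a few channels has a low
  PR even when many channels exist;
* the conditional input analysis: for every ordered pair of inputs (A, B),
  the number of outputs receiving both, z-scored against the
  marginal-preserving shuffle null, with K-means groupings of inputs over
  a range of cluster counts;
* clustering of outputs by their binary input composition (spectral
  clustering with silhouette model selection, plus hierarchical
  co-clustering orders for heatmap display).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import cosine_similarity

from .model import ConnectivityMatrix
from .null_models import ShuffleConfig, _binary_matrix, _shuffle_binary

logger = logging.getLogger(__name__)


@dataclass
class ParticipationRatioResult:
    pr: float
    trace: float
    trace_sq: float
    n_channels: int


def participation_ratio(
    m: ConnectivityMatrix, weighted: bool = True
) -> ParticipationRatioResult:
    """Effective dimensionality of the input-connectivity covariance.

    The covariance is taken over input channels with outputs as
    observations, on synapse-weighted connectivity by default (input
    currents depend on synaptic weight); ``weighted=False`` uses the
    binarized matrix.  PR is invariant to channel permutation and to
    overall scaling of the matrix, and satisfies 1 <= PR <= rank(C).
    """
    if len(m.output_ids) < 2:
        raise ValueError("participation ratio needs at least 2 outputs")
    W = m.W if weighted else m.binarize().W
    if not np.any(W):
        raise ValueError("all-zero connectivity matrix")
    C = np.atleast_2d(np.cov(W))
    trace = float(np.trace(C))
    trace_sq = float(np.sum(C * C))  # tr(C^2) for symmetric C
    if trace_sq <= 0:
        raise ValueError("degenerate (zero-variance) connectivity")
    return ParticipationRatioResult(
        pr=trace**2 / trace_sq,
        trace=trace,
        trace_sq=trace_sq,
        n_channels=len(m.input_ids),
    )


@dataclass
class ConditionalInputResult:
    """Pairwise co-input counts, z-scores vs the shuffle null, and
    K-means groupings of inputs at each k."""

    input_ids: list[str]
    count: np.ndarray
    z: np.ndarray
    degenerate: np.ndarray
    clusterings: dict[int, np.ndarray]


def conditional_input_analysis(
    m: ConnectivityMatrix,
    cfg: ShuffleConfig,
    k_range: range = range(2, 11),
) -> ConditionalInputResult:
    """Count outputs receiving input A given input B, for all pairs.

    Each connection counts once regardless of synaptic weight, so the
    matrix is binarized.  count(A, B) = number of outputs receiving both A
    and B (count(A, A) = A's partner count).  The null mean and sd per
    pair come from ``cfg.n_shuffles`` marginal-preserving shuffles;
    z = (obs - mean) / sd, with sd = 0 reported as z = 0 and flagged.
    K-means (20 restarts, seeded) groups inputs by their z-profiles for
    each k in ``k_range``.
    """
    b = _binary_matrix(m)
    B = b.W
    count = B @ B.T

    rng = np.random.default_rng(cfg.seed)
    marginals = B.sum(axis=1)
    acc = np.zeros_like(count)
    acc2 = np.zeros_like(count)
    for _ in range(cfg.n_shuffles):
        S = _shuffle_binary(B, rng, marginals=marginals, method=cfg.method)
        c = S @ S.T
        acc += c
        acc2 += c * c
    mean = acc / cfg.n_shuffles
    var = np.clip(acc2 / cfg.n_shuffles - mean**2, 0.0, None)
    sd = np.sqrt(var)
    degenerate = sd == 0
    z = np.zeros_like(count)
    np.divide(count - mean, sd, out=z, where=~degenerate)
    if degenerate.any():
        logger.info(
            "conditional input: %d pairs have a degenerate (sd=0) null",
            int(degenerate.sum()),
        )

    n_inputs = len(b.input_ids)
    ks = [k for k in k_range if k <= n_inputs]
    if len(ks) < len(list(k_range)):
        warnings.warn(
            f"k_range truncated to k <= {n_inputs} inputs", stacklevel=2
        )
    clusterings: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=20, random_state=cfg.seed)
        clusterings[k] = km.fit_predict(z)
    return ConditionalInputResult(
        input_ids=list(b.input_ids),
        count=count,
        z=z,
        degenerate=degenerate,
        clusterings=clusterings,
    )


@dataclass
class OutputClusteringResult:
    """Spectral clustering of outputs with silhouette model selection."""

    output_ids: list[str]
    labels_per_k: dict[int, np.ndarray]
    silhouettes: dict[int, float]
    selected_k: int
    labels: np.ndarray
    no_clear_structure: bool
    excluded_outputs: list[str]
    row_order: np.ndarray
    col_order: np.ndarray


def cluster_outputs(
    m: ConnectivityMatrix,
    k_range: range = range(2, 11),
    seed: int = 0,
    silhouette_floor: float = 0.25,
) -> OutputClusteringResult:
    """Group outputs by binary input composition.

    Spectral clustering (cosine-similarity affinity between output input
    vectors) is run for each k; the silhouette score, computed with
    Euclidean distance on the binary input profiles, selects the best k.  A maximum silhouette below ``silhouette_floor`` raises
    the no-clear-structure flag.  Outputs with zero inputs are excluded
    with a notice.  Hierarchical co-clustering (average linkage, Jaccard
    distance) supplies row/column orders for heatmap export.
    """
    b = _binary_matrix(m)
    keep = b.W.sum(axis=0) > 0
    excluded = [o for o, k in zip(b.output_ids, keep) if not k]
    if excluded:
        logger.info("cluster_outputs: excluding %d outputs with zero inputs", len(excluded))
    X = b.W[:, keep].T  # outputs x inputs
    output_ids = [o for o, k in zip(b.output_ids, keep) if k]
    ks = [k for k in k_range if k + 1 <= len(output_ids)]
    if not ks:
        raise ValueError("not enough connected outputs for the requested k range")

    affinity = cosine_similarity(X)
    np.fill_diagonal(affinity, 1.0)
    labels_per_k: dict[int, np.ndarray] = {}
    silhouettes: dict[int, float] = {}
    for k in ks:
        sc = SpectralClustering(
            n_clusters=k,
            affinity="precomputed",
            assign_labels="kmeans",
            random_state=seed,
            n_init=20,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign graph-connectivity warnings
            labels = sc.fit_predict(affinity)
        labels_per_k[k] = labels
        if len(np.unique(labels)) < 2:
            silhouettes[k] = -1.0
        else:
            silhouettes[k] = float(silhouette_score(X, labels, metric="euclidean"))
    selected_k = max(ks, key=lambda k: (silhouettes[k], -k))
    best = silhouettes[selected_k]

    # Heatmap orders from hierarchical co-clustering of the binary matrix.
    row_order = _leaf_order(b.W[:, keep])
    col_order = _leaf_order(X)
    return OutputClusteringResult(
        output_ids=output_ids,
        labels_per_k=labels_per_k,
        silhouettes=silhouettes,
        selected_k=selected_k,
        labels=labels_per_k[selected_k],
        no_clear_structure=bool(best < silhouette_floor),
        excluded_outputs=excluded,
        row_order=row_order,
        col_order=col_order,
    )


def _leaf_order(M: np.ndarray) -> np.ndarray:
    if M.shape[0] < 3:
        return np.arange(M.shape[0])
    d = pdist(M.astype(bool), metric="jaccard")
    d = np.nan_to_num(d, nan=1.0)
    link = hierarchy.linkage(d, method="average")
    return np.asarray(hierarchy.leaves_list(link))
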
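"""Core data model for bipartite connectome wiring analysis.

The central object is :class:`ConnectivityMatrix`, a weighted input x output
synapse-count matrix with an explicit synapse-count threshold and
binarization state.  Everything downstream (shuffle nulls, spectrum tests,
participation ratio, conditional-input analysis) consumes this object.

Conventions
-----------
* Rows are presynaptic inputs (e.g. visual projection neurons and local
  visual interneurons), columns are postsynaptic outputs (e.g. Kenyon
  cells).
* The synapse threshold applies per (pre, post) pair *before* any
  aggregation; aggregation never resurrects sub-threshold edges.
* Identifier ordering is lexicographic everywhere, so all derived
  quantities are deterministic.
* Synapse locations, where present, are in nanometres as exported; no
  voxel/physical conversion is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIDES = ("left", "right")
SUPER_CLASSES = ("KC", "VPN", "LVIN", "OPN", "ORN", "other")
NEUROPILS = ("Me", "Lo", "aMe", "LoP", "ocellar", "none")


@dataclass(frozen=True)
class NeuronRecord:
    """Metadata for one neuron.

    ``neuropil_origin`` is meaningful only for visual projection neurons
    (their dendritic neuropil: medulla, lobula, accessory medulla, lobula
    plate or ocellar); for every other super-class it is ``"none"``.
    """

    neuron_id: str
    side: str = "left"
    super_class: str = "other"
    subtype: str = ""
    neuropil_origin: str = "none"
    nt_prediction: str | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.super_class not in SUPER_CLASSES:
            raise ValueError(
                f"super_class must be one of {SUPER_CLASSES}, got {self.super_class!r}"
            )
        if self.neuropil_origin not in NEUROPILS:
            raise ValueError(
                f"neuropil_origin must be one of {NEUROPILS}, got {self.neuropil_origin!r}"
            )
        if self.super_class != "VPN" and self.neuropil_origin != "none":
            raise ValueError("neuropil_origin is only defined for VPNs")


@dataclass(frozen=True)
class SynapseEdge:
    """One pre -> post connection with its synapse count.

    ``locations`` optionally carries one 3-D point (nm) per synapse, in
    which case its length must equal ``count``.
    """

    pre_id: str
    post_id: str
    count: int
    locations: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("synapse count must be >= 1")
        if self.locations is not None and len(self.locations) != self.count:
            raise ValueError(
                f"edge {self.pre_id}->{self.post_id}: {len(self.locations)} "
                f"locations for count {self.count}"
            )


@dataclass
class ConnectivityMatrix:
    """Thresholded synapse-count matrix, rows = inputs, cols = outputs."""

    input_ids: list[str]
    output_ids: list[str]
    W: np.ndarray
    threshold: int = 0
    binarized: bool = False

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.input_ids), len(self.output_ids)):
            raise ValueError(
                f"matrix shape {self.W.shape} does not match "
                f"{len(self.input_ids)} inputs x {len(self.output_ids)} outputs"
            )
        if np.any(self.W < 0):
            raise ValueError("synapse counts must be non-negative")
        if self.binarized and not np.isin(self.W, (0.0, 1.0)).all():
            raise ValueError("binarized matrix must contain only 0/1 entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape

    def binarize(self) -> "ConnectivityMatrix":
        """Return a 0/1 copy (identity if already binarized)."""
        if self.binarized:
            return self.copy()
        return replace(
            self,
            input_ids=list(self.input_ids),
            output_ids=list(self.output_ids),
            W=(self.W > 0).astype(float),
            binarized=True,
        )

    def copy(self) -> "ConnectivityMatrix":
        return replace(
            self,
            input_ids=list(self.input_ids),
            output_ids=list(self.output_ids),
            W=self.W.copy(),
        )

    def in_degrees(self) -> np.ndarray:
        """Number of distinct inputs per output (column-wise)."""
        return (self.W > 0).sum(axis=0)

    def input_degrees(self) -> np.ndarray:
        """Number of distinct outputs contacted per input (row-wise)."""
        return (self.W > 0).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.input_ids, columns=self.output_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, threshold: int = 0, binarized: bool = False
    ) -> "ConnectivityMatrix":
        return cls(
            input_ids=[str(i) for i in df.index],
            output_ids=[str(c) for c in df.columns],
            W=df.to_numpy(dtype=float),
            threshold=threshold,
            binarized=binarized,
        )


def build_matrix(
    edges: Iterable[SynapseEdge],
    inputs: Iterable[str],
    outputs: Iterable[str],
    threshold: int = 5,
    binarize: bool = False,
) -> ConnectivityMatrix:
    """Assemble a thresholded connectivity matrix from an edge list.

    Edges whose endpoints fall outside ``inputs``/``outputs`` are ignored;
    edges with fewer than ``threshold`` synapses are zeroed.  Duplicate
    (pre, post) pairs signal a malformed export and raise ``ValueError``.
    Row/column order is lexicographic by identifier.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    input_ids = sorted({str(i) for i in inputs})
    output_ids = sorted({str(o) for o in outputs})
    row = {nid: i for i, nid in enumerate(input_ids)}
    col = {nid: j for j, nid in enumerate(output_ids)}
    W = np.zeros((len(input_ids), len(output_ids)))
    seen: set[tuple[str, str]] = set()
    for e in edges:
        key = (str(e.pre_id), str(e.post_id))
        if key in seen:
            raise ValueError(f"duplicate edge {key[0]}->{key[1]} in export")
        seen.add(key)
        if key[0] not in row or key[1] not in col:
            continue
        if e.count >= threshold:
            W[row[key[0]], col[key[1]]] = e.count
    m = ConnectivityMatrix(input_ids, output_ids, W, threshold=threshold)
    return m.binarize() if binarize else m


@dataclass(frozen=True)
class TypeMap:
    """Mapping from neuron id to a type-class label, plus how to combine."""

    labels: Mapping[str, str]
    mode: str = "mean"

    def __post_init__(self) -> None:
        if self.mode not in ("sum", "mean"):
            raise ValueError(f"aggregation mode must be 'sum' or 'mean', got {self.mode!r}")

    def label(self, neuron_id: str) -> str:
        return self.labels[neuron_id]


def aggregate_by_type(m: ConnectivityMatrix, tmap: TypeMap) -> ConnectivityMatrix:
    """Condense matrix rows by cell type (sum or mean over same-type inputs).

    Every input id of ``m`` must be covered by ``tmap`` (singleton labels
    are allowed).  The output axis is unchanged; aggregated rows are ordered
    lexicographically by label.
    """
    missing = [i for i in m.input_ids if i not in tmap.labels]
    if missing:
        raise KeyError(f"type map does not cover input ids: {missing[:5]}")
    df = m.to_frame()
    grouped = df.groupby([tmap.labels[i] for i in m.input_ids], sort=True)
    agg = grouped.sum() if tmap.mode == "sum" else grouped.mean()
    values = agg.to_numpy(dtype=float)
    still_binary = m.binarized and bool(np.isin(values, (0.0, 1.0)).all())
    return ConnectivityMatrix(
        input_ids=[str(i) for i in agg.index],
        output_ids=list(m.output_ids),
        W=values,
        threshold=m.threshold,
        binarized=still_binary,
    )


@dataclass
class InputSummary:
    """Per-group, per-input and per-output composition summaries."""

    group_table: pd.DataFrame
    input_ranking: pd.DataFrame
    output_composition: pd.DataFrame
    n_connected_outputs: int


def summarize_inputs(
    m: ConnectivityMatrix, groups: Mapping[str, str]
) -> InputSummary:
    """Summarize synaptic contributions by input group.

    ``groups`` maps every input id to a group label (e.g. VPN vs LVIN, or
    neuropil of origin).  Returns per-group partner counts and synapse
    fractions, a ranking of inputs by total synaptic contribution
    (descending, ties broken by id), the per-output composition over groups
    (restricted to outputs that receive at least one input), and the
    percentage of outputs each input contacts.
    """
    missing = [i for i in m.input_ids if i not in groups]
    if missing:
        raise KeyError(f"groups does not cover input ids: {missing[:5]}")
    df = m.to_frame()
    totals = df.sum(axis=1)
    grand_total = float(totals.sum())
    if grand_total == 0:
        logger.warning("summarize_inputs: empty connectivity matrix")
    glabels = pd.Series({i: groups[i] for i in m.input_ids})

    connected = (df > 0).any(axis=1)
    by_group = pd.DataFrame(
        {
            "n_partners": connected.groupby(glabels).sum(),
            "synapse_total": totals.groupby(glabels).sum(),
        }
    )
    by_group["synapse_fraction"] = (
        by_group["synapse_total"] / grand_total if grand_total > 0 else 0.0
    )

    n_out = len(m.output_ids)
    ranking = pd.DataFrame(
        {
            "input_id": m.input_ids,
            "group": [groups[i] for i in m.input_ids],
            "synapse_total": totals.to_numpy(),
            "n_outputs_contacted": (df > 0).sum(axis=1).to_numpy(),
        }
    )
    ranking["pct_outputs_contacted"] = (
        100.0 * ranking["n_outputs_contacted"] / n_out if n_out else 0.0
    )
    ranking = ranking.sort_values(
        ["synapse_total", "input_id"], ascending=[False, True]
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    per_output = df.groupby(glabels.to_numpy()).sum().T  # outputs x groups
    received = per_output.sum(axis=1)
    per_output = per_output.loc[received > 0]
    composition = per_output.div(per_output.sum(axis=1), axis=0)

    return InputSummary(
        group_table=by_group,
        input_ranking=ranking,
        output_composition=composition,
        n_connected_outputs=int((received > 0).sum()),
    )


def greedy_one_to_one_matching(scores: pd.DataFrame) -> dict[str, str]:
    """Resolve morphology-score matches to a one-to-one query->target map.

    ``scores`` has columns ``query_id``, ``target_id``, ``score`` (one row
    per candidate pair, scores in [0, 1]).  Each query is first paired with
    its highest-scoring target; when several queries claim the same target
    the strongest score wins and the losers fall back to their next-best
    available target, iterating until the mapping is one-to-one.  Ties are
    broken lexicographically (by target id within a query's candidate list,
    by query id between competing queries).  A query that exhausts all its
    candidates maps to ``"unmatched"``.
    """
    required = {"query_id", "target_id", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    if not np.isfinite(scores["score"]).all():
        raise ValueError("scores must be finite")

    candidates: dict[str, list[tuple[float, str]]] = {}
    for qid, sub in scores.groupby("query_id", sort=True):
        ordered = sub.sort_values(["score", "target_id"], ascending=[False, True])
        candidates[str(qid)] = [
            (float(s), str(t)) for s, t in zip(ordered["score"], ordered["target_id"])
        ]
        if not candidates[str(qid)]:
            raise ValueError(f"query {qid} has no candidate targets")

    # Deferred acceptance with a common target-side preference (the score):
    # a target tentatively holds its strongest claimant; a displaced query
    # falls back to its next-best candidate.  The fixed point is the greedy
    # descending-score assignment and is independent of processing order.
    pointer = {q: 0 for q in candidates}
    holder: dict[str, tuple[float, str]] = {}
    assignment: dict[str, str] = {}
    free = sorted(candidates)
    while free:
        q = free.pop(0)
        placed = False
        while pointer[q] < len(candidates[q]):
            score, target = candidates[q][pointer[q]]
            incumbent = holder.get(target)
            if incumbent is None or (-score, q) < (-incumbent[0], incumbent[1]):
                holder[target] = (score, q)
                if incumbent is not None:
                    loser = incumbent[1]
                    pointer[loser] += 1
                    free.append(loser)
                placed = True
                break
            pointer[q] += 1
        if not placed:
            assignment[q] = "unmatched"
    for target, (_, q) in holder.items():
        assignment[q] = target
    return assignment
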
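"""Synthetic connectome generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: bipartite
input->output wiring matrices under three wiring hypotheses (labeled-line
channels, biased mixtures, random mixtures), left/right hemisphere pairs
with controllable stereotypy, 3-D synapse-location clouds of the two
morphological connection classes (bouton-claw vs en-passant), and a
hex-grid eyemap with point-cloud skeletons carrying planted receptive
fields.  All generators are pure functions of (spec, seed).

The default study conditions mirror the measured circuit: 74 visual inputs
onto 147 Kenyon cells, per-cell in-degrees of 1-7 with median 3, a >= 5
synapse threshold, and a 759-column eyemap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import ConnectivityMatrix, TypeMap

#: In-degree law matching the observed per-KC visual input counts
#: (1-7 unique inputs, median 3).
DEFAULT_INDEGREES = (1, 2, 2, 3, 3, 3, 4, 4, 5, 6, 7)

WIRING_MODELS = ("random", "labeled_line", "biased_mixture")


@dataclass
class WiringSpec:
    """Parameters for one bipartite wiring draw.

    ``input_probs`` is the relative availability of each input channel
    (uniform if omitted).  ``indegree_dist`` is either a fixed integer or a
    sequence resampled empirically per output.  ``model`` selects the wiring
    hypothesis; ``model_params`` carries the community count / assignment
    for ``labeled_line`` (key ``n_communities`` or ``communities``, plus
    ``noise`` for off-community contamination) and the per-input bias
    vector for ``biased_mixture`` (key ``bias``).
    """

    n_inputs: int = 74
    n_outputs: int = 147
    input_probs: np.ndarray | None = None
    indegree_dist: int | Sequence[int] = DEFAULT_INDEGREES
    model: str = "random"
    model_params: dict = field(default_factory=dict)
    threshold: int = 5
    count_geom_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in WIRING_MODELS:
            raise ValueError(f"model must be one of {WIRING_MODELS}")
        if self.input_probs is None:
            self.input_probs = np.full(self.n_inputs, 1.0 / self.n_inputs)
        self.input_probs = np.asarray(self.input_probs, dtype=float)
        if self.input_probs.shape != (self.n_inputs,):
            raise ValueError("input_probs must have length n_inputs")
        if np.any(self.input_probs < 0) or not np.isclose(self.input_probs.sum(), 1.0):
            raise ValueError("input_probs must be a probability vector")
        degrees = (
            [self.indegree_dist]
            if np.isscalar(self.indegree_dist)
            else list(self.indegree_dist)
        )
        if max(degrees) > self.n_inputs:
            raise ValueError("in-degree cannot exceed number of inputs")


@dataclass
class WiringTruth:
    """Ground truth recorded alongside a generated matrix."""

    input_communities: np.ndarray | None = None
    output_communities: np.ndarray | None = None
    sampling_probs: np.ndarray | None = None


def _draw_indegree(spec: WiringSpec, rng: np.random.Generator) -> int:
    if np.isscalar(spec.indegree_dist):
        return int(spec.indegree_dist)
    choices = np.asarray(spec.indegree_dist, dtype=int)
    return int(rng.choice(choices))


def _weighted_distinct(
    rng: np.random.Generator, probs: np.ndarray, k: int
) -> np.ndarray:
    support = int((probs > 0).sum())
    if k > support:
        raise ValueError(
            f"in-degree {k} exceeds the {support} inputs with nonzero probability"
        )
    return rng.choice(len(probs), size=k, replace=False, p=probs / probs.sum())


def _synapse_counts(
    rng: np.random.Generator, n: int, threshold: int, geom_p: float
) -> np.ndarray:
    # Shifted geometric: threshold + Geom(p) - 1, so every retained edge
    # clears the synapse threshold.  Structural statistics binarize anyway.
    base = max(threshold, 1)
    return base + rng.geometric(geom_p, size=n) - 1


def generate_wiring(spec: WiringSpec) -> tuple[ConnectivityMatrix, WiringTruth]:
    """Draw one connectivity matrix under the spec's wiring hypothesis.

    Each output draws its in-degree, then samples that many distinct
    inputs:

    * ``random`` — with probability proportional to ``input_probs``;
    * ``labeled_line`` — only within its assigned input community, with
      each draw escaping to the full input pool at rate
      ``model_params["noise"]``;
    * ``biased_mixture`` — ``input_probs`` reweighted by the bias vector.

    Synapse counts ride above the threshold on a shifted geometric.
    Returns the matrix and the ground truth (community assignments and
    effective sampling probabilities).
    """
    rng = np.random.default_rng(spec.seed)
    probs = spec.input_probs.copy()
    truth = WiringTruth()

    if spec.model == "biased_mixture":
        bias = np.asarray(spec.model_params.get("bias"), dtype=float)
        if bias.shape != (spec.n_inputs,) or np.any(bias < 0):
            raise ValueError("biased_mixture requires a non-negative bias vector")
        probs = probs * bias
        if probs.sum() <= 0:
            raise ValueError("bias annihilates all input probability")
        probs = probs / probs.sum()
    truth.sampling_probs = probs.copy()

    in_comm = out_comm = None
    noise = 0.0
    if spec.model == "labeled_line":
        noise = float(spec.model_params.get("noise", 0.0))
        if "communities" in spec.model_params:
            in_comm = np.asarray(spec.model_params["communities"], dtype=int)
            if in_comm.shape != (spec.n_inputs,):
                raise ValueError("community assignment must cover all inputs")
        else:
            n_comm = int(spec.model_params.get("n_communities", 4))
            in_comm = np.arange(spec.n_inputs) % n_comm
        labels = np.unique(in_comm)
        out_comm = labels[rng.integers(len(labels), size=spec.n_outputs)]
        truth.input_communities = in_comm
        truth.output_communities = out_comm

    W = np.zeros((spec.n_inputs, spec.n_outputs))
    for j in range(spec.n_outputs):
        k = _draw_indegree(spec, rng)
        if spec.model == "labeled_line":
            mask = in_comm == out_comm[j]
            # Each slot escapes its community at the contamination rate.
            chosen: list[int] = []
            avail = probs.copy()
            for _ in range(k):
                pool = avail.copy()
                if rng.random() >= noise:
                    pool[~mask] = 0.0
                if pool.sum() <= 0:
                    raise ValueError(
                        f"in-degree {k} exhausts the inputs available to output {j}"
                    )
                pick = int(rng.choice(spec.n_inputs, p=pool / pool.sum()))
                chosen.append(pick)
                avail[pick] = 0.0
            idx = np.asarray(chosen, dtype=int)
        else:
            idx = _weighted_distinct(rng, probs, k)
        W[idx, j] = _synapse_counts(rng, len(idx), spec.threshold, spec.count_geom_p)

    input_ids = [f"in{str(i).zfill(3)}" for i in range(spec.n_inputs)]
    output_ids = [f"out{str(j).zfill(3)}" for j in range(spec.n_outputs)]
    m = ConnectivityMatrix(input_ids, output_ids, W, threshold=spec.threshold)
    return m, truth


def generate_bilateral_pair(
    spec: WiringSpec, stereotypy: str = "independent"
) -> tuple[ConnectivityMatrix, ConnectivityMatrix, TypeMap]:
    """Draw a left/right hemisphere pair of wiring matrices.

    ``mirrored`` copies one random draw to both hemispheres (the
    bilaterally stereotyped model); ``independent`` draws each hemisphere
    separately with identical marginal laws.  The returned TypeMap pairs
    input i of the left matrix with input i of the right matrix under a
    shared type label.
    """
    if stereotypy not in ("independent", "mirrored"):
        raise ValueError("stereotypy must be 'independent' or 'mirrored'")
    left, _ = generate_wiring(spec)
    if stereotypy == "mirrored":
        right = left.copy()
    else:
        rng = np.random.default_rng(spec.seed)
        right_seed = int(rng.integers(2**31 - 1)) ^ 0x5EED
        right_spec = WiringSpec(
            n_inputs=spec.n_inputs,
            n_outputs=spec.n_outputs,
            input_probs=spec.input_probs,
            indegree_dist=spec.indegree_dist,
            model=spec.model,
            model_params=spec.model_params,
            threshold=spec.threshold,
            count_geom_p=spec.count_geom_p,
            seed=right_seed,
        )
        right, _ = generate_wiring(right_spec)
    left.input_ids = [f"L_{i}" for i in left.input_ids]
    left.output_ids = [f"L_{o}" for o in left.output_ids]
    right.input_ids = [f"R_{i}" for i in right.input_ids]
    right.output_ids = [f"R_{o}" for o in right.output_ids]
    labels = {}
    for lid, rid in zip(left.input_ids, right.input_ids):
        shared = lid[2:]
        labels[lid] = shared
        labels[rid] = shared
    return left, right, TypeMap(labels=labels, mode="sum")


CLOUD_CLASSES = ("bouton_claw", "en_passant")


@dataclass
class CloudSpec:
    """One synthetic synapse-location cloud.

    ``scale`` is the bouton radius sigma (nm) for ``bouton_claw`` and the
    passage length L (nm) for ``en_passant``.
    """

    cloud_class: str
    n_synapses: int
    scale: float
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cloud_class not in CLOUD_CLASSES:
            raise ValueError(f"cloud class must be one of {CLOUD_CLASSES}")
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def generate_synapse_cloud(spec: CloudSpec) -> np.ndarray:
    """Sample 3-D synapse locations (nm) for one pre->post connection.

    Bouton-claw synapses cluster isotropically (Gaussian, sd = scale)
    around a bouton centre; en-passant synapses spread uniformly along a
    straight axon segment of length ``scale``, with optional isotropic
    jitter, in a random orientation.
    """
    rng = np.random.default_rng(spec.seed)
    center = rng.uniform(-1e5, 1e5, size=3)
    if spec.cloud_class == "bouton_claw":
        return center + rng.normal(scale=spec.scale, size=(spec.n_synapses, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = rng.uniform(-spec.scale / 2.0, spec.scale / 2.0, size=spec.n_synapses)
    pts = center + t[:, None] * direction[None, :]
    if spec.jitter > 0:
        pts = pts + rng.normal(scale=spec.jitter, size=pts.shape)
    return pts


@dataclass
class SyntheticEye:
    """Hex-grid patch eyemap with planted receptive fields.

    ``directions`` are unit view-direction vectors, one per ommatidial
    column; ``marker_positions`` are the corresponding columnar marker
    points in tissue coordinates (nm).
    """

    column_ids: list[str]
    directions: np.ndarray
    marker_positions: np.ndarray


def make_hex_eye(
    n_columns: int = 759,
    angular_spacing_deg: float = 2.0,
    marker_radius_nm: float = 2.5e5,
) -> SyntheticEye:
    """Build a hexagonal patch of ommatidial columns on the unit sphere.

    A planar hex lattice (spacing = ``angular_spacing_deg`` in gnomonic
    coordinates) centred on the +x axis is projected back to the sphere;
    the ``n_columns`` columns nearest the patch centre are kept.  Markers
    sit at ``marker_radius_nm`` along each view direction, so angular and
    tissue geometry are consistent.
    """
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    s = np.tan(np.radians(angular_spacing_deg))
    # Generous hex lattice, then trim to the n nearest the centre.
    half = int(np.ceil(np.sqrt(n_columns))) + 2
    pts = []
    for row in range(-half, half + 1):
        for col in range(-half, half + 1):
            y = s * (col + 0.5 * (row % 2))
            z = s * row * np.sqrt(3) / 2.0
            pts.append((y, z))
    pts = np.asarray(pts)
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    pts = pts[order[:n_columns]]
    dirs = np.column_stack([np.ones(len(pts)), pts[:, 0], pts[:, 1]])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    ids = [f"col{str(i).zfill(4)}" for i in range(len(dirs))]
    return SyntheticEye(
        column_ids=ids,
        directions=dirs,
        marker_positions=dirs * marker_radius_nm,
    )


@dataclass
class PlantedRF:
    """A disc-shaped true receptive field for one synthetic neuron."""

    neuron_id: str
    center_column: int
    radius_deg: float


@dataclass
class SyntheticVisualSystem:
    eye: SyntheticEye
    skeletons: dict[str, np.ndarray]
    true_covered: dict[str, set[str]]
    true_threshold_nm: float


def generate_visual_system(
    eye: SyntheticEye,
    rf_specs: Sequence[PlantedRF],
    true_threshold_nm: float = 4000.0,
    points_per_column: int = 3,
    seed: int = 0,
) -> SyntheticVisualSystem:
    """Plant neurons with known receptive fields on an eyemap.

    For each spec, the true covered set is every column whose view
    direction lies within ``radius_deg`` of the centre column's direction.
    Dendritic points are scattered within ``true_threshold_nm`` / 2 of each
    covered column's marker, so proximity coverage at the true threshold
    recovers the planted field.
    """
    rng = np.random.default_rng(seed)
    skeletons: dict[str, np.ndarray] = {}
    covered: dict[str, set[str]] = {}
    for spec in rf_specs:
        if not 0 <= spec.center_column < len(eye.column_ids):
            raise ValueError(f"rf centre {spec.center_column} outside the eye patch")
        center_dir = eye.directions[spec.center_column]
        cosang = eye.directions @ center_dir
        members = np.where(cosang >= np.cos(np.radians(spec.radius_deg)))[0]
        if len(members) == 0:
            raise ValueError("planted rf covers no columns")
        pts = []
        for col in members:
            offsets = rng.normal(size=(points_per_column, 3))
            offsets /= np.linalg.norm(offsets, axis=1, keepdims=True)
            radii = rng.uniform(0, true_threshold_nm / 2.0, size=points_per_column)
            pts.append(eye.marker_positions[col] + offsets * radii[:, None])
        skeletons[spec.neuron_id] = np.vstack(pts)
        covered[spec.neuron_id] = {eye.column_ids[i] for i in members}
    return SyntheticVisualSystem(
        eye=eye,
        skeletons=skeletons,
        true_covered=covered,
        true_threshold_nm=true_threshold_nm,
    )
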
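"""Receptive-field estimation from skeleton-to-column proximity.

An eyemap assigns every ommatidial column a unit view-direction vector and
a columnar marker point in tissue coordinates (nm).  A neuron's receptive
field is estimated by (1) collecting the columns whose marker lies within
a distance threshold of any skeleton point, (2) taking the spherical
convex hull of those columns' view directions (via gnomonic projection
about the covered-set centroid), and (3) counting every eyemap column
inside the hull.  RF size is reported in ommatidial columns.

The distance threshold is calibrated per neuropil layer against
hand-annotated column sets by maximizing Jaccard overlap.  Mollweide map
coordinates are provided for display, and synapse-weighted effective RFs
compose a Kenyon cell's visual field from its direct and LVIN-relayed
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .model import ConnectivityMatrix
from .synthetic import SyntheticEye

logger = logging.getLogger(__name__)


@dataclass
class EyeMap:
    """Ommatidial columns as view directions plus per-layer markers."""

    column_ids: list[str]
    directions: np.ndarray
    marker_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("view directions must be unit vectors (|v| = 1 ± 1e-9)")
        for layer, pos in self.marker_positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (len(self.column_ids), 3):
                raise ValueError(f"layer {layer!r}: one marker per column required")
            self.marker_positions[layer] = pos

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    @classmethod
    def from_synthetic(cls, eye: SyntheticEye, layer: str = "M5") -> "EyeMap":
        return cls(
            column_ids=list(eye.column_ids),
            directions=eye.directions.copy(),
            marker_positions={layer: eye.marker_positions.copy()},
        )


@dataclass
class ReceptiveField:
    """Covered columns, their spherical hull, size and centroid."""

    covered: set[str]
    hull_columns: set[str]
    size: int
    centroid: np.ndarray


def covered_columns(
    skeleton_points: np.ndarray,
    eye: EyeMap,
    layer: str,
    threshold_nm: float,
) -> set[str]:
    """Columns whose marker lies within ``threshold_nm`` of the skeleton.

    Distance is the minimum point-to-marker Euclidean distance in nm over
    all skeleton points (no skeleton resampling is performed, so coverage
    depends on the export's node density).  Monotone in the threshold.
    """
    if threshold_nm < 0:
        raise ValueError("threshold_nm must be >= 0")
    pts = np.atleast_2d(np.asarray(skeleton_points, dtype=float))
    if pts.size == 0:
        logger.warning("covered_columns: empty skeleton")
        return set()
    markers = eye.marker_positions[layer]
    dist, _ = cKDTree(pts).query(markers)
    return {cid for cid, d in zip(eye.column_ids, dist) if d <= threshold_nm}


def _gnomonic(directions: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Project directions onto the tangent plane at ``center``."""
    e1 = np.cross(center, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-12:
        e1 = np.cross(center, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(center, e1)
    t = directions @ center
    scaled = directions / t[:, None]
    return np.column_stack([scaled @ e1, scaled @ e2])


def rf_from_columns(covered: set[str], eye: EyeMap) -> ReceptiveField:
    """Spherical convex hull of the covered columns' view directions.

    The hull is taken in the gnomonic (tangent-plane) projection about the
    normalized mean direction of the covered set, which is faithful for
    fields spanning less than a hemisphere; covered sets spanning more
    than 150 degrees of visual angle are rejected.  ``hull_columns`` is
    every eyemap column whose direction falls inside the hull (covered
    columns included); size = |hull_columns| in ommatidial columns.
    """
    if not covered:
        raise ValueError("covered column set is empty")
    idx = {cid: i for i, cid in enumerate(eye.column_ids)}
    unknown = covered - idx.keys()
    if unknown:
        raise KeyError(f"columns not in eyemap: {sorted(unknown)[:5]}")
    rows = sorted(idx[c] for c in covered)
    dirs = eye.directions[rows]
    centroid = dirs.mean(axis=0)
    nrm = np.linalg.norm(centroid)
    if nrm < 1e-12:
        raise ValueError("covered columns are antipodally balanced; no centroid")
    centroid = centroid / nrm
    cosang = dirs @ centroid
    if np.any(cosang < np.cos(np.radians(75.0))):
        raise ValueError(
            "covered set spans more than 150 degrees of visual angle; "
            "gnomonic hull is not defined"
        )
    if len(rows) == 1:
        only = {eye.column_ids[rows[0]]}
        return ReceptiveField(covered=set(covered), hull_columns=only, size=1,
                              centroid=eye.directions[rows[0]].copy())

    planar = _gnomonic(dirs, centroid)
    try:
        hull = ConvexHull(planar)
        equations = hull.equations
    except QhullError:
        # Degenerate (collinear) covered set: fall back to the covered
        # columns themselves.
        logger.info("rf_from_columns: degenerate hull, using covered set")
        return ReceptiveField(
            covered=set(covered),
            hull_columns=set(covered),
            size=len(covered),
            centroid=centroid,
        )
    # Candidate columns must sit in front of the tangent plane.
    front = eye.directions @ centroid > np.cos(np.radians(89.0))
    cand = np.flatnonzero(front)
    proj = _gnomonic(eye.directions[cand], centroid)
    inside = np.all(
        proj @ equations[:, :2].T + equations[:, 2][None, :] <= 1e-9, axis=1
    )
    hull_cols = {eye.column_ids[i] for i in cand[inside]} | set(covered)
    return ReceptiveField(
        covered=set(covered),
        hull_columns=hull_cols,
        size=len(hull_cols),
        centroid=centroid,
    )


def calibrate_rf_threshold(
    ground_truth: Sequence[tuple[np.ndarray, set[str]]],
    eye: EyeMap,
    layer: str,
    grid: Sequence[float],
) -> tuple[float, dict[float, float]]:
    """Distance threshold maximizing mean Jaccard overlap with annotations.

    ``ground_truth`` holds (skeleton points, annotated column set) pairs
    for one neuropil layer; thresholds are calibrated per layer since
    marker geometry differs between medulla and lobula.  Returns the best
    threshold (smallest on ties) and the per-threshold mean Jaccard table.
    """
    if not ground_truth:
        raise ValueError("empty ground truth")
    if not len(grid):
        raise ValueError("empty threshold grid")
    scores: dict[float, float] = {}
    for t in sorted(grid):
        js = []
        for skeleton, annotated in ground_truth:
            est = covered_columns(skeleton, eye, layer, t)
            union = est | annotated
            js.append(len(est & annotated) / len(union) if union else 1.0)
        scores[float(t)] = float(np.mean(js))
    best = max(scores, key=lambda t: (scores[t], -t))
    return best, scores


@dataclass(frozen=True)
class ProjectionConfig:
    """Mollweide projection parameters.

    ``R`` scales the map; ``tol`` bounds the Newton iteration solving the
    auxiliary angle equation 2*theta + sin(2*theta) = pi * sin(phi).
    Conventions: equator phi = 0, frontal midline lambda = 0.
    """

    R: float = 1.0
    tol: float = 1e-12
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def mollweide_project(
    directions: np.ndarray, cfg: ProjectionConfig = ProjectionConfig()
) -> np.ndarray:
    """Equal-area Mollweide map coordinates for unit view directions.

    x = (2*sqrt(2)/pi) * R * lambda * cos(theta),  y = sqrt(2) * R *
    sin(theta), with theta solved by Newton iteration; the poles are
    handled analytically (theta = +/- pi/2).
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(dirs, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise ValueError("directions must be unit vectors")
    phi = np.arcsin(np.clip(dirs[:, 2], -1.0, 1.0))
    lam = np.arctan2(dirs[:, 1], dirs[:, 0])

    theta = phi.copy()
    target = np.pi * np.sin(phi)
    at_pole = np.abs(np.abs(phi) - np.pi / 2) < 1e-12
    active = ~at_pole
    for _ in range(cfg.max_iter):
        if not active.any():
            break
        f = 2 * theta[active] + np.sin(2 * theta[active]) - target[active]
        fp = 2 + 2 * np.cos(2 * theta[active])
        step = f / fp
        theta[active] -= step
        conv = np.abs(step) < cfg.tol
        idx = np.flatnonzero(active)
        active[idx[conv]] = False
    theta[at_pole] = np.sign(phi[at_pole]) * np.pi / 2

    x = (2 * np.sqrt(2) / np.pi) * cfg.R * lam * np.cos(theta)
    y = np.sqrt(2) * cfg.R * np.sin(theta)
    return np.column_stack([x, y])


def effective_rf(
    kc_id: str,
    direct_matrix: ConnectivityMatrix,
    lvin_to_kc: ConnectivityMatrix | None,
    vpn_to_lvin: ConnectivityMatrix | None,
    rfs: Mapping[str, ReceptiveField],
    eye: EyeMap,
    normalize: bool = False,
) -> dict[str, np.ndarray]:
    """Synapse-weighted composite receptive field of one Kenyon cell.

    The direct component sums each incident VPN's hull indicator field
    weighted by its VPN->KC synapse count.  The indirect component sums
    each incident LVIN's field weighted by its LVIN->KC synapse count,
    where an LVIN's field is the VPN->LVIN-synapse-weighted sum of its VPN
    inputs' indicator fields, normalized per LVIN so direct and indirect
    components are on comparable scales.  Fields are vectors over eyemap
    columns; with ``normalize=True`` each nonzero component sums to 1.
    """
    col_index = {cid: i for i, cid in enumerate(eye.column_ids)}
    n = eye.n_columns

    def indicator(neuron: str) -> np.ndarray:
        rf = rfs[neuron]
        out = np.zeros(n)
        for c in rf.hull_columns:
            out[col_index[c]] = 1.0
        return out

    direct = np.zeros(n)
    j = direct_matrix.output_ids.index(kc_id)
    for i, vpn in enumerate(direct_matrix.input_ids):
        w = direct_matrix.W[i, j]
        if w > 0:
            direct += w * indicator(vpn)

    indirect = np.zeros(n)
    if lvin_to_kc is not None and vpn_to_lvin is not None and kc_id in lvin_to_kc.output_ids:
        jk = lvin_to_kc.output_ids.index(kc_id)
        for li, lvin in enumerate(lvin_to_kc.input_ids):
            w_lk = lvin_to_kc.W[li, jk]
            if w_lk <= 0 or lvin not in vpn_to_lvin.output_ids:
                continue
            jl = vpn_to_lvin.output_ids.index(lvin)
            lvin_field = np.zeros(n)
            for vi, vpn in enumerate(vpn_to_lvin.input_ids):
                w_vl = vpn_to_lvin.W[vi, jl]
                if w_vl > 0 and vpn in rfs:
                    lvin_field += w_vl * indicator(vpn)
            total = lvin_field.sum()
            if total > 0:
                indirect += w_lk * (lvin_field / total)

    if direct.sum() == 0 and indirect.sum() == 0:
        logger.info("effective_rf: %s receives no visual input; empty fields", kc_id)
    if normalize:
        if direct.sum() > 0:
            direct = direct / direct.sum()
        if indirect.sum() > 0:
            indirect = indirect / indirect.sum()
    return {"direct": direct, "indirect": indirect}


def rf_size_weight_correlation(
    sizes: Sequence[float], synapse_sums: Sequence[float]
) -> float:
    """Pearson correlation between RF sizes and synapse sums."""
    from scipy.stats import pearsonr

    r, _ = pearsonr(np.asarray(sizes, float), np.asarray(synapse_sums, float))
    return float(r)


def plot_mollweide(
    field: np.ndarray,
    eye: EyeMap,
    path: str,
    cfg: ProjectionConfig = ProjectionConfig(),
) -> None:
    """Write a Mollweide scatter of a per-column field with equator and
    frontal-midline reference curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = mollweide_project(eye.directions, cfg)
    fig, ax = plt.subplots(figsize=(7, 4))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=field, s=12, cmap="viridis")
    lam = np.linspace(-np.pi, np.pi, 361)
    eq = np.column_stack([np.cos(lam), np.sin(lam), np.zeros_like(lam)])
    eq_xy = mollweide_project(eq, cfg)
    ax.plot(eq_xy[:, 0], eq_xy[:, 1], color="0.6", lw=0.8)
    phi = np.linspace(-np.pi / 2, np.pi / 2, 181)
    mid = np.column_stack([np.cos(phi), np.zeros_like(phi), np.sin(phi)])
    mid_xy = mollweide_project(mid, cfg)
    ax.plot(mid_xy[:, 0], mid_xy[:, 1], color="0.6", lw=0.8)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.colorbar(sc, ax=ax, shrink=0.7, label="field weight")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
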
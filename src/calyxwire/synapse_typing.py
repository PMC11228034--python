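"""Classification of connections as bouton-claw vs en-passant.

A presynaptic bouton wrapped by a dendritic claw concentrates its synapses
in a small ball, while en-passant contacts are strung out along the axon.
The classifier therefore uses a single geometric statistic per pre->post
connection: the population variance of synapse distances from the synapse
centroid (nm^2).  A dispersion threshold is calibrated on labeled ground
truth (train/test split) and applied to unlabeled connections.

Connections with fewer than 3 synapses are left unclassified: any
two-point cloud has dispersion identically zero (both points sit at d/2
from the centroid), so the statistic carries no information there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

LABELS = ("bouton_claw", "en_passant", "unclassified")


def dispersion_statistic(points: np.ndarray) -> float:
    """Population variance of point-to-centroid distances (nm^2).

    Invariant to rigid rotation and translation; scales as s^2 under
    spatial scaling by s.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("dispersion needs at least one point")
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    return float(np.mean((d - d.mean()) ** 2))


@dataclass
class SynapseTypeCall:
    pre_id: str
    post_id: str
    n_synapses: int
    dispersion: float
    label: str


@dataclass
class CalibrationResult:
    threshold: float
    train_accuracy: float
    test_accuracy: float
    n_train: int
    n_test: int


def _best_threshold(disp: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Dispersion cutoff maximizing accuracy of `bouton iff dispersion < t`.

    Candidates are midpoints between consecutive order statistics (plus
    one below the minimum and one above the maximum); among maximizers the
    smallest cutoff is returned.
    """
    order = np.argsort(disp, kind="stable")
    d = disp[order]
    is_bouton = labels[order] == "bouton_claw"
    cuts = [d[0] - 1.0]
    cuts += [0.5 * (a + b) for a, b in zip(d[:-1], d[1:])]
    cuts.append(d[-1] + 1.0)
    best_t, best_acc = cuts[0], -1.0
    for t in cuts:
        pred_bouton = d < t
        acc = float(np.mean(pred_bouton == is_bouton))
        if acc > best_acc:
            best_t, best_acc = t, acc
    return best_t, best_acc


def calibrate_and_classify(
    labeled: Sequence[tuple[np.ndarray, str]],
    unlabeled: Sequence[tuple[str, str, np.ndarray]] = (),
    split: float = 0.5,
    seed: int = 0,
) -> tuple[CalibrationResult, list[SynapseTypeCall]]:
    """Calibrate a dispersion cutoff on ground truth and classify new pairs.

    ``labeled`` holds (points, label) pairs with labels in
    {bouton_claw, en_passant}; ``unlabeled`` holds (pre_id, post_id,
    points).  The ground truth is split (stratified, seeded) into a
    training fraction ``split`` and a held-out test set; the cutoff is the
    midpoint between the best-separating training order statistics, and
    the reported test accuracy comes from the held-out set only.
    Classification is monotone in dispersion: below the cutoff ->
    bouton_claw, at or above -> en_passant; clouds of < 3 synapses ->
    unclassified.
    """
    if not labeled:
        raise ValueError("empty labeled set")
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    labels = np.array([lab for _, lab in labeled])
    classes = set(labels)
    if not {"bouton_claw", "en_passant"} <= classes:
        raise ValueError("ground truth must contain both synapse classes")
    disp = np.array([dispersion_statistic(p) for p, _ in labeled])

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(classes):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = max(1, int(round(split * len(idx))))
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else n_train
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx = np.asarray(sorted(train_idx))
    test_idx = np.asarray(sorted(test_idx))

    threshold, train_acc = _best_threshold(disp[train_idx], labels[train_idx])
    if len(test_idx):
        pred = np.where(disp[test_idx] < threshold, "bouton_claw", "en_passant")
        test_acc = float(np.mean(pred == labels[test_idx]))
    else:
        test_acc = float("nan")

    calls = []
    for pre, post, pts in unlabeled:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = dispersion_statistic(pts)
        if pts.shape[0] < 3:
            lab = "unclassified"
        else:
            lab = "bouton_claw" if d < threshold else "en_passant"
        calls.append(
            SynapseTypeCall(
                pre_id=pre,
                post_id=post,
                n_synapses=pts.shape[0],
                dispersion=d,
                label=lab,
            )
        )
    result = CalibrationResult(
        threshold=threshold,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )
    return result, calls


def type_shares_by_group(
    calls: Sequence[SynapseTypeCall], groups: Mapping[str, str]
) -> dict[str, dict[str, float]]:
    """Fraction of classified connections of each type, per input group
    (e.g. VPN vs LVIN presynaptic class)."""
    shares: dict[str, dict[str, float]] = {}
    for g in sorted(set(groups.values())):
        sub = [c for c in calls if groups.get(c.pre_id) == g and c.label != "unclassified"]
        n = len(sub)
        shares[g] = {
            "bouton_claw": sum(c.label == "bouton_claw" for c in sub) / n if n else 0.0,
            "en_passant": sum(c.label == "en_passant" for c in sub) / n if n else 0.0,
            "n_classified": float(n),
        }
    return shares
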
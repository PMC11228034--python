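"""End-to-end orchestration: configuration, staging, artifacts, manifest.

``run_pipeline`` executes the full analysis in order — matrix assembly,
input summaries, spectrum and bilateral shuffle tests, participation
ratio, conditional input analysis, output clustering, synapse typing
(when synapse locations are present) and receptive fields (when an eyemap
and skeletons are present).  Missing optional inputs skip their stage
with a logged notice.  Every stochastic stage consumes a seed derived
deterministically from the global seed and the stage name, and every
artifact is written alongside a manifest carrying the config hash, so
reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cwio
from .model import ConnectivityMatrix, build_matrix
from .null_models import ShuffleConfig, bilateral_identity_test, pca_spectrum_test
from .receptive_fields import EyeMap, calibrate_rf_threshold, covered_columns, rf_from_columns
from .structure import cluster_outputs, conditional_input_analysis, participation_ratio
from .synapse_typing import calibrate_and_classify
from .synthetic import WiringSpec, generate_bilateral_pair, generate_wiring

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """All knobs of one reproducible run.

    In real-data mode ``edges_path`` (and optionally ``right_edges_path``,
    ``locations_path``, ``eyemap_path``, ``skeleton_dir``) point at
    exports; otherwise the synthetic generator supplies every input.
    """

    out_dir: str = "calyxwire_run"
    seed: int = 0
    synapse_threshold: int = 5
    n_shuffles: int = 1000
    k_min: int = 2
    k_max: int = 10
    rf_layer: str = "M5"
    rf_threshold_nm: float | None = None
    edges_path: str | None = None
    right_edges_path: str | None = None
    locations_path: str | None = None
    eyemap_path: str | None = None
    synthetic_model: str = "random"
    n_inputs: int = 74
    n_outputs: int = 147

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _assemble(cfg: RunConfig) -> tuple[ConnectivityMatrix, ConnectivityMatrix | None]:
    if cfg.edges_path:
        edges = cwio.read_edges(cfg.edges_path)
        inputs = {e.pre_id for e in edges}
        outputs = {e.post_id for e in edges}
        left = build_matrix(edges, inputs, outputs, threshold=cfg.synapse_threshold)
        right = None
        if cfg.right_edges_path:
            redges = cwio.read_edges(cfg.right_edges_path)
            right = build_matrix(
                redges,
                {e.pre_id for e in redges},
                {e.post_id for e in redges},
                threshold=cfg.synapse_threshold,
            )
        return left, right
    spec = WiringSpec(
        n_inputs=cfg.n_inputs,
        n_outputs=cfg.n_outputs,
        model=cfg.synthetic_model,
        threshold=cfg.synapse_threshold,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    left, right, _ = generate_bilateral_pair(spec, stereotypy="independent")
    return left, right


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    k_range = range(cfg.k_min, cfg.k_max + 1)

    left, right = _assemble(cfg)
    cwio.write_matrix(left, out / "matrix_left.csv")
    manifest["stages"]["matrix"] = {
        "n_inputs": len(left.input_ids),
        "n_outputs": len(left.output_ids),
        "threshold": left.threshold,
    }

    groups = {i: "input" for i in left.input_ids}
    from .model import summarize_inputs

    summary = summarize_inputs(left, groups)
    summary.input_ranking.to_csv(out / "input_ranking.csv", index=False)
    summary.output_composition.to_csv(out / "output_composition.csv")
    manifest["stages"]["summaries"] = {
        "n_connected_outputs": summary.n_connected_outputs
    }

    scfg = ShuffleConfig(n_shuffles=cfg.n_shuffles, seed=stage_seed(cfg.seed, "spectrum"))
    spectrum = pca_spectrum_test(left, scfg)
    _dump_json(
        out / "spectrum.json",
        {
            "observed_fractions": spectrum.observed_fractions.tolist(),
            "null_mean": spectrum.null_mean.tolist(),
            "null_lo": spectrum.null_lo.tolist(),
            "null_hi": spectrum.null_hi.tolist(),
            "components_outside": spectrum.components_outside.tolist(),
            "n_shuffles": spectrum.n_shuffles,
            "seed": scfg.seed,
        },
    )
    manifest["stages"]["spectrum"] = {
        "n_components_outside": int(len(spectrum.components_outside))
    }

    if right is not None:
        from .model import TypeMap

        labels = {}
        for lid, rid in zip(sorted(left.input_ids), sorted(right.input_ids)):
            shared = lid.split("_", 1)[-1]
            labels[lid] = shared
            labels[rid] = shared
        bcfg = ShuffleConfig(
            n_shuffles=cfg.n_shuffles,
            seed=stage_seed(cfg.seed, "bilateral"),
            mode="independent",
        )
        bil = bilateral_identity_test(left, right, TypeMap(labels, "sum"), bcfg)
        _dump_json(
            out / "bilateral.json",
            {
                "observed_count": bil.observed_count,
                "p_value": bil.p_value,
                "n_eligible": bil.n_eligible,
                "null_mean": float(np.mean(bil.null_counts)),
                "seed": bcfg.seed,
            },
        )
        manifest["stages"]["bilateral"] = {"p_value": bil.p_value}
    else:
        logger.info("no right-hemisphere matrix; bilateral stage skipped")
        manifest["stages"]["bilateral"] = "skipped"

    pr = participation_ratio(left)
    _dump_json(out / "participation_ratio.json", {"pr": pr.pr, "n_channels": pr.n_channels})
    manifest["stages"]["pr"] = {"pr": pr.pr}

    ccfg = ShuffleConfig(n_shuffles=cfg.n_shuffles, seed=stage_seed(cfg.seed, "condinput"))
    cond = conditional_input_analysis(left, ccfg, k_range)
    pd.DataFrame(cond.z, index=cond.input_ids, columns=cond.input_ids).to_csv(
        out / "conditional_z.csv", index_label="input_id"
    )
    pd.DataFrame(
        {f"k{k}": v for k, v in cond.clusterings.items()}, index=cond.input_ids
    ).to_csv(out / "conditional_clusters.csv", index_label="input_id")
    manifest["stages"]["condinput"] = {
        "max_abs_z": float(np.max(np.abs(cond.z)))
    }

    clus = cluster_outputs(left, k_range, seed=stage_seed(cfg.seed, "cluster"))
    pd.DataFrame(
        {"output_id": clus.output_ids, "cluster": clus.labels}
    ).to_csv(out / "output_clusters.csv", index=False)
    _dump_json(
        out / "cluster_orders.json",
        {
            "selected_k": clus.selected_k,
            "silhouettes": clus.silhouettes,
            "no_clear_structure": clus.no_clear_structure,
            "row_order": clus.row_order.tolist(),
            "col_order": clus.col_order.tolist(),
        },
    )
    manifest["stages"]["cluster"] = {
        "selected_k": clus.selected_k,
        "no_clear_structure": clus.no_clear_structure,
    }

    if cfg.locations_path:
        locations = cwio.read_synapse_locations(cfg.locations_path)
        unlabeled = [(pre, post, pts) for (pre, post), pts in locations.items()]
        # Without external ground truth, calibrate on synthetic clouds.
        from .synthetic import CloudSpec, generate_synapse_cloud

        sseed = stage_seed(cfg.seed, "syntype")
        labeled = []
        for i in range(30):
            labeled.append(
                (generate_synapse_cloud(CloudSpec("bouton_claw", 20, 500.0, seed=sseed + i)),
                 "bouton_claw")
            )
            labeled.append(
                (generate_synapse_cloud(
                    CloudSpec("en_passant", 20, 10000.0, jitter=200.0, seed=sseed + 1000 + i)),
                 "en_passant")
            )
        calib, calls = calibrate_and_classify(labeled, unlabeled, seed=sseed)
        pd.DataFrame(
            [(c.pre_id, c.post_id, c.n_synapses, c.dispersion, c.label) for c in calls],
            columns=["pre_id", "post_id", "n_synapses", "dispersion", "label"],
        ).to_csv(out / "synapse_types.csv", index=False)
        manifest["stages"]["syntype"] = {
            "threshold_nm2": calib.threshold,
            "test_accuracy": calib.test_accuracy,
        }
    else:
        logger.info("no synapse locations; synapse-typing stage skipped")
        manifest["stages"]["syntype"] = "skipped"

    if cfg.eyemap_path:
        eye = cwio.read_eyemap(cfg.eyemap_path)
        threshold = cfg.rf_threshold_nm or 4000.0
        sizes = []
        # RFs for inputs with skeleton files next to the eyemap, if any.
        skel_dir = Path(cfg.eyemap_path).parent / "skeletons"
        if skel_dir.is_dir():
            for swc in sorted(skel_dir.glob("*.swc")):
                pts = cwio.swc_points(swc)
                cov = covered_columns(pts, eye, cfg.rf_layer, threshold)
                if cov:
                    rf = rf_from_columns(cov, eye)
                    sizes.append((swc.stem, rf.size, len(rf.covered)))
        pd.DataFrame(sizes, columns=["neuron_id", "rf_size", "n_covered"]).to_csv(
            out / "rf_sizes.csv", index=False
        )
        manifest["stages"]["rf"] = {"n_neurons": len(sizes), "threshold_nm": threshold}
    else:
        logger.info("no eyemap; receptive-field stage skipped")
        manifest["stages"]["rf"] = "skipped"

    _dump_json(out / "manifest.json", manifest)
    return manifest


def _dump_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
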
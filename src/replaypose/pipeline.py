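"""End-to-end pipeline: run -> cluster -> rank with shared seed derivation.

All stages derive their seeds from one root seed, so a re-run with the same
config and seed reproduces every numeric output bitwise (toy propagator).
The report deliberately excludes timestamps; those live in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .clustering import compute_rmsd_matrix, select_best_clustering
from .config import RunConfig
from .errors import InputError
from .propagation import HarmonicWell, ToyLangevinPropagator
from .ranking import cluster_probabilities, geometry_report
from .replay import ReplayBuffer, run_protocol
from .structures import PoseSet, Structure, read_pose_set, read_structure, resolve_selection
from .synthetic import TwoBasinSpec, make_two_basin_system

__all__ = ["pipeline_end_to_end", "cluster_buffer", "rank_buffer", "combine_structures"]

logger = logging.getLogger(__name__)


def combine_structures(a: Structure, b: Structure) -> Structure:
    """Concatenate two structures (receptor + ligand pose) into one."""
    return Structure(
        atom_names=a.atom_names + b.atom_names,
        elements=a.elements + b.elements,
        coords=np.vstack([a.coords, b.coords]),
        residue_ids=a.residue_ids + b.residue_ids,
        source=f"{a.source}+{b.source}",
    )


def _build_toy_system(config: RunConfig, receptor_path, poses_path):
    """Inputs for run_protocol: molecular files if given, else the built-in
    two-basin toy system."""
    if poses_path is not None:
        if receptor_path is None:
            raise InputError("molecular runs need --receptor alongside --poses")
        receptor = read_structure(receptor_path)
        poses = read_pose_set(poses_path)
        # toy reference propagator for molecular smoke runs: a harmonic well
        # over ligand coordinates centered on the mean docked placement
        center = np.mean(np.stack(poses.pose_coords), axis=0)
        landscape = HarmonicWell(
            center=center, k=config.propagator.harmonic_k, kT=config.propagator.kT
        )
        propagator = ToyLangevinPropagator(
            landscape=landscape,
            kT=config.propagator.kT,
            dt=config.propagator.dt,
            friction=config.propagator.friction,
        )
        return receptor, poses, propagator
    landscape, states, _ = make_two_basin_system(TwoBasinSpec(kT=config.propagator.kT))
    propagator = ToyLangevinPropagator(
        landscape=landscape,
        kT=config.propagator.kT,
        dt=config.propagator.dt,
        friction=config.propagator.friction,
    )
    return None, states, propagator


def cluster_buffer(buffer: ReplayBuffer, config: RunConfig, seed: int):
    """Distance matrix + self-tuning spectral clustering for a buffer."""
    cs = config.clustering
    rmsd_sel = align_sel = None
    coords = buffer.coords_array()
    if coords.ndim == 3 and (cs.rmsd_selection or cs.align_selection):
        # resolve expressions against the stored system topology
        template = getattr(buffer, "pose_template", None)
        if template is not None:
            if cs.rmsd_selection:
                rmsd_sel = resolve_selection(template, cs.rmsd_selection)
            if cs.align_selection:
                align_sel = resolve_selection(template, cs.align_selection)
    d = compute_rmsd_matrix(buffer, rmsd_sel, align_sel)
    result = select_best_clustering(
        d,
        k_max=cs.k_max,
        n_repeats=cs.n_repeats,
        seed=seed,
        k_nn=cs.k_nn,
        n_candidates=cs.n_candidates,
    )
    return d, result


def rank_buffer(buffer, clustering, d, config: RunConfig):
    return cluster_probabilities(
        buffer, clustering, d=d, include_init=config.clustering.include_init_in_occupancy
    )


def clustering_to_json(result) -> dict:
    return {
        "k": result.k,
        "silhouette": result.silhouette,
        "candidate_ks": [int(k) for k in result.candidate_ks],
        "eigenvalue_head": [float(x) for x in result.eigenvalues[: min(30, result.eigenvalues.size)]],
        "labels": [int(x) for x in result.labels],
        "trials": [
            {"trial": t["trial"], "k": int(t["k"]), "seed": int(t["seed"]),
             "silhouette": float(t["silhouette"])}
            for t in result.trials
        ],
    }


def pipeline_end_to_end(
    config: RunConfig,
    seed: int,
    out_dir,
    receptor_path=None,
    poses_path=None,
) -> Path:
    """run -> cluster -> rank; returns the report directory.

    Without molecular inputs the built-in two-basin toy system is used, so
    the full protocol is exercisable at desk scale.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    receptor, poses, propagator = _build_toy_system(config, receptor_path, poses_path)
    protocol = config.protocol.to_protocol_config(seed)

    buffer = run_protocol(poses, receptor, protocol, propagator)
    template = poses.ligand_template if isinstance(poses, PoseSet) else None
    buffer.to_dir(out / "buffer", pose_template=template)
    buffer.pose_template = template

    d, result = cluster_buffer(buffer, config, seed)
    (out / "clustering.json").write_text(json.dumps(clustering_to_json(result), indent=2))
    np.savetxt(out / "distance_matrix.csv", d, delimiter=",", fmt="%.10g")

    clusters = rank_buffer(buffer, result, d, config)
    report = {
        "n_entries": len(buffer),
        "k": result.k,
        "silhouette": result.silhouette,
        "candidate_ks": [int(k) for k in result.candidate_ks],
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "occupancy": c.occupancy,
                "probability": c.probability,
                "representative_index": c.representative_index,
                "mean_energy": c.mean_energy,
                "origin_pose_histogram": c.origin_pose_histogram,
            }
            for c in clusters
        ],
    }
    if config.geometry and receptor is not None and template is not None:
        top = clusters[0]
        rep_coords = buffer[top.representative_index].state.coords
        combined = combine_structures(receptor, template.with_coords(rep_coords))
        gr = geometry_report(combined, [g.model_dump() for g in config.geometry])
        report["geometry"] = gr.to_dict(orient="records")
        gr.to_csv(out / "geometry.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info(
        "pipeline done: %d entries, k=%d, top probability %.3f",
        len(buffer), result.k, clusters[0].probability,
    )
    return out
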
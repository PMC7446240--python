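"""Declarative end-to-end runs: simulate -> model -> RSA -> inference.

A YAML config describes which stages to run and with what parameters;
:func:`run_pipeline` executes them, writes every product (RDM CSVs, map
TSVs, cluster tables) under the configured output directory, and records
a manifest with the package version, seed, parameters and SHA-256
checksums of all outputs.  The schema is strict: unknown keys are
rejected so a mistyped permutation count or alpha cannot silently fall
back to a default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, model_rdms, searchlight, synth, temporal
from .types import PlantSpec, WindowScheme

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

_TOP_KEYS = {"seed", "out_dir", "n_conditions", "geometry_dims", "stages"}
_STAGE_KEYS = {
    "glove_model": {"n_runs", "trials_per_block", "noise_sd", "signal_scale"},
    "emg_model": {"n_runs", "trials_per_block", "noise_sd", "signal_scale", "fs"},
    "ethological_model": set(),
    "searchlight": {
        "subdivisions",
        "radius_mm",
        "patch_radius_mm",
        "n_runs",
        "noise_sd",
        "signal_scale",
        "diameter_mm",
        "n_perm",
        "alpha",
        "block_s",
    },
    "temporal": {
        "band",
        "window_ms",
        "n_sources",
        "fs",
        "trials_per_condition",
        "noise_sd",
        "signal_scale",
        "n_partitions",
        "width_ms",
        "step_ms",
        "n_perm",
        "cluster_p",
        "fwe_alpha",
    },
}


def _check_keys(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(allowed)}"
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path) -> dict:
    """Run the configured stages end to end; returns the manifest dict."""
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(f"config file not found: {config_path}")
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    stages = cfg.get("stages", {})
    _check_keys(stages, set(_STAGE_KEYS), "stages")
    for name, params in stages.items():
        _check_keys(params or {}, _STAGE_KEYS[name], f"stage {name!r}")

    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "pipeline_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    n_cond = int(cfg.get("n_conditions", 26))
    geom_dims = int(cfg.get("geometry_dims", 5))

    movements = synth.default_movement_set(n_cond)
    target = synth.random_geometry_rdm(
        movements.n, seed=seed, n_dims=geom_dims, labels=movements.labels
    )
    outputs: list[Path] = []
    results: dict = {}

    def save_rdm(rdm, name):
        path = out_dir / f"{name}.csv"
        io.write_rdm(rdm, path)
        outputs.append(path)

    save_rdm(target, "target_rdm")

    if "glove_model" in stages:
        p = stages["glove_model"] or {}
        logger.info("stage glove_model")
        spec = PlantSpec(
            target, signal_scale=p.get("signal_scale", 1.0),
            noise_sd=p.get("noise_sd", 0.2), seed=seed,
        )
        epochs = synth.gen_glove_session(
            movements, spec,
            n_runs=p.get("n_runs", 5), trials_per_block=p.get("trials_per_block", 8),
        )
        avgs, conds = model_rdms.average_by_condition(epochs)
        kin = model_rdms.channel_correlation_rdm(avgs, conds)
        save_rdm(kin, "kinematic_rdm")
        results["kinematic_rdm_mean"] = float(kin.condensed().mean())

    if "emg_model" in stages:
        p = stages["emg_model"] or {}
        logger.info("stage emg_model")
        spec = PlantSpec(
            target, signal_scale=p.get("signal_scale", 1.0),
            noise_sd=p.get("noise_sd", 0.2), seed=seed + 1,
        )
        epochs = synth.gen_emg_session(
            movements, spec, n_runs=p.get("n_runs", 5),
            trials_per_block=p.get("trials_per_block", 2), fs=p.get("fs", 256.0),
        )
        normed = model_rdms.mnn_trials(epochs, shrinkage=0.1)
        avgs, conds = model_rdms.average_by_condition(normed)
        mus = model_rdms.channel_correlation_rdm(avgs, conds)
        save_rdm(mus, "muscle_rdm")
        results["muscle_rdm_mean"] = float(mus.condensed().mean())

    if "ethological_model" in stages:
        logger.info("stage ethological_model")
        eth = model_rdms.ethological_rdm(movements)
        save_rdm(eth, "ethological_rdm")

    if "searchlight" in stages:
        p = stages["searchlight"] or {}
        logger.info("stage searchlight")
        mesh = synth.make_icosphere(
            subdivisions=p.get("subdivisions", 1), radius_mm=p.get("radius_mm", 40.0)
        )
        region = synth.mesh_patch(mesh, 0, p.get("patch_radius_mm", 15.0))
        plant = PlantSpec(
            target, signal_scale=p.get("signal_scale", 1.0),
            noise_sd=p.get("noise_sd", 1.0), region=region, seed=seed + 2,
        )
        sess = synth.gen_fmri_session(
            mesh, plant, movements, n_runs=p.get("n_runs", 4),
            seed=seed + 2, block_s=p.get("block_s", 17.0),
        )
        folds, resids = [], []
        for series, ev in zip(sess.runs, sess.events):
            pats, res, conds = searchlight.fit_glm(series, ev, sess.tr_s, sess.conditions)
            folds.append(pats)
            resids.append(res)
        from .types import FoldPatterns

        fp = FoldPatterns(folds, sess.conditions)
        lights = searchlight.build_searchlights(mesh, p.get("diameter_mm", 10.0))
        stat = searchlight.omnibus_threshold(
            fp, resids, lights, target,
            n_perm=p.get("n_perm", 500), alpha=p.get("alpha", 0.01), seed=seed + 3,
        )
        map_path = out_dir / "searchlight_rho.tsv"
        np.savetxt(
            map_path,
            np.column_stack([np.arange(len(stat.values)), stat.values]),
            delimiter="\t", header="vertex\trho", comments="",
        )
        outputs.append(map_path)
        results["searchlight_threshold"] = stat.threshold
        results["searchlight_n_significant"] = int(np.sum(stat.mask))
        results["searchlight_peak_in_region"] = bool(
            np.nanargmax(stat.values) in set(region.tolist())
        )

    if "temporal" in stages:
        p = stages["temporal"] or {}
        logger.info("stage temporal")
        band = p.get("band", "beta")
        band_hz = temporal.BAND_PRESETS[band]
        fs = p.get("fs", 300.0)
        # default amplitude preserves the full-size calibrated effect at
        # this stage's reduced problem size (see docs/methods.md)
        plant = PlantSpec(
            target, signal_scale=p.get("signal_scale", 3.0),
            noise_sd=p.get("noise_sd", 1.0),
            window_ms=tuple(p.get("window_ms", (-210.0, -90.0))),
            band_hz=band_hz, seed=seed + 4,
        )
        epochs = synth.gen_meg_session(
            plant, movements, n_sources=p.get("n_sources", 16), fs=fs,
            trials_per_condition=p.get("trials_per_condition", 20), seed=seed + 4,
        )
        filt = temporal.bandpass(epochs, band)
        base = temporal.baseline_correct(filt, (epochs.t0_ms, 0.0))
        pm = temporal.partition_average(
            base, n_partitions=p.get("n_partitions", 5), seed=seed + 5
        )
        scheme = WindowScheme(
            p.get("width_ms", 20.0), p.get("step_ms", 5.0),
            (epochs.t0_ms, epochs.times_ms[-1] + 1000.0 / fs),
        )
        tc = temporal.sliding_rdms(pm, scheme, band=band)
        io.write_rdm_timecourse(tc, out_dir / "rdm_timecourse.h5")
        outputs.append(out_dir / "rdm_timecourse.h5")
        res = temporal.cluster_inference(
            tc, target, n_perm=p.get("n_perm", 500),
            cluster_p=p.get("cluster_p", 0.01), fwe_alpha=p.get("fwe_alpha", 0.01),
            seed=seed + 6,
        )
        cl_path = out_dir / "clusters.tsv"
        with cl_path.open("w") as f:
            f.write("start_ms\tend_ms\tmass\tp\n")
            for c in res.clusters:
                f.write(f"{c['start_ms']}\t{c['end_ms']}\t{c['mass']}\t{c['p']}\n")
        outputs.append(cl_path)
        results["temporal_n_significant_clusters"] = len(res.significant())
        if res.significant():
            results["temporal_first_cluster"] = {
                k: res.significant()[0][k] for k in ("start_ms", "end_ms", "p")
            }

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "results": results,
        "checksums": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out_dir)
    return manifest
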
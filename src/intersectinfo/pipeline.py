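"""End-to-end orchestration: simulate -> preprocess -> information -> decode.

A run sweeps one synthetic session per learning stage, executes every
analysis stage on it, and writes tidy CSV tables plus a manifest (parameters,
seeds, content hashes) into an output directory.  Per-stage seeds derive
deterministically from the master seed, so a rerun with the same
configuration reproduces every table bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding as dec
from . import dprime as dp
from .info import framewise_info, subsample_to_performance
from .intersection import ii_framewise
from .io import write_session, write_trials
from .preprocess import align_trials, compute_dff
from .synthetic import (SessionConfig, classify_stage, generate_session,
                        stage_config, CORRECT_OUTCOMES)

log = logging.getLogger("intersectinfo")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Parameters of a full stage-sweep analysis run."""

    stages: dict[int, SessionConfig] = field(default_factory=dict)
    n_bins: int = 2
    n_perm: int = 50
    n_shuffles: int = 10            # decoder label shuffles per neuron
    alignment_window: tuple[float, float] = (-3.0, 7.0)
    analysis_window: tuple[float, float] = (0.0, 1.0)
    equalize_performance: float | None = None
    run_curves: bool = True
    curve_prefix_step: int = 4      # decode every k-th cumulative prefix
    run_noise_gain: bool = False
    noise_shuffles: int = 1000
    decoder: dec.DecoderSpec = field(default_factory=dec.DecoderSpec)
    out_dir: str | Path = "results/run"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            self.stages = {k: stage_config(k) for k in (1, 2, 3)}

    def stage_seed(self, stage: int, substream: int = 0) -> np.random.Generator:
        ss = np.random.SeedSequence([self.master_seed, stage, substream])
        return np.random.default_rng(ss)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analyze_session(stage: int, cfg: RunConfig) -> dict[str, pd.DataFrame]:
    t0 = time.time()
    scfg = cfg.stages[stage]
    rng = cfg.stage_seed(stage, 0)
    trials, fluor, truth = generate_session(scfg, rng)

    out = Path(cfg.out_dir)
    write_trials(trials, out / f"trials_stage{stage}.csv")
    write_session(out / f"session_stage{stage}.h5", fluor,
                  spikes=truth.spikes, seed=cfg.master_seed)
    (out / f"config_stage{stage}.yaml").write_text(
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(scfg).items()}))

    dff = compute_dff(fluor)
    tensor = align_trials(dff, trials, cfg.alignment_window, scfg.frame_rate)
    inc = tensor.included_trials
    stim = trials["stimulus"].to_numpy()[inc]
    choice = trials["choice"].to_numpy()[inc]
    perf = float(trials["outcome"].isin(CORRECT_OUTCOMES).mean())

    keep = np.arange(inc.size)
    if cfg.equalize_performance is not None:
        keep = subsample_to_performance(
            trials.iloc[inc], cfg.equalize_performance, cfg.stage_seed(stage, 5))
        tensor.values = tensor.values[:, keep]
        tensor.included_trials = inc[keep]
        stim, choice = stim[keep], choice[keep]

    tables: dict[str, pd.DataFrame] = {}

    # --- single-neuron information -------------------------------------
    mi_rows = []
    for task, labels in (("stimulus", stim), ("choice", choice)):
        res = framewise_info(tensor, labels, cfg.n_bins, cfg.n_perm,
                             cfg.stage_seed(stage, 1),
                             sig_window=cfg.analysis_window)
        tidy = res.to_frame()
        tidy.insert(0, "task", task)
        mi_rows.append(tidy)
    mi = pd.concat(mi_rows, ignore_index=True)
    mi.insert(0, "stage", stage)
    tables["mi"] = mi

    # --- intersection information --------------------------------------
    iires = ii_framewise(tensor, stim, choice, cfg.n_bins, cfg.n_perm,
                         cfg.stage_seed(stage, 2),
                         sig_window=cfg.analysis_window)
    j, f = iires.ii_raw.shape
    jj, ff = np.meshgrid(np.arange(j), np.arange(f), indexing="ij")
    ii = pd.DataFrame({
        "stage": stage, "neuron": jj.ravel(), "frame": ff.ravel(),
        "si_c_sr": iires.si_c_sr.ravel(), "si_s_cr": iires.si_s_cr.ravel(),
        "ii": iires.ii_raw.ravel(), "ii_corrected": iires.ii_corrected.ravel(),
        "mi_rs": iires.mi_rs.ravel(), "mi_rc": iires.mi_rc.ravel(),
        "ii_over_mirs": iires.ii_over_mirs.ravel(),
        "p": np.repeat(iires.p_value, f),
        "significant": np.repeat(iires.significant, f),
    })
    tables["ii"] = ii

    # --- population decoding -------------------------------------------
    feats = dec.decoder_features(tensor, cfg.analysis_window)
    dec_rows, curve_rows = [], []
    spec = cfg.decoder
    for task, labels in (("stimulus", stim), ("choice", choice)):
        if not dec.apply_session_filter(trials.iloc[inc], task=task):
            log.info("stage %d: session excluded for %s decoding", stage, task)
            continue
        rng_d = cfg.stage_seed(stage, 3 if task == "stimulus" else 4)
        j_neurons = feats.shape[0]
        per_neuron = np.array(
            [dec.decode(feats[jn][None], labels, spec, rng_d).dec_mi
             for jn in range(j_neurons)])
        nulls = [dec.decoder_null(feats[jn][None], labels, spec,
                                  cfg.n_shuffles, rng_d)
                 for jn in range(j_neurons)]
        pooled = dec.fov_null(nulls)
        p95 = float(np.percentile(pooled, 95))
        disc = per_neuron > p95
        dec_rows.append(pd.DataFrame({
            "stage": stage, "task": task, "neuron": np.arange(j_neurons),
            "dec_mi": per_neuron, "null_p95": p95, "discriminative": disc,
        }))
        if cfg.run_curves:
            for pool_name, mask, grid in (
                    ("all", None, dec.CURVE_GRID_FULL),
                    ("nondisc", ~disc, dec.CURVE_GRID_NONDISC)):
                if mask is not None and mask.sum() < 2:
                    continue
                g, v = _sparse_curve(feats, labels, per_neuron, mask, spec,
                                     grid, rng_d, cfg.curve_prefix_step)
                curve_rows.append(pd.DataFrame({
                    "stage": stage, "task": task, "pool": pool_name,
                    "grid_pct": g, "dec_mi": v}))
    if dec_rows:
        tables["decmi"] = pd.concat(dec_rows, ignore_index=True)
    if curve_rows:
        tables["curves"] = pd.concat(curve_rows, ignore_index=True)

    if cfg.run_noise_gain:
        rng_n = cfg.stage_seed(stage, 6)
        gain, _ = dec.noise_correlation_gain(feats, stim, cfg.noise_shuffles,
                                             spec, rng_n)
        tables["noise_gain"] = pd.DataFrame(
            {"stage": [stage], "task": ["stimulus"], "gain": [gain]})

    # --- d-prime --------------------------------------------------------
    win = tensor.frames_in(*cfg.analysis_window)
    dp_rows = []
    for task, labels in (("stimulus", stim), ("choice", choice)):
        for j_n in range(tensor.values.shape[0]):
            vals = tensor.values[j_n][:, win]
            dp_rows.append({
                "stage": stage, "task": task, "neuron": j_n,
                "raw": dp.abs_dprime(*dp.split_by_class(vals.sum(axis=1),
                                                        labels)),
                "median": dp.median_threshold_dprime(vals, labels),
            })
    tables["dprime"] = pd.DataFrame(dp_rows)

    meta = pd.DataFrame({
        "stage": [stage], "performance": [perf],
        "classified_stage": [classify_stage(perf)],
        "n_neurons": [scfg.n_neurons], "n_trials_included": [stim.size],
        "wall_time_s": [round(time.time() - t0, 2)],
    })
    tables["sessions"] = meta
    log.info("stage %d done in %.1fs (perf %.2f, %d trials)",
             stage, time.time() - t0, perf, stim.size)
    return tables


def _sparse_curve(feats, labels, per_neuron, mask, spec, grid, rng, step):
    """Cumulative curve decoding only every ``step``-th prefix (then interp)."""
    pool_idx = (np.arange(feats.shape[0]) if mask is None
                else np.flatnonzero(mask))
    order = pool_idx[np.argsort(per_neuron[pool_idx], kind="stable")]
    sizes = np.unique(np.r_[1, np.arange(step, order.size, step), order.size])
    pct = 100.0 * sizes / order.size
    vals = np.array([dec.decode(feats[order[:k]], labels, spec, rng).dec_mi
                     for k in sizes])
    return grid, np.interp(grid, pct, vals)


def run(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full sweep; returns the concatenated result tables.

    Writes one CSV per table plus ``manifest.json`` into ``config.out_dir``.
    Reruns with identical configuration are bit-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    merged: dict[str, list[pd.DataFrame]] = {}
    for stage in sorted(config.stages):
        try:
            tables = _analyze_session(stage, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage {stage}") from exc
        for name, df in tables.items():
            merged.setdefault(name, []).append(df)
    results = {name: pd.concat(parts, ignore_index=True)
               for name, parts in merged.items()}
    for name, df in results.items():
        df.to_csv(out / f"{name}.csv", index=False)

    files = sorted(p for p in out.iterdir() if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "master_seed": config.master_seed,
        "parameters": {
            "n_bins": config.n_bins, "n_perm": config.n_perm,
            "n_shuffles": config.n_shuffles,
            "equalize_performance": config.equalize_performance,
            "analysis_window": list(config.analysis_window),
            "stages": {s: {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(c).items()}
                       for s, c in config.stages.items()},
        },
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
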
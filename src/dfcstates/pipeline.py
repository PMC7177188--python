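"""End-to-end orchestration: synthesize → dFC → states → validation → report.

A single :class:`RunConfig` drives a complete reproducible run on synthetic
data: two-modality parcel series with planted connectivity states, group
dFC matrices, nested-CV selection of (k, lambda) per modality, dictionary
fits, phase-randomization state validation, network-template (Dice) and
cross-modal state matching, the GLM task map, and the state-task
correlation table. All randomness flows from one master seed through named
substreams; the same config yields a byte-identical report apart from the
timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dfc, evaluation, glm, matching, states, surrogates, synth

logger = logging.getLogger("dfcstates")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str = "dfcstates_run"
    seed: int = 0
    # synthetic group
    R: int = 20
    k_true: int = 5
    n_participants: int = 2
    duration_s: float = 600.0
    dwell_s: float = 60.0
    noise_sd: float = 0.05
    # windows: preset name from dfc.WINDOW_PRESETS
    window_preset: str = "default"
    # model selection
    select_hyperparams: bool = True
    k_grid: list[int] = field(default_factory=lambda: list(states.DEFAULT_K_GRID))
    lam_grid: list[float] | None = None
    lam_default: float = 0.25
    nonneg: bool = True
    n_restarts: int = 3
    # validation
    n_surrogates: int = 200
    n_orderings: int = 10000
    alpha: float = 0.05
    # maps / RSN stage
    n_templates: int = 10
    n_ics: int = 40
    split_fraction_eeg: float = 0.5
    z_threshold: float = 3.0
    # GLM stage
    cluster_z: float = 2.7
    cluster_min_voxels: int = 10

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def _window_specs(config: RunConfig, tr_s: float, eeg_rate: float):
    preset = dfc.WINDOW_PRESETS[config.window_preset]
    lf, sf = preset[dfc.HEMODYNAMIC]
    le, se = preset[dfc.ELECTROPHYSIOLOGICAL]
    return (
        dfc.WindowSpec.from_seconds(lf, sf, tr_s),
        dfc.WindowSpec.from_seconds(le, se, 1.0 / eeg_rate),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write a machine-readable report bundle.

    Returns the report dict; writes ``report.json``, the config, and stage
    outputs (dFC HDF5, state models, map sets, verdict JSONs) under
    ``config.out_dir``.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"config": dataclasses.asdict(config)}

    # --- stage: simulate ---------------------------------------------------
    logger.info("simulate: R=%d k=%d participants=%d duration=%.0fs",
                config.R, config.k_true, config.n_participants, config.duration_s)
    truth = synth.GroundTruth.with_dwell_states(
        R=config.R, k_true=config.k_true, duration_s=config.duration_s,
        dwell_s=config.dwell_s, seed=config.seed,
    )
    truth.noise_sd = {m: config.noise_sd for m in truth.noise_sd}
    w_f, w_e = _window_specs(config, truth.tr_s, truth.eeg_rate_hz)
    parts_f, parts_e = [], []
    for p in range(config.n_participants):
        ds_f1, ds_e1 = evaluation.build_modality_dfc(
            truth, seed=p, participant_id=f"sub-{p + 1:02d}"
        )
        parts_f.append((ds_f1.C, ds_f1.static_fc[0]))
        parts_e.append((ds_e1.C, ds_e1.static_fc[0]))
    ds = {
        dfc.HEMODYNAMIC: dfc.concat_group(parts_f, config.R, w_f, dfc.HEMODYNAMIC),
        dfc.ELECTROPHYSIOLOGICAL: dfc.concat_group(
            parts_e, config.R, w_e, dfc.ELECTROPHYSIOLOGICAL
        ),
    }
    for name, d in ds.items():
        d.to_hdf5(out / f"dfc_{name}.h5")

    # --- stage: model selection + states -----------------------------------
    fit_kw = dict(nonneg=config.nonneg, n_restarts=config.n_restarts)
    models: dict[str, states.StateModel] = {}
    report["selection"] = {}
    for name, d in ds.items():
        if config.select_hyperparams:
            sel = states.nested_cv_select(
                d.C, k_grid=config.k_grid, lam_grid=config.lam_grid,
                seed=config.seed, participant_slices=d.participant_slices,
            )
            k_opt, lam_opt = sel.k_opt, sel.lam_opt
            sel.to_json(out / f"selection_{name}.json")
            report["selection"][name] = {
                "k_opt": k_opt, "lam_opt": lam_opt,
                "fold_choices": sel.fold_choices,
            }
        else:
            k_opt, lam_opt = config.k_true, config.lam_default
            report["selection"][name] = {"k_opt": k_opt, "lam_opt": lam_opt,
                                         "fold_choices": None}
        logger.info("states[%s]: k=%d lambda=%.4f", name, k_opt, lam_opt)
        model = states.fit_dictionary(d.C, k_opt, lam_opt, seed=config.seed, **fit_kw)
        model.to_hdf5(out / f"states_{name}.h5")
        models[name] = model

    # --- stage: per-state significance -------------------------------------
    report["state_significance"] = {}
    for name, d in ds.items():
        verdict = surrogates.state_significance(
            d.C, models[name], n_surr=config.n_surrogates, seed=config.seed, **fit_kw
        )
        surrogates.verdicts_to_json(verdict, out / f"state_significance_{name}.json")
        report["state_significance"][name] = {
            "meaningful": verdict["meaningful"].tolist(),
            "threshold": verdict["threshold"],
            "E_true": verdict["E_true"].tolist(),
        }

    # --- stage: RSN identification (synthetic maps) ------------------------
    templates = synth.gen_map_set(n_templates=config.n_templates, seed=config.seed)
    templates.z_threshold = config.z_threshold
    report["rsn"] = {}
    for name, split in ((dfc.HEMODYNAMIC, 0.0),
                        (dfc.ELECTROPHYSIOLOGICAL, config.split_fraction_eeg)):
        ics, _ = synth.gen_ic_maps(
            templates, n_ics=config.n_ics, split_fraction=split, seed=config.seed + 1
        )
        ics.z_threshold = config.z_threshold
        res = matching.identify_networks(
            ics, templates, n_orderings=config.n_orderings, seed=config.seed
        )
        res.to_json(out / f"rsn_{name}.json")
        report["rsn"][name] = {
            "d_max": res.max_similarity,
            "d_mean": res.mean_similarity,
            "null_threshold": res.null_threshold,
            "significant": res.significant,
            "pairs": res.pairs,
        }

    # --- stage: cross-modal state match -------------------------------------
    match = matching.match_states(
        models[dfc.HEMODYNAMIC].D, models[dfc.ELECTROPHYSIOLOGICAL].D,
        alpha=config.alpha, n_orderings=config.n_orderings, seed=config.seed,
    )
    match.to_json(out / "state_match.json")
    null = surrogates.crossmodal_null(
        ds[dfc.HEMODYNAMIC].C, models[dfc.ELECTROPHYSIOLOGICAL].D,
        models[dfc.HEMODYNAMIC].k, models[dfc.HEMODYNAMIC].lam,
        n_surr=config.n_surrogates, seed=config.seed, alpha=config.alpha, **fit_kw,
    )
    report["state_match"] = {
        "pairs": match.pairs,
        "s_max": match.max_similarity,
        "s_mean": match.mean_similarity,
        "p_values": None if match.p_values is None else list(match.p_values),
        "null_fraction_significant": null["fraction_significant"],
        "null_max_corr_best": float(null["null_max_corrs"].max()) if len(null["null_max_corrs"]) else None,
    }

    # --- stage: GLM task mapping --------------------------------------------
    design = synth.gen_task_design("localizer", n_cycles=8, seed=config.seed)
    design.to_tsv(out / "task_design.tsv")
    grid = (12, 12, 8)
    active = np.zeros(grid, dtype=bool)
    active[3:7, 4:8, 2:5] = True
    report["glm"] = {}
    masks = {}
    for name, convolve, dt in ((dfc.HEMODYNAMIC, True, truth.tr_s),
                               (dfc.ELECTROPHYSIOLOGICAL, False, 1.0 / truth.eeg_rate_hz)):
        data = synth.gen_voxel_data(
            design, active, amplitude=1.0, noise_sd=1.0, TR_s=dt,
            hrf=convolve, seed=config.seed + 5,
        )
        X = glm.build_design_matrix(design, sample_interval=dt, convolve=convolve)
        fit = glm.fit_glm(data.reshape(-1, data.shape[-1]).T, X)
        contrast = evaluation._balanced_contrast(X.names)
        z = glm.contrast_z(fit, contrast).reshape(grid)
        mask = glm.cluster_threshold(z, z=config.cluster_z,
                                     min_voxels=config.cluster_min_voxels)
        masks[name] = mask
        report["glm"][name] = {
            "n_supra_voxels": int(mask.sum()),
            "sensitivity": float((z[active] > config.cluster_z).mean()),
        }
    report["glm"]["mask_dice"] = matching.dice(*masks.values())

    # --- stage: state-task correlation --------------------------------------
    report["state_task"] = {}
    for name, convolve, dt, w in ((dfc.HEMODYNAMIC, True, truth.tr_s, w_f),
                                  (dfc.ELECTROPHYSIOLOGICAL, False, 1.0 / truth.eeg_rate_hz, w_e)):
        series = synth.expression_contrast_series(design, dt)
        if convolve:
            series = glm.convolve_regressor(series, glm.hrf_kernel(dt=dt))
        # repeat per participant and window-average within participants
        n_rep = int(np.ceil(ds[name].T * w.step_samples / series.shape[0])) + config.n_participants
        series_full = np.tile(series, n_rep)
        per_part = []
        for sl in ds[name].participant_slices:
            t_cols = sl.stop - sl.start
            n_samp = (t_cols - 1) * w.step_samples + w.length_samples
            per_part.append(series_full[:n_samp])
        table = glm.state_task_correlation(
            models[name].A, np.concatenate(per_part), w,
            alpha=config.alpha, per_participant=config.n_participants,
        )
        report["state_task"][name] = table
    (out / "state_task.json").write_text(json.dumps(_jsonable(report["state_task"]), indent=2))

    report["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1fs -> %s", report["elapsed_s"], out / "report.json")
    return _jsonable(report)
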
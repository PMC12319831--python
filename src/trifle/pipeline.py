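"""End-to-end orchestration of the analysis stages, driven by a config.

Wires: load -> variance normalize -> dual regression -> temporal ICA ->
time-resolved mixing (demeaned, task-sign-aligned) -> trial epoching and
per-timepoint statistics -> HRF-basis GLM tables.  All settings live in a
single YAML config; defaults follow the reference study conditions
(epoch of 60 frames, AR(5) errors, alpha 0.05, 6 basis functions).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core, glm, hrf, spatial, stats, tfm
from .io import (load_bold, load_events, load_templates, setup_logging,
                 variance_normalize, write_matrix_tsv)

logger = logging.getLogger("trifle")


@dataclass
class RunConfig:
    bold: str = ""
    mask: str = ""
    templates: str = ""
    events: str = ""
    outdir: str = "trifle_out"
    k: int = 15                    # temporal-ICA model order
    tr: float | None = None        # overrides the NIfTI header when set
    epoch_frames: int = 60
    lock: str = "stimulus"
    ar_order: int = 5
    alpha: float = 0.05
    n_basis: int = 6
    flobs_ranges: dict = field(default_factory=lambda: {
        k: list(v) for k, v in hrf.DEFAULT_RANGES.items()})
    flobs_n_sampled: int = 1000
    seed: int = 0
    source: str = "denoised"       # input to the time-resolved stage

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs under ``config.outdir``.

    Returns a dict of output paths plus the in-memory key results.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "trifle.log")

    run = load_bold(config.bold, config.mask, tr=config.tr)
    run = variance_normalize(run)
    templates = load_templates(config.templates, config.mask)
    events = load_events(config.events)

    logger.info("stage 1: dual regression against %d templates", templates.d)
    sd = spatial.dual_regression(run, templates)
    write_matrix_tsv(sd.timeseries.T, out / "network_timeseries.tsv", sd.labels)

    logger.info("stage 2: temporal ICA, k=%d", config.k)
    decomp = tfm.fit_temporal_ica(sd.timeseries, k=config.k, seed=config.seed)
    write_matrix_tsv(decomp.mixing, out / "mixing.tsv",
                     [f"TFM{i + 1}" for i in range(decomp.k)],
                     index_name="network")
    write_matrix_tsv(decomp.modes.T, out / "modes.tsv",
                     [f"TFM{i + 1}" for i in range(decomp.k)])

    logger.info("stage 3: time-resolved mixing (source=%s)", config.source)
    if config.source == "denoised":
        data = core.denoised_reconstruction(sd, decomp)
    elif config.source == "raw":
        data = run.data
    else:
        raise ValueError(f"unknown source '{config.source}'")
    trm = core.time_resolved_mixing(sd.pinv_maps, data, decomp.modes,
                                    source=config.source)

    regressor = core.task_regressor(
        events, hrf.canonical_hrf(run.tr), run.tr, run.n_frames)
    mode_idx, task_corr, sign = core.select_task_tfm(decomp, regressor)
    trm = core.demean_over_time(trm)
    trm = core.align_sign(trm, mode_idx, sign)
    np.savez_compressed(out / "time_resolved_mixing.npz", f=trm.f,
                        scaling=trm.scaling, static_mixing=trm.static_mixing,
                        sign_flips=trm.sign_flips)
    for m in range(trm.k):
        write_matrix_tsv(trm.f[:, m, :].T, out / f"f_mode{m + 1:02d}.tsv",
                         sd.labels)

    logger.info("validation: epoching and per-timepoint statistics")
    epochs = stats.epoch_trials(trm.mode_weights(mode_idx), events, run.tr,
                                epoch_frames=config.epoch_frames,
                                lock=config.lock)
    one_sample = stats.timepoint_one_sample_t(epochs)
    group = stats.combine_group_z([one_sample])
    write_matrix_tsv(one_sample.t_values.T, out / "timepoint_t.tsv", sd.labels)
    write_matrix_tsv(group.z_values.T, out / "timepoint_z.tsv", sd.labels)

    logger.info("validation: HRF-basis GLM (AR(%d))", config.ar_order)
    ranges = {k: tuple(v) for k, v in config.flobs_ranges.items()}
    basis = hrf.flobs_basis(ranges=ranges, n_sampled=config.flobs_n_sampled,
                            n_basis=config.n_basis, dt=run.tr,
                            seed=config.seed)
    hrf.save_basis_tsv(basis, out / "flobs_basis.tsv")
    design = glm.build_design(events, basis, run.tr, run.n_frames,
                              family="baseline")
    tables = {}
    for j, label in enumerate(sd.labels):
        y = trm.f[j, mode_idx, :]
        fit = glm.fit_glsar(y, design, ar_order=config.ar_order,
                            alpha=config.alpha)
        tables[label] = glm.fit_table(fit)
        tables[label].to_csv(out / f"glm_{label}.tsv", sep="\t", index=False)

    meta = {
        "config": asdict(config),
        "task_mode_index": int(mode_idx),
        "task_correlation": float(task_corr),
        "sign": float(sign),
        "ica_converged": bool(decomp.converged),
        "condition_number": float(sd.condition_number),
        "n_trials_epoched": int(epochs.n_trials),
        "epoch_duration_s": float(epochs.epoch_duration),
    }
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return {"outdir": str(out), "meta": meta, "trm": trm, "decomp": decomp,
            "spatial": sd, "epochs": epochs, "glm_tables": tables}


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
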
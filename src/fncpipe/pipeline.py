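"""End-to-end orchestration of the FNC analysis.

Stage order: simulate (or load) -> preprocess -> concatenate -> order /
PCA / Infomax -> dual regression -> network selection -> RSN masks ->
voxelwise group stats -> per-subject FNC -> group inference.  Every
stage's outputs are written before the next starts; identical config +
seed reproduces all numeric outputs bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fnc as fnc_mod
from . import gica, ginf, io, netsel, prep, synth, vstat
from .config import RunConfig
from .core import AcquisitionParams, Volume4D

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: RunConfig
    config_hash: str
    cohort: synth.CohortResult | None
    prep_logs: list
    included: list[str]
    order: gica.OrderEstimate | None
    decomposition: gica.IcaDecomposition
    subject_sets: dict[str, gica.SubjectNetworkSet]
    assignment: dict[str, netsel.Assignment]
    rsn_masks: dict[str, np.ndarray]
    anova_maps: dict[str, vstat.VoxelStatMap]
    contrast_maps: dict[str, dict[str, vstat.VoxelStatMap]]
    fnc_matrices: dict[str, fnc_mod.FncMatrix]
    edges: list[tuple[str, str]]
    within_group: dict[str, pd.DataFrame]
    connection_table: pd.DataFrame
    summary: dict
    log_events: list = field(default_factory=list)


def _load_external(cfg: RunConfig):
    manifest = pd.read_csv(cfg.input_manifest, sep="\t")
    base = Path(cfg.input_manifest).parent
    volumes, motion = {}, {}
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        vol = io.read_volume(base / row["path"], tr_override=cfg.cohort.tr_s)
        vol.subject_id = sid
        volumes[sid] = vol
        mpath = base / f"{sid}_motion.tsv"
        motion[sid] = io.read_motion(mpath) if mpath.exists() else np.zeros((vol.n_volumes, 6))
    return manifest, volumes, motion


def run_pipeline(
    cfg: RunConfig,
    atlas: dict[str, np.ndarray] | None = None,
    write_outputs: bool = True,
    cohort: synth.CohortResult | None = None,
) -> PipelineResult:
    """Execute the full pipeline under one configuration.

    ``atlas`` overrides the template set used for network selection; for
    simulated cohorts it defaults to the planted ground-truth maps.  A
    pre-simulated ``cohort`` (e.g. with custom planted effects) can be
    supplied to skip the simulation stage.
    """
    chash = cfg.config_hash()
    out = Path(cfg.out_dir)
    events: list[dict] = []

    def log_event(stage: str, **kw):
        events.append({"t": round(time.time(), 3), "stage": stage, **kw})

    def write_tsv(df: pd.DataFrame, name: str):
        if not write_outputs:
            return
        path = out / name
        with open(path, "w") as f:
            f.write(f"# fncpipe seed={cfg.seed} config_hash={chash}\n")
            df.to_csv(f, sep="\t", index=False)

    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    # ---- simulate / load ------------------------------------------------
    stage = "simulate"
    try:
        if cohort is not None or cfg.input_manifest is None:
            if cohort is None:
                spec = synth.default_cohort_spec(
                    grid_dims=cfg.cohort.grid_dims,
                    n_volumes=cfg.cohort.n_volumes,
                    group_sizes=dict(cfg.cohort.group_sizes),
                    noise_sd=cfg.cohort.noise_sd,
                    with_default_effects=cfg.cohort.with_default_effects,
                )
                spec.motion_exceed_fraction = cfg.cohort.motion_exceed_fraction
                cohort = synth.simulate_cohort(spec, seed=cfg.seed)
            manifest, volumes, motion = cohort.manifest, cohort.volumes, cohort.truth.motion
            wm, csf = cohort.truth.wm_mask, cohort.truth.csf_mask
            acq = cohort.acq
            if atlas is None:
                atlas = {
                    lab: cohort.truth.maps[i]
                    for i, lab in enumerate(cohort.truth.labels)
                }
        else:
            cohort = None
            manifest, volumes, motion = _load_external(cfg)
            first = next(iter(volumes.values()))
            acq = AcquisitionParams(
                tr_s=first.tr_s, n_volumes=first.n_volumes,
                grid_dims=first.grid_dims, voxel_mm=first.voxel_mm,
            )
            wm, csf = synth.default_nuisance_masks(acq.grid_dims)
            if atlas is None:
                raise ValueError("an atlas of template maps is required for external data")
        log_event(stage, n_subjects=len(volumes))
        write_tsv(manifest, "manifest.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- preprocess -----------------------------------------------------
    stage = "preprocess"
    try:
        prepped: dict[str, Volume4D] = {}
        logs = []
        for sid, vol in volumes.items():
            pvol, plog = prep.preprocess_subject(
                vol, motion[sid], wm, csf,
                n_discard=cfg.prep.n_discard,
                trans_thresh_mm=cfg.prep.trans_thresh_mm,
                rot_thresh_deg=cfg.prep.rot_thresh_deg,
                fwhm_mm=cfg.prep.fwhm_mm,
            )
            logs.append(plog)
            if pvol is not None:
                prepped[sid] = pvol
        included = list(prepped)
        n_excluded = len(volumes) - len(included)
        log_event(stage, n_included=len(included), n_excluded=n_excluded)
        if write_outputs:
            with open(out / "prep_log.jsonl", "w") as f:
                for rec in logs:
                    f.write(json.dumps(rec) + "\n")
        if len(included) < 6:
            raise ValueError(f"only {len(included)} subjects survive motion screening")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    groups = {sid: manifest.set_index("subject_id")["group"][sid] for sid in included}

    # ---- group ICA ------------------------------------------------------
    stage = "ica"
    try:
        concat = gica.concat_temporal(prepped)
        dec, order = gica.group_ica(
            concat, k=cfg.ica.k, seed=cfg.seed,
            max_iter=cfg.ica.max_iter, tol=cfg.ica.tol,
            learning_rate=cfg.ica.learning_rate,
        )
        mask3d = concat.mask
        del concat
        log_event(stage, k=int(dec.component_maps.shape[0]),
                  n_iter=dec.n_iter, converged=dec.converged)
        if write_outputs:
            full_maps = np.zeros((dec.component_maps.shape[0],) + mask3d.shape)
            full_maps[:, mask3d] = dec.component_maps
            io.write_maps(full_maps, acq, out / "group_components.nii")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- dual regression ------------------------------------------------
    stage = "dual_regression"
    try:
        subject_sets = {
            sid: gica.dual_regression(dec.component_maps, prepped[sid], mask3d, subject_id=sid)
            for sid in included
        }
        log_event(stage, n_subjects=len(subject_sets))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- network selection ----------------------------------------------
    stage = "select"
    try:
        atlas_flat = {lab: np.asarray(m)[mask3d] for lab, m in atlas.items()}
        assignment = netsel.match_templates(
            dec.component_maps, atlas_flat, threshold=cfg.stats.match_threshold
        )
        labels = list(assignment)
        log_event(stage, matched={l: a.component for l, a in assignment.items()})
        write_tsv(pd.DataFrame([
            {"label": l, "component": a.component, "score": a.score, "matched": a.matched}
            for l, a in assignment.items()
        ]), "rsn_assignment.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- RSN masks + voxel stats ----------------------------------------
    stage = "voxel_stats"
    try:
        rsn_masks: dict[str, np.ndarray] = {}
        anova_maps: dict[str, vstat.VoxelStatMap] = {}
        contrast_maps: dict[str, dict[str, vstat.VoxelStatMap]] = {}
        summary_rows = []
        for lab in labels:
            comp = assignment[lab].component
            smap_stack = np.stack([
                _embed(subject_sets[sid].maps[comp], mask3d) for sid in included
            ])
            m = vstat.rsn_mask(smap_stack, alpha=cfg.stats.mask_alpha,
                               correction=cfg.stats.mask_correction)
            if not m.any():
                # degenerate cohort: fall back to the top 2% of the group map
                gmap = np.abs(_embed(dec.component_maps[comp], mask3d))
                m = gmap >= np.quantile(gmap[mask3d], 0.98)
                log_event(stage, rsn=lab, fallback="group-map threshold")
            rsn_masks[lab] = m
            smaps = {sid: _embed(subject_sets[sid].maps[comp], mask3d) for sid in included}
            anova_maps[lab] = vstat.voxelwise_anova(smaps, groups, m)
            contrast_maps[lab] = vstat.pairwise_contrasts(smaps, groups, m)
            supra = anova_maps[lab].suprathreshold(cfg.stats.anova_alpha)
            summary_rows.append({
                "rsn": lab, "mask_voxels": int(m.sum()),
                "anova_suprathreshold": int(supra.sum()),
            })
        log_event(stage, n_rsns=len(labels))
        write_tsv(pd.DataFrame(summary_rows), "voxel_stats_summary.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- FNC ------------------------------------------------------------
    stage = "fnc"
    try:
        lag_spec = fnc_mod.LagSpec(
            max_lag_s=cfg.fnc.max_lag_s, step_s=cfg.fnc.step_s,
            interpolation=cfg.fnc.interpolation,
        )
        fnc_matrices: dict[str, fnc_mod.FncMatrix] = {}
        for sid in included:
            if cfg.fnc.timecourse_source == "mask":
                tcs = {
                    lab: fnc_mod.extract_timecourse(prepped[sid], rsn_masks[lab], label=lab)
                    for lab in labels
                }
            elif cfg.fnc.timecourse_source == "dualreg":
                tcs = {
                    lab: fnc_mod.NetworkTimeCourse(
                        subject_sets[sid].timecourses[:, assignment[lab].component],
                        tr_s=acq.tr_s, label=lab, subject_id=sid,
                    )
                    for lab in labels
                }
            else:
                raise ValueError(
                    f"unknown timecourse_source {cfg.fnc.timecourse_source!r}"
                )
            fnc_matrices[sid] = fnc_mod.build_fnc_matrix(tcs, lag_spec, subject_id=sid)
        edges = [
            (labels[i], labels[j])
            for i in range(len(labels)) for j in range(i + 1, len(labels))
        ]
        log_event(stage, n_edges=len(edges))
        write_tsv(pd.concat([m.to_long() for m in fnc_matrices.values()],
                            ignore_index=True), "fnc_edges.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- group inference ------------------------------------------------
    stage = "group_inference"
    try:
        z_rows = np.stack([
            _upper(fnc_matrices[sid].z) for sid in included
        ])
        glabels = np.array([groups[sid] for sid in included])
        within = {}
        for g in sorted(set(glabels)):
            within[g] = ginf.within_group_test(
                z_rows[glabels == g], edges, group=g, alpha=cfg.stats.within_alpha
            )
        table = ginf.anova_tukey(z_rows, glabels, edges, alpha=cfg.stats.anova_alpha)
        summary = ginf.summarize_connections(table, alpha=cfg.stats.anova_alpha)
        log_event(stage, n_significant=summary["n_significant"])
        write_tsv(table, "connection_stats.tsv")
        for g, df in within.items():
            write_tsv(df, f"within_group_{g}.tsv")
        write_tsv(summary["table"], "significant_connections.tsv")
        for name, df in summary["contrasts"].items():
            write_tsv(df, f"contrast_{name}.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    result = PipelineResult(
        config=cfg, config_hash=chash, cohort=cohort, prep_logs=logs,
        included=included, order=order, decomposition=dec,
        subject_sets=subject_sets, assignment=assignment, rsn_masks=rsn_masks,
        anova_maps=anova_maps, contrast_maps=contrast_maps,
        fnc_matrices=fnc_matrices, edges=edges, within_group=within,
        connection_table=table, summary=summary, log_events=events,
    )
    if write_outputs:
        with open(out / "run_log.jsonl", "w") as f:
            for ev in events:
                f.write(json.dumps(ev) + "\n")
    return result


def _embed(flat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    full = np.zeros(mask.shape)
    full[mask] = flat
    return full


def _upper(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    return mat[iu]
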
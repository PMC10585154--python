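"""End-to-end orchestration: simulate -> quantify -> analyze -> report.

The pipeline generates a cohort, rebuilds each subject's measurements
through the image-level quantification chain (flow phantom -> CBF, SBO
phantom -> SvO2 -> Fick CMRO2, MRS amplitudes -> lactate, label map ->
volumes), assembles the cohort tables, runs the statistical analyses
and writes a machine-readable summary.  Every output embeds the seed
and a configuration hash; an identical seed yields a byte-identical
summary.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cerebroquant import mrs, pcm, sbo, volumetry
from cerebroquant.config import CohortConfig, default_config
from cerebroquant.stats import (
    fit_group_differences,
    fit_mixed_response,
    fit_volume_response_assoc,
    plot_partial_regression,
)
from cerebroquant.synthetic import phantoms
from cerebroquant.synthetic.cohort import cohort_to_long, cohort_to_wide, generate_cohort
from cerebroquant.utils import config_hash, json_dumps_stable, save_json, save_nifti

log = logging.getLogger("cerebroquant")


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    seed: int = 0
    cohort: CohortConfig | None = None        # None -> calibrated defaults
    output_dir: str = "cerebroquant_run"
    pcm_noise_sd: float = 0.0                 # rad, phantom phase noise
    sbo_noise_sd: float = 0.0                 # rad
    mrs_noise_sd: float = 0.0                 # a.u., lactate-amplitude scale
    responses: tuple[str, ...] = ("cbf", "cmro2", "lactate")
    patients_only: bool = False               # extra volume-response subset fit
    write_images: bool = False                # NIfTI phantoms for first subject
    make_plots: bool = False


def _quantify_subject(rec, rcfg: RunConfig, rng: np.random.Generator,
                      warn_counts: dict) -> dict:
    """Rebuild one subject's measurements through the image-level chain."""
    out = {"subject_id": rec.subject_id, "group": rec.group}

    # volumetry from a synthetic label map (GM/WM/CSF only)
    csf = max(rec.icv - rec.tbv, 1.0)
    labels = phantoms.generate_label_map(rec.gm, rec.wm, csf)
    vols = volumetry.volumes_from_labels(labels)
    out["volumes"] = vols.as_dict()

    brain_mass = rec.tbv * pcm.BRAIN_DENSITY_G_PER_ML
    for cond in ("normoxia", "hypoxia"):
        seed_pair = int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))

        # flow phantom scaled so the quantified inflow reproduces this CBF:
        # calibrate against the discrete (pixelized) flow of the noise-free
        # base phantom, which cancels discretization error exactly (flow is
        # linear in the velocity scale)
        target_flow = rec.cbf[cond] * brain_mass / 100.0           # ml/min
        base = [phantoms.Vessel(v.center, v.radius, v.peak_velocity, v.profile)
                for v in phantoms.DEFAULT_VESSELS]
        phase0, _, rois0 = phantoms.generate_pcm_phantom(base, noise_sd=0.0)
        vel0 = pcm.phase_to_velocity(phase0, venc=100.0)
        discrete_flow = sum(pcm.vessel_flow(vel0, roi) for roi in rois0)
        scale = target_flow / discrete_flow
        for v in base:
            v.peak_velocity *= scale
        phase, true_flows, rois = phantoms.generate_pcm_phantom(
            base, noise_sd=rcfg.pcm_noise_sd, seed=seed_pair[0])
        vel = pcm.phase_to_velocity(phase, venc=100.0, unwrap="shift")
        flows = [pcm.vessel_flow(vel, roi) for roi in rois]
        cbf_q = pcm.total_cbf(flows, rec.tbv)

        # oximetry phantom at the SvO2 implied by this condition's physiology
        sao2_frac = rec.sao2[cond] / 100.0
        svo2_true = sao2_frac - rec.cmro2[cond] / (rec.hgb * rec.cbf[cond])
        svo2_true = float(np.clip(svo2_true, 0.0, 1.0))
        hct = sbo.hct_from_hgb(rec.hgb)
        (p1, p2), sroi, troi, sbo_truth = phantoms.generate_sbo_phantom(
            svo2_true, hct, noise_sd=rcfg.sbo_noise_sd, seed=seed_pair[1])
        oxy = sbo.quantify_sbo(p1, p2, sroi, troi, rec.hgb, cbf_q, sao2_frac)
        if oxy.clipped:
            warn_counts["svo2_clipped"] += 1

        # MRS voxel scaled to the subject's tissue composition
        gmf = rec.mrs_gm_fraction
        wmf, csff = 0.85 * (1.0 - gmf), 0.15 * (1.0 - gmf)
        obs = phantoms.generate_mrs_observation(
            rec.lactate[cond], gmf, wmf, csff,
            noise_sd=rcfg.mrs_noise_sd, seed=seed_pair[0] ^ seed_pair[1])
        lac_q = mrs.lactate_concentration(obs)

        out[cond] = {
            "vessel_flows_ml_min": flows, "total_flow_ml_min": float(np.sum(flows)),
            "cbf": cbf_q, "dphi_rad": oxy.dphi, "svo2": oxy.svo2,
            "sao2": sao2_frac, "cmro2": oxy.cmro2, "lactate": lac_q,
            "truth": {"cbf": rec.cbf[cond], "cmro2": rec.cmro2[cond],
                      "lactate": rec.lactate[cond], "svo2": svo2_true},
        }
    return out


def run_end_to_end(rcfg: RunConfig) -> dict:
    """Run the full pipeline; returns the summary dict (also written to disk)."""
    outdir = Path(rcfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    cohort_cfg = rcfg.cohort if rcfg.cohort is not None else default_config()
    hashed = {**asdict(rcfg), "cohort": asdict(cohort_cfg)}
    for presentation_only in ("output_dir", "write_images", "make_plots"):
        hashed.pop(presentation_only)
    chash = config_hash(hashed)
    meta = {"seed": rcfg.seed, "config_hash": chash}
    warn_counts = {"svo2_clipped": 0}
    summary = {"meta": meta}

    try:
        stage = "simulate"
        log.info("stage %s (seed %d, config %s)", stage, rcfg.seed, chash)
        records = generate_cohort(cohort_cfg, seed=rcfg.seed)
        long_df = cohort_to_long(records)
        wide_df = cohort_to_wide(records)
        long_df.to_csv(outdir / "cohort_long.csv", index=False)
        wide_df.to_csv(outdir / "cohort_wide.csv", index=False)
        save_json({**meta, "subjects": {r.subject_id: r.truth for r in records}},
                  outdir / "ground_truth.json")

        stage = "quantify"
        rng = np.random.default_rng(rcfg.seed + 7)
        quants = []
        for rec in records:
            try:
                quants.append(_quantify_subject(rec, rcfg, rng, warn_counts))
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage} failed for subject {rec.subject_id}: {exc}"
                ) from exc
        save_json({**meta, "subjects": quants}, outdir / "quantification.json")
        if rcfg.write_images:
            rec = records[0]
            phase, _, _ = phantoms.generate_pcm_phantom(seed=rcfg.seed)
            save_nifti(phase, outdir / f"{rec.subject_id}_pcm_phase.nii.gz")
            (p1, p2), *_ = phantoms.generate_sbo_phantom(
                0.64, 0.42, seed=rcfg.seed)
            save_nifti(np.stack([p1, p2], axis=-1),
                       outdir / f"{rec.subject_id}_sbo_phase.nii.gz",
                       voxel_sizes=(0.688, 0.688, 8.0))
            labels = phantoms.generate_label_map(rec.gm, rec.wm,
                                                 max(rec.icv - rec.tbv, 1.0))
            save_nifti(labels, outdir / f"{rec.subject_id}_labels.nii.gz",
                       voxel_sizes=(0.70, 0.70, 0.70))

        stage = "analyze"
        group_sizes = wide_df.groupby("group").size().to_dict()
        summary["cohort"] = {"n": len(records), "group_sizes": group_sizes}
        summary["quantification"] = {
            "n_subjects": len(quants),
            "warnings": warn_counts,
            "max_abs_cbf_error": max(abs(q[c]["cbf"] - q[c]["truth"]["cbf"])
                                     for q in quants
                                     for c in ("normoxia", "hypoxia")),
            "max_abs_lactate_error": max(abs(q[c]["lactate"] - q[c]["truth"]["lactate"])
                                         for q in quants
                                         for c in ("normoxia", "hypoxia")),
        }

        mixed = {}
        for resp in rcfg.responses:
            fit = fit_mixed_response(long_df, resp,
                                     include_gm_covariate=(resp == "lactate"))
            mixed[resp] = {"slope_sao2": fit.slope_sao2,
                           "interaction": fit.interaction,
                           "n_obs": fit.n_obs, "n_subjects": fit.n_subjects}
            fit.coefficients.to_csv(outdir / f"mixed_{resp}.csv")
        summary["mixed_models"] = mixed

        groupdiff = {}
        for outcome in ("tbv", "gm", "wm", "bpf", "cbf_normoxia",
                        "cmro2_normoxia", "lactate_normoxia"):
            tab = fit_group_differences(wide_df, outcome)
            tab.to_csv(outdir / f"groupdiff_{outcome}.csv")
            groupdiff[outcome] = tab.to_dict("index")
        summary["group_differences"] = groupdiff

        assoc = {}
        for vol in ("tbv", "gm"):
            for ratio in ("lactate_ratio", "cbf_ratio"):
                res = fit_volume_response_assoc(wide_df, vol, ratio)
                key = f"{vol}~{ratio}"
                assoc[key] = {"slope": res.slope, "ci_low": res.ci_low,
                              "ci_high": res.ci_high, "pvalue": res.pvalue,
                              "n": res.n}
                if rcfg.make_plots:
                    plot_partial_regression(res.partial,
                                            outdir / f"partial_{vol}_{ratio}.png")
                if rcfg.patients_only:
                    sub = fit_volume_response_assoc(wide_df, vol, ratio,
                                                    patients_only=True)
                    assoc[key + "|patients"] = {
                        "slope": sub.slope, "ci_low": sub.ci_low,
                        "ci_high": sub.ci_high, "pvalue": sub.pvalue, "n": sub.n}
        summary["volume_response"] = assoc
    except Exception:
        summary["status"] = "failed"
        (outdir / "summary.json").write_text(json_dumps_stable(summary) + "\n")
        log.removeHandler(fh)
        raise
    summary["status"] = "ok"
    (outdir / "summary.json").write_text(json_dumps_stable(summary) + "\n")
    log.info("run complete: %s", outdir / "summary.json")
    log.removeHandler(fh)
    return summary
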
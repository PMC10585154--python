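"""Cohort generator.

Draws per-subject demographics, brain volumes and paired
normoxia/hypoxia physiology from the configured group distributions.
Structure (everything else is independent):

* each subject has a true response slope per physiologic variable
  (group slope + individual deviation); the hypoxia value is the
  normoxia value plus slope x (SaO2_hyp - SaO2_norm) plus measurement
  noise;
* gray- and white-matter volumes are linked to the subject's true
  lactate response ratio (ratio = -slope, positive when lactate rises
  under desaturation) and to age and sex, anchored at the healthy-group
  means; total brain volume adds a small unsegmented-parenchyma
  component so the group TBV means match the study table;
* intracranial volume follows from TBV and a drawn parenchymal fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cerebroquant.config import GROUPS, CohortConfig, default_config, resid_sd


@dataclass
class SubjectRecord:
    """One participant: demographics, volumes, paired physiology."""

    subject_id: str
    group: str
    age: float                    # years
    sex: str                      # "F" or "M"
    hgb: float                    # mmol/l (monomer)
    icv: float                    # ml
    tbv: float                    # ml
    gm: float                     # ml
    wm: float                     # ml
    sao2: dict[str, float]        # % per condition {normoxia, hypoxia}
    cbf: dict[str, float]         # ml/100 g/min
    cmro2: dict[str, float]       # umol/100 g/min
    lactate: dict[str, float]     # mmol/l
    mrs_gm_fraction: float        # unitless, [0, 1]
    truth: dict[str, float] = field(default_factory=dict)

    @property
    def bpf(self) -> float:
        return self.tbv / self.icv

    @property
    def desaturation(self) -> float:
        """SaO2 drop from normoxia to hypoxia, percentage points."""
        return self.sao2["normoxia"] - self.sao2["hypoxia"]


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   floor: float) -> float:
    """Normal draw truncated below by redrawing; degenerate sd=0 passes through."""
    if sd == 0.0:
        return max(mean, floor)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > floor:
            return x
    return floor + abs(rng.normal(0.0, sd))


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> list[SubjectRecord]:
    """Generate one synthetic cohort.

    Parameters
    ----------
    config
        Cohort configuration; the study-calibrated defaults when omitted.
    seed
        Overrides ``config.seed`` when given.

    Returns
    -------
    list of SubjectRecord, grouped healthy first, albuminuria last.
    Each record stores its generating ground truth (true slopes, true
    resting values) under ``record.truth``.
    """
    cfg = config if config is not None else default_config()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cov = cfg.covariates
    noise = cfg.noise
    healthy = cfg.groups["healthy"]
    ratio_healthy = -healthy.lactate_slope

    gm_resid = (noise.gm_resid_sd if noise.gm_resid_sd is not None else
                resid_sd(healthy.gm_sd,
                         cfg.volume_response_slope_gm * noise.lactate_slope_sd,
                         cov.age_gm * healthy.age_sd,
                         cov.sex_gm * np.sqrt(healthy.male_prop * (1 - healthy.male_prop))))
    wm_resid = (noise.wm_resid_sd if noise.wm_resid_sd is not None else
                resid_sd(healthy.wm_sd,
                         cfg.volume_response_slope_wm * noise.lactate_slope_sd,
                         cov.age_wm * healthy.age_sd,
                         cov.sex_wm * np.sqrt(healthy.male_prop * (1 - healthy.male_prop))))

    records: list[SubjectRecord] = []
    idx = 0
    for gname in GROUPS:
        g = cfg.groups[gname]
        other_mean = g.tbv_mean - g.gm_mean - g.wm_mean
        for _ in range(g.n):
            idx += 1
            sid = f"S{idx:03d}"
            male = float(rng.random() < g.male_prop)
            age = float(np.clip(rng.normal(g.age_mean, g.age_sd), 18.0, 90.0))
            hgb = _draw_positive(rng, g.hgb_mean, g.hgb_sd, 3.0)

            # true response slopes (units per % SaO2)
            sl_lac = rng.normal(g.lactate_slope, noise.lactate_slope_sd)
            sl_cbf = rng.normal(g.cbf_slope, noise.cbf_slope_sd)
            sl_cmro2 = rng.normal(g.cmro2_slope, noise.cmro2_slope_sd)
            ratio = -sl_lac

            # volumes: healthy anchor + response link + age/sex + residual
            d_age = age - healthy.age_mean
            d_sex = male - healthy.male_prop
            gm = (healthy.gm_mean
                  + cfg.volume_response_slope_gm * (ratio - ratio_healthy)
                  + cov.age_gm * d_age + cov.sex_gm * d_sex
                  + rng.normal(0.0, gm_resid))
            wm = (healthy.wm_mean
                  + cfg.volume_response_slope_wm * (ratio - ratio_healthy)
                  + cov.age_wm * d_age + cov.sex_wm * d_sex
                  + rng.normal(0.0, wm_resid))
            other = max(rng.normal(other_mean, noise.other_parenchyma_sd), 0.0)
            gm, wm = max(gm, 50.0), max(wm, 50.0)
            tbv = gm + wm + other
            bpf = float(np.clip(rng.normal(g.bpf_mean, g.bpf_sd), 0.55, 0.92))
            icv = tbv / bpf

            # paired physiology
            s_norm = min(rng.normal(cfg.sao2_normoxia_mean, cfg.sao2_normoxia_sd), 100.0)
            s_hyp = rng.normal(cfg.sao2_hypoxia_mean, cfg.sao2_hypoxia_sd)
            s_hyp = float(np.clip(s_hyp, 55.0, s_norm - 5.0))
            dsat = s_hyp - s_norm   # negative

            def paired(mean, sd, meas_sd, slope, floor):
                true0 = _draw_positive(rng, mean, resid_sd(sd, meas_sd), floor)
                norm = max(true0 + rng.normal(0.0, meas_sd) if meas_sd else true0, floor)
                hyp = max(true0 + slope * dsat + (rng.normal(0.0, meas_sd) if meas_sd else 0.0), floor)
                return true0, norm, hyp

            lac0, lac_n, lac_h = paired(g.lactate_mean, g.lactate_sd,
                                        noise.lactate_meas_sd, sl_lac, 0.01)
            cbf0, cbf_n, cbf_h = paired(g.cbf_mean, g.cbf_sd,
                                        noise.cbf_meas_sd, sl_cbf, 5.0)
            # oxygen extraction fraction CMRO2/(Hgb*CBF) must stay
            # physiological (venous saturation well inside (0, 1)), so the
            # CMRO2 tails are constrained by the subject's Hgb and CBF
            lo_e, hi_e = 0.10, 0.50
            for _ in range(100):
                cm0, cm_n, cm_h = paired(g.cmro2_mean, g.cmro2_sd,
                                         noise.cmro2_meas_sd, sl_cmro2, 20.0)
                if (lo_e <= cm_n / (hgb * cbf_n) <= hi_e
                        and lo_e <= cm_h / (hgb * cbf_h) <= hi_e):
                    break
            else:
                cm_n = float(np.clip(cm_n, lo_e * hgb * cbf_n, hi_e * hgb * cbf_n))
                cm_h = float(np.clip(cm_h, lo_e * hgb * cbf_h, hi_e * hgb * cbf_h))
                cm0 = (cm_n + cm_h) / 2.0

            gm_frac = float(np.clip(rng.normal(cfg.mrs_gm_fraction_mean,
                                               cfg.mrs_gm_fraction_sd), 0.0, 1.0))

            records.append(SubjectRecord(
                subject_id=sid, group=gname, age=age, sex="M" if male else "F",
                hgb=hgb, icv=icv, tbv=tbv, gm=gm, wm=wm,
                sao2={"normoxia": s_norm, "hypoxia": s_hyp},
                cbf={"normoxia": cbf_n, "hypoxia": cbf_h},
                cmro2={"normoxia": cm_n, "hypoxia": cm_h},
                lactate={"normoxia": lac_n, "hypoxia": lac_h},
                mrs_gm_fraction=gm_frac,
                truth={
                    "lactate_slope": float(sl_lac), "cbf_slope": float(sl_cbf),
                    "cmro2_slope": float(sl_cmro2), "lactate_ratio": float(ratio),
                    "resting_lactate": float(lac0), "resting_cbf": float(cbf0),
                    "resting_cmro2": float(cm0),
                },
            ))
    return records


def cohort_to_long(records: list[SubjectRecord]) -> pd.DataFrame:
    """Long table: one row per subject x condition, ready for model fitting."""
    rows = []
    for r in records:
        for cond in ("normoxia", "hypoxia"):
            rows.append({
                "subject_id": r.subject_id, "group": r.group,
                "condition": cond, "sao2": r.sao2[cond],
                "cbf": r.cbf[cond], "cmro2": r.cmro2[cond],
                "lactate": r.lactate[cond],
                "age": r.age, "sex": 1 if r.sex == "M" else 0,
                "mrs_gm_fraction": r.mrs_gm_fraction,
            })
    return pd.DataFrame(rows)


def cohort_to_wide(records: list[SubjectRecord]) -> pd.DataFrame:
    """Wide table: one row per subject, incl. volumes and response ratios."""
    rows = []
    for r in records:
        dsat = r.desaturation
        rows.append({
            "subject_id": r.subject_id, "group": r.group,
            "age": r.age, "sex": 1 if r.sex == "M" else 0, "hgb": r.hgb,
            "icv": r.icv, "tbv": r.tbv, "gm": r.gm, "wm": r.wm, "bpf": r.bpf,
            "sao2_normoxia": r.sao2["normoxia"], "sao2_hypoxia": r.sao2["hypoxia"],
            "cbf_normoxia": r.cbf["normoxia"], "cbf_hypoxia": r.cbf["hypoxia"],
            "cmro2_normoxia": r.cmro2["normoxia"], "cmro2_hypoxia": r.cmro2["hypoxia"],
            "lactate_normoxia": r.lactate["normoxia"],
            "lactate_hypoxia": r.lactate["hypoxia"],
            "mrs_gm_fraction": r.mrs_gm_fraction,
            "lactate_ratio": (r.lactate["hypoxia"] - r.lactate["normoxia"]) / dsat,
            "cbf_ratio": (r.cbf["hypoxia"] - r.cbf["normoxia"]) / dsat,
            "true_lactate_ratio": r.truth["lactate_ratio"],
        })
    return pd.DataFrame(rows)
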
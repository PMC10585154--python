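"""Cohort configuration for the synthetic-data generator.

The default configuration emulates a three-group case-control hypoxia
study: healthy controls (n=19), type-1-diabetes patients without
albuminuria (n=22) and with albuminuria (n=11).  Group marginals (age,
sex, hemoglobin, brain volumes, resting physiology) reproduce the study's
summary tables; the structural links the generator models are

* physiologic response to desaturation: per-group true slope of each
  variable versus SaO2 (mmol/l, ml/100g/min or umol/100g/min per %
  saturation), with between-subject slope heterogeneity;
* brain volumes linked to the subject's true lactate response ratio
  (ml per ratio-unit) and to age and sex.

Group differences in brain volume are carried entirely by the age effect
and the response link (no per-group volume intercepts), so that a
volume ~ response-ratio regression adjusted for age and sex recovers the
configured link slope without bias.  The age-effect defaults are derived
below from the calibration identity that makes the albuminuria group's
gray- and white-matter means land on the summary-table values.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

GROUPS = ("healthy", "t1d_no_alb", "t1d_alb")


@dataclass
class GroupParams:
    """Marginal distributions and true response slopes for one group."""

    n: int
    male_prop: float          # proportion of males
    age_mean: float           # years
    age_sd: float
    hgb_mean: float           # mmol/l (hemoglobin monomer)
    hgb_sd: float
    gm_mean: float            # ml
    gm_sd: float
    wm_mean: float            # ml
    wm_sd: float
    tbv_mean: float           # ml, incl. unsegmented parenchyma
    bpf_mean: float           # brain parenchymal fraction
    bpf_sd: float
    cbf_mean: float           # ml/100 g/min, resting
    cbf_sd: float
    cmro2_mean: float         # umol/100 g/min, resting
    cmro2_sd: float
    lactate_mean: float       # mmol/l, resting
    lactate_sd: float
    # true response slopes, units of the variable per % SaO2
    lactate_slope: float
    cbf_slope: float
    cmro2_slope: float


@dataclass
class NoiseParams:
    """Between-subject slope heterogeneity and per-condition measurement noise."""

    lactate_slope_sd: float = 0.006    # mmol/l per %
    cbf_slope_sd: float = 0.25         # (ml/100g/min) per %
    cmro2_slope_sd: float = 0.40       # (umol/100g/min) per %
    lactate_meas_sd: float = 0.01      # mmol/l
    cbf_meas_sd: float = 1.5           # ml/100g/min
    cmro2_meas_sd: float = 6.0         # umol/100g/min
    other_parenchyma_sd: float = 8.0   # ml
    gm_resid_sd: float | None = None   # ml; None -> derived from gm_sd
    wm_resid_sd: float | None = None


@dataclass
class CovariateEffects:
    """Age and sex effects on brain volumes (ml/year, ml for male vs female)."""

    age_gm: float
    age_wm: float
    sex_gm: float = 40.0
    sex_wm: float = 35.0


@dataclass
class CohortConfig:
    groups: dict[str, GroupParams]
    noise: NoiseParams = field(default_factory=NoiseParams)
    covariates: CovariateEffects | None = None   # None -> calibrated defaults
    # brain-volume link to the true lactate response ratio, ml per ratio-unit
    volume_response_slope_gm: float = 1405.0
    volume_response_slope_wm: float = 2407.0
    sao2_normoxia_mean: float = 98.0   # %
    sao2_normoxia_sd: float = 1.0
    sao2_hypoxia_mean: float = 78.0
    sao2_hypoxia_sd: float = 4.0
    mrs_gm_fraction_mean: float = 0.55
    mrs_gm_fraction_sd: float = 0.05
    seed: int = 0

    @property
    def volume_response_slope(self) -> float:
        """Total-brain-volume link (GM link + WM link), ml per ratio-unit."""
        return self.volume_response_slope_gm + self.volume_response_slope_wm

    def validate(self) -> None:
        for name, g in self.groups.items():
            if g.n < 1:
                raise ValueError(f"group size for '{name}' must be >= 1, got {g.n}")
            if not 0.0 <= g.male_prop <= 1.0:
                raise ValueError(f"male_prop for '{name}' must be in [0, 1]")
            for fld, val in asdict(g).items():
                if fld.endswith("_sd") and val < 0:
                    raise ValueError(f"negative sd in group '{name}': {fld} = {val}")
        for fld, val in asdict(self.noise).items():
            if val is not None and val < 0:
                raise ValueError(f"negative sd: noise.{fld} = {val}")
        for fld in ("sao2_normoxia_sd", "sao2_hypoxia_sd", "mrs_gm_fraction_sd"):
            if getattr(self, fld) < 0:
                raise ValueError(f"negative sd: {fld}")
        if self.sao2_hypoxia_mean >= self.sao2_normoxia_mean:
            raise ValueError("hypoxia SaO2 mean must be below normoxia SaO2 mean")


def _calibrated_age_effects(groups: dict[str, GroupParams],
                            link_gm: float, link_wm: float,
                            sex_gm: float, sex_wm: float) -> tuple[float, float]:
    """Age slopes (ml/year) that place the albuminuria-group GM/WM means on
    their configured values given the response link and demographics."""
    h, a = groups["healthy"], groups["t1d_alb"]
    d_age = a.age_mean - h.age_mean
    d_sex = a.male_prop - h.male_prop
    # ratio = -lactate slope, so the link contribution uses the slope difference
    d_ratio = -(a.lactate_slope - h.lactate_slope)
    age_gm = (a.gm_mean - h.gm_mean - link_gm * d_ratio - sex_gm * d_sex) / d_age
    age_wm = (a.wm_mean - h.wm_mean - link_wm * d_ratio - sex_wm * d_sex) / d_age
    return age_gm, age_wm


def default_groups() -> dict[str, GroupParams]:
    return {
        "healthy": GroupParams(
            n=19, male_prop=12 / 19, age_mean=45.0, age_sd=14.0,
            hgb_mean=8.9, hgb_sd=0.6,
            gm_mean=632.0, gm_sd=52.0, wm_mean=478.0, wm_sd=54.0,
            tbv_mean=1139.0, bpf_mean=0.78, bpf_sd=0.02,
            cbf_mean=42.0, cbf_sd=4.9, cmro2_mean=124.8, cmro2_sd=20.5,
            lactate_mean=0.53, lactate_sd=0.12,
            lactate_slope=-0.012, cbf_slope=-0.40, cmro2_slope=0.0,
        ),
        "t1d_no_alb": GroupParams(
            n=22, male_prop=9 / 22, age_mean=47.3, age_sd=12.9,
            hgb_mean=8.9, hgb_sd=0.7,
            gm_mean=628.0, gm_sd=49.0, wm_mean=482.0, wm_sd=65.0,
            tbv_mean=1139.0, bpf_mean=0.78, bpf_sd=0.03,
            cbf_mean=41.3, cbf_sd=8.6, cmro2_mean=130.9, cmro2_sd=32.8,
            lactate_mean=0.48, lactate_sd=0.10,
            lactate_slope=-0.010, cbf_slope=-0.40, cmro2_slope=0.0,
        ),
        "t1d_alb": GroupParams(
            n=11, male_prop=7 / 11, age_mean=56.0, age_sd=10.8,
            hgb_mean=8.6, hgb_sd=0.7,
            gm_mean=585.0, gm_sd=45.0, wm_mean=441.0, wm_sd=55.0,
            tbv_mean=1053.0, bpf_mean=0.75, bpf_sd=0.03,
            cbf_mean=39.3, cbf_sd=8.6, cmro2_mean=117.6, cmro2_sd=23.4,
            lactate_mean=0.42, lactate_sd=0.09,
            lactate_slope=-0.004, cbf_slope=-0.20, cmro2_slope=0.0,
        ),
    }


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The study-calibrated default configuration.

    Keyword overrides replace top-level CohortConfig fields.
    """
    cfg = CohortConfig(groups=default_groups(), seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    if cfg.covariates is None:
        sex_gm, sex_wm = 40.0, 35.0
        age_gm, age_wm = _calibrated_age_effects(
            cfg.groups, cfg.volume_response_slope_gm, cfg.volume_response_slope_wm,
            sex_gm, sex_wm)
        cfg.covariates = CovariateEffects(
            age_gm=age_gm, age_wm=age_wm, sex_gm=sex_gm, sex_wm=sex_wm)
    cfg.validate()
    return cfg


def resid_sd(total_sd: float, *components: float) -> float:
    """Residual sd left after removing variance of known components.

    Clamped at zero when the components overshoot the marginal sd.
    """
    v = total_sd ** 2 - sum(c ** 2 for c in components)
    return math.sqrt(max(v, 0.0))


def load_config(path: str | Path) -> CohortConfig:
    """Load a cohort configuration from YAML, layered over the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config(seed=raw.pop("seed", 0))
    for gname, gfields in (raw.pop("groups", {}) or {}).items():
        if gname not in cfg.groups:
            raise ValueError(f"unknown group '{gname}'")
        cfg.groups[gname] = replace(cfg.groups[gname], **gfields)
    if "noise" in raw:
        cfg.noise = replace(cfg.noise, **raw.pop("noise"))
    if "covariates" in raw:
        cfg.covariates = replace(cfg.covariates, **raw.pop("covariates"))
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config field '{key}'")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


def dump_config(cfg: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
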
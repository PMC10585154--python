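"""Absolute MRS lactate quantification with internal water referencing.

The fitted lactate methyl-doublet amplitude is scaled by the voxel's
water amplitude.  Both signals are corrected back to TE = 0 with
literature T2 values, the water signal is converted to an absolute
concentration via the voxel's tissue composition (GM/WM/CSF fractions
times compartment water contents times pure-water molarity), and the
proton counts (2 for water, 3 for the lactate methyl group) are divided
out.  Concentrations are "wet", per liter of water-visible voxel
tissue; no CSF-exclusion renormalization is applied (tissue composition
is instead handled as a statistical covariate downstream).

T1 saturation effects are neglected: at TR = 3000 ms the residual
saturation of water and lactate is small and largely cancels in the
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RelaxationTable:
    """Literature relaxation and water-content constants (editable).

    T2 values in ms, water contents as fractions of pure water,
    pure-water molarity in mmol/l.
    """

    t2_water_gm: float = 90.0
    t2_water_wm: float = 70.0
    t2_water_csf: float = 500.0
    t2_lactate: float = 240.0
    water_content_gm: float = 0.78
    water_content_wm: float = 0.65
    water_content_csf: float = 0.97
    pure_water_molarity: float = 55510.0

    def __post_init__(self):
        for name in ("t2_water_gm", "t2_water_wm", "t2_water_csf", "t2_lactate",
                     "pure_water_molarity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("water_content_gm", "water_content_wm", "water_content_csf"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class MRSObservation:
    """Fitted spectral amplitudes plus voxel tissue composition."""

    lactate_amplitude: float      # a.u.
    water_amplitude: float        # a.u.
    te: float                     # ms
    gm_frac: float
    wm_frac: float
    csf_frac: float
    voxel_dims: tuple[float, float, float] = (30.0, 35.0, 30.0)   # mm
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lactate_amplitude < 0 or self.water_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        s = self.gm_frac + self.wm_frac + self.csf_frac
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"tissue fractions must sum to 1, got {s:.6f}")


def voxel_water_concentration(gm_frac: float, wm_frac: float, csf_frac: float,
                              table: RelaxationTable | None = None) -> float:
    """Water concentration of the voxel in mmol/l: the tissue-fraction-
    weighted sum of compartment water contents times pure-water molarity."""
    s = gm_frac + wm_frac + csf_frac
    if any(f < 0 for f in (gm_frac, wm_frac, csf_frac)) or abs(s - 1.0) > 1e-6:
        raise ValueError("tissue fractions must be non-negative and sum to 1")
    tab = table or RelaxationTable()
    return tab.pure_water_molarity * (gm_frac * tab.water_content_gm
                                      + wm_frac * tab.water_content_wm
                                      + csf_frac * tab.water_content_csf)


def lactate_concentration(obs: MRSObservation,
                          table: RelaxationTable | None = None) -> float:
    """Absolute lactate concentration, mmol/l.

    Both amplitudes are decay-corrected to TE = 0: the lactate amplitude
    by exp(TE/T2_lactate), the water amplitude by the composite decay of
    its compartments (each weighted by tissue fraction and water
    content).  The ratio, times the water/lactate proton-count ratio 2/3
    and the voxel water concentration, gives mmol/l.
    """
    if obs.water_amplitude <= 0:
        raise ValueError("water amplitude must be positive")
    tab = table or RelaxationTable()
    fracs = (obs.gm_frac, obs.wm_frac, obs.csf_frac)
    contents = (tab.water_content_gm, tab.water_content_wm, tab.water_content_csf)
    t2s = (tab.t2_water_gm, tab.t2_water_wm, tab.t2_water_csf)
    # composite water decay factor at this TE (fraction of the TE=0 signal)
    w_te = sum(f * w * np.exp(-obs.te / t2) for f, w, t2 in zip(fracs, contents, t2s))
    w_0 = sum(f * w for f, w in zip(fracs, contents))
    water_corrected = obs.water_amplitude / (w_te / w_0)
    lac_corrected = obs.lactate_amplitude * np.exp(obs.te / tab.t2_lactate)
    conc_w = voxel_water_concentration(*fracs, table=tab)
    return float((lac_corrected / water_corrected) * (2.0 / 3.0) * conc_w)
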
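"""Susceptibility-based oximetry and Fick-principle CMRO2.

Deoxyhemoglobin makes venous blood paramagnetic relative to tissue.  For
a long cylindrical vessel at angle theta to B0, the intravascular field
offset is

    dB = 1/2 * dchi_do * Hct * (1 - SvO2) * B0 * (cos^2 theta - 1/3)

with dchi_do the susceptibility difference between fully deoxygenated
and fully oxygenated red cells (SI volume units).  The phase a dual-echo
gradient-echo acquisition accrues between the echoes, referenced to
adjacent tissue, is gamma * dB * dTE; inverting it yields SvO2.  The
small susceptibility offset of fully oxygenated blood relative to tissue
is neglected (systematic approximation of order a few percent
saturation).

CMRO2 follows from the Fick principle: the brain extracts
(SaO2 - SvO2) of the oxygen carried in, so

    CMRO2 = Hgb * CBF * (SaO2 - SvO2)

with Hgb in mmol/l of hemoglobin monomer (one O2 binding site per
monomer; mmol/l = umol/ml) and CBF in ml/100 g/min, giving CMRO2 in
umol/100 g/min.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from cerebroquant.utils import wrap_phase

GAMMA_RAD_S_T = 2.6752218744e8          # proton gyromagnetic ratio
DCHI_DO_SI = 4.0 * math.pi * 0.27e-6    # fully deoxy vs oxy red cells, SI
HGB_MW_MONOMER = 16114.0                # g/mol
HCT_PER_G_DL = 0.03                     # hematocrit per g/dl hemoglobin
MAGIC_ANGLE_DEG = math.degrees(math.acos(math.sqrt(1.0 / 3.0)))


@dataclass
class SboAcquisition:
    """Dual-echo gradient-echo acquisition parameters."""

    b0: float = 3.0              # T
    te1: float = 8.07            # ms
    te2: float = 17.77           # ms
    theta_deg: float = 0.0       # vessel angle to B0
    gamma: float = GAMMA_RAD_S_T

    def __post_init__(self):
        if self.te2 <= self.te1:
            raise ValueError("te2 must exceed te1")
        if abs(self.theta_deg) >= MAGIC_ANGLE_DEG:
            raise ValueError(
                f"|theta| must be below the magic angle ({MAGIC_ANGLE_DEG:.1f} deg) "
                "for the intravascular cylinder model")

    @property
    def dte_s(self) -> float:
        return (self.te2 - self.te1) * 1e-3

    @property
    def geometry_factor(self) -> float:
        return math.cos(math.radians(self.theta_deg)) ** 2 - 1.0 / 3.0


@dataclass
class BloodModel:
    """Blood susceptibility constants and the Hgb -> Hct conversion."""

    hct: float = 0.42
    dchi_do: float = DCHI_DO_SI
    hgb_mw_monomer: float = HGB_MW_MONOMER
    hct_per_gdl: float = HCT_PER_G_DL

    def __post_init__(self):
        if not 0.0 < self.hct < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.dchi_do <= 0:
            raise ValueError("dchi_do must be positive")


@dataclass
class OxygenationResult:
    dphi: float      # rad
    svo2: float      # fraction
    sao2: float      # fraction
    cmro2: float     # umol/100 g/min
    clipped: bool = False


def sbo_phase_offset(svo2: float, acq: SboAcquisition, blood: BloodModel) -> float:
    """Forward model: inter-echo sinus-minus-tissue phase offset, rad."""
    return (0.5 * acq.gamma * acq.b0 * acq.dte_s * blood.dchi_do * blood.hct
            * (1.0 - svo2) * acq.geometry_factor)


def svo2_from_phase(dphi: float, acq: SboAcquisition,
                    blood: BloodModel) -> tuple[float, bool]:
    """Invert the cylinder model: venous saturation from the phase offset.

    Returns (svo2, clipped); svo2 is clipped into [0, 1] with a warning
    when the offset is outside the physical range.
    """
    scale = (0.5 * acq.gamma * acq.b0 * acq.dte_s * blood.dchi_do * blood.hct
             * acq.geometry_factor)
    svo2 = 1.0 - dphi / scale
    clipped = not 0.0 <= svo2 <= 1.0
    if clipped:
        warnings.warn(f"SvO2 = {svo2:.3f} outside [0, 1]; clipping", stacklevel=2)
        svo2 = float(np.clip(svo2, 0.0, 1.0))
    return svo2, clipped


def interecho_phase_difference(phase_te1: np.ndarray, phase_te2: np.ndarray,
                               sinus_roi: np.ndarray,
                               tissue_roi: np.ndarray) -> float:
    """Sinus-minus-tissue inter-echo phase difference, rad.

    Per-pixel differences are rewrapped into (-pi, pi], which undoes any
    single 2*pi wrap accrued between the echoes.  An ROI whose wrapped
    differences are wildly inconsistent (circular spread > pi/2) signals
    phase evolution beyond a single wrap and raises.
    """
    sinus = np.asarray(sinus_roi, dtype=bool)
    tissue = np.asarray(tissue_roi, dtype=bool)
    if not sinus.any() or not tissue.any():
        raise ValueError("empty ROI")
    if (sinus & tissue).any():
        raise ValueError("sinus and tissue ROIs must be disjoint")
    diff = wrap_phase(np.asarray(phase_te2, float) - np.asarray(phase_te1, float))
    means = []
    for name, mask in (("sinus", sinus), ("tissue", tissue)):
        vals = diff[mask]
        # circular mean/spread: robust to values straddling the +/-pi seam
        z = np.exp(1j * vals)
        r = abs(z.mean())
        if r < 0.5 or np.sqrt(max(-2.0 * np.log(max(r, 1e-12)), 0.0)) > np.pi / 2:
            raise ValueError(f"{name} ROI phase differences exceed single-wrap "
                             "correction (inconsistent wrapped values)")
        means.append(float(np.angle(z.mean())))
    return wrap_phase(means[0] - means[1]).item()


def hct_from_hgb(hgb_mmol_l: float, blood: BloodModel | None = None) -> float:
    """Hematocrit fraction from hemoglobin in mmol/l of monomer.

    mmol/l -> g/dl via the monomer molar weight, then the standard
    ~3 percentage points of hematocrit per g/dl.
    """
    if hgb_mmol_l <= 0:
        raise ValueError("hemoglobin must be positive")
    b = blood or BloodModel()
    g_dl = hgb_mmol_l * b.hgb_mw_monomer / 10000.0
    return g_dl * b.hct_per_gdl


def hgb_gdl_to_mmol_l(hgb_g_dl: float,
                      mw_monomer: float = HGB_MW_MONOMER) -> float:
    """Convert hemoglobin from g/dl to mmol/l of monomer."""
    if hgb_g_dl <= 0:
        raise ValueError("hemoglobin must be positive")
    return hgb_g_dl * 10000.0 / mw_monomer


def cmro2_fick(hgb_mmol_l: float, cbf: float, sao2: float, svo2: float) -> float:
    """CMRO2 in umol/100 g/min by the Fick principle.

    Parameters are hemoglobin (mmol/l monomer, one O2 per monomer), CBF
    (ml/100 g/min) and arterial/venous saturations as fractions.
    """
    if hgb_mmol_l <= 0 or cbf <= 0:
        raise ValueError("hemoglobin and CBF must be positive")
    if not 0.0 <= svo2 <= 1.0 or not 0.0 < sao2 <= 1.0:
        raise ValueError("saturations must be fractions in [0, 1]")
    if sao2 < svo2:
        raise ValueError("SaO2 below SvO2: physically inconsistent pair")
    return hgb_mmol_l * cbf * (sao2 - svo2)


def quantify_sbo(phase_te1, phase_te2, sinus_roi, tissue_roi,
                 hgb_mmol_l: float, cbf: float, sao2: float,
                 acq: SboAcquisition | None = None) -> OxygenationResult:
    """Full SBO chain: phase offset -> SvO2 -> Fick CMRO2."""
    acq = acq or SboAcquisition()
    dphi = interecho_phase_difference(phase_te1, phase_te2, sinus_roi, tissue_roi)
    blood = BloodModel(hct=hct_from_hgb(hgb_mmol_l))
    svo2, clipped = svo2_from_phase(dphi, acq, blood)
    return OxygenationResult(dphi=dphi, svo2=svo2, sao2=sao2,
                             cmro2=cmro2_fick(hgb_mmol_l, cbf, sao2, svo2),
                             clipped=clipped)
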
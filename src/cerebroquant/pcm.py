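"""Phase-contrast flow quantification.

Velocity-encoded phase images map through-plane blood velocity linearly
into pixel phase, v = venc * phi / pi, with the venc (here 100 cm/s by
default) producing a full pi shift.  Vessel flow is the spatial mean
velocity over a vessel ROI times the ROI cross-sectional area; total
inflow over the feeding arteries (both internal carotids and the basilar
artery) normalized to brain mass gives CBF in ml/100 g/min.

Acquisitions are assumed ungated, so a single image represents the
time-averaged velocity.  Aliasing correction is single-wrap only: a
pixel whose velocity opposes the expected flow direction by more than
venc/2 is assumed to have wrapped once and is shifted by 2*venc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BRAIN_DENSITY_G_PER_ML = 1.05


@dataclass
class VelocityImage:
    """Velocity map (cm/s) with pixel geometry."""

    data: np.ndarray          # cm/s
    pixel_area: float         # mm^2
    venc: float               # cm/s

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")


def phase_to_velocity(phase: np.ndarray, venc: float,
                      pixel_area: float = 0.75 ** 2,
                      unwrap: str = "none",
                      direction: int = +1) -> VelocityImage:
    """Convert a wrapped phase image (rad) to a velocity map (cm/s).

    Parameters
    ----------
    phase
        Phase image in (-pi, pi].
    venc
        Velocity encoding, cm/s.
    unwrap
        "none" maps phase linearly.  "shift" additionally corrects
        single-wrap aliasing: pixels whose velocity opposes ``direction``
        by more than venc/2 get one 2*pi wrap undone.
    direction
        Expected flow sign (+1 caudocranial positive).
    """
    if venc <= 0:
        raise ValueError("venc must be positive")
    if unwrap not in ("none", "shift"):
        raise ValueError(f"unknown unwrap policy '{unwrap}'")
    phase = np.asarray(phase, dtype=float)
    v = venc * phase / np.pi
    if unwrap == "shift":
        wrapped = direction * v < -venc / 2.0
        v = np.where(wrapped, v + direction * 2.0 * venc, v)
        if np.any(np.abs(v) > 2.0 * venc):
            raise ValueError("velocities beyond a single wrap are unrecoverable")
    return VelocityImage(data=v, pixel_area=pixel_area, venc=venc)


def vessel_flow(vel: VelocityImage, roi: np.ndarray) -> float:
    """Blood flow through one vessel ROI, ml/min (sign preserved).

    flow = mean velocity over the ROI x ROI area.  A pixel belongs to
    the vessel when its mask value is >= 0.5 (no sub-pixel correction).
    """
    mask = np.asarray(roi)
    if mask.dtype != bool:
        mask = mask >= 0.5
    if mask.shape != vel.data.shape:
        raise ValueError("ROI shape does not match image")
    npix = int(mask.sum())
    if npix == 0:
        raise ValueError("empty vessel ROI")
    mean_v_mm_s = float(vel.data[mask].mean()) * 10.0     # cm/s -> mm/s
    area_mm2 = npix * vel.pixel_area
    return mean_v_mm_s * area_mm2 * 60.0 / 1000.0          # mm^3/s -> ml/min


def total_cbf(flows, brain_volume: float,
              brain_density: float = BRAIN_DENSITY_G_PER_ML) -> float:
    """Normalize summed arterial inflow to brain mass: CBF in ml/100 g/min."""
    flows = np.atleast_1d(np.asarray(flows, dtype=float))
    if flows.size == 0:
        raise ValueError("at least one vessel flow required")
    if brain_volume <= 0:
        raise ValueError("brain volume must be positive")
    if brain_density <= 0:
        raise ValueError("brain density must be positive")
    return float(flows.sum()) / (brain_volume * brain_density) * 100.0
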
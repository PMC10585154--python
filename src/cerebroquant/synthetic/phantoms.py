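"""Image-level phantoms for each quantification stage.

Each phantom is generated from analytic ground truth (vessel flows, the
venous saturation behind a susceptibility phase offset, a known lactate
concentration, known tissue volumes) and returns that truth alongside
the images, so the quantification operations can be validated exactly in
the noise-free limit and within noise-propagated bounds otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from cerebroquant.mrs import MRSObservation, RelaxationTable
from cerebroquant.sbo import BloodModel, SboAcquisition, sbo_phase_offset
from cerebroquant.utils import wrap_phase


@dataclass
class Vessel:
    """Circular vessel cross-section in the imaging slice."""

    center: tuple[float, float]       # mm, (x, y)
    radius: float                     # mm
    peak_velocity: float              # cm/s (through-plane)
    profile: Literal["uniform", "parabolic"] = "parabolic"

    @property
    def area(self) -> float:
        """Cross-sectional area, mm^2."""
        return np.pi * self.radius ** 2

    @property
    def mean_velocity(self) -> float:
        """Spatial mean velocity, cm/s (parabolic profile averages to half peak)."""
        return self.peak_velocity if self.profile == "uniform" else self.peak_velocity / 2.0

    @property
    def true_flow(self) -> float:
        """Analytic flow, ml/min: area x mean velocity (1 cm/s = 10 mm/s)."""
        return self.area * self.mean_velocity * 10.0 * 60.0 / 1000.0


DEFAULT_VESSELS = (
    Vessel(center=(-12.0, 0.0), radius=2.5, peak_velocity=42.0, profile="parabolic"),
    Vessel(center=(12.0, 0.0), radius=2.5, peak_velocity=42.0, profile="parabolic"),
    Vessel(center=(0.0, 10.0), radius=1.7, peak_velocity=35.0, profile="parabolic"),
)


def generate_pcm_phantom(vessels=DEFAULT_VESSELS,
                         pixel_size: float = 0.75,
                         venc: float = 100.0,
                         noise_sd: float = 0.0,
                         seed: int | None = None,
                         fov: float = 48.0):
    """Velocity-encoded phase image of circular vessels in static tissue.

    Pixel phase is pi * v / venc wrapped into (-pi, pi], so velocities
    beyond the venc alias, as in an acquisition.

    Returns
    -------
    phase : 2-D array, rad
    true_flows : list of float, ml/min per vessel (analytic)
    rois : list of 2-D bool arrays, one mask per vessel
    """
    if venc <= 0:
        raise ValueError("venc must be positive")
    for v in vessels:
        if v.radius <= 0:
            raise ValueError("vessel radius must be positive")
    n = int(round(fov / pixel_size))
    coords = (np.arange(n) + 0.5) * pixel_size - fov / 2.0
    x, y = np.meshgrid(coords, coords, indexing="xy")

    velocity = np.zeros((n, n))
    rois = []
    for v in vessels:
        r2 = (x - v.center[0]) ** 2 + (y - v.center[1]) ** 2
        mask = r2 <= v.radius ** 2
        if v.profile == "uniform":
            velocity[mask] = v.peak_velocity
        else:
            velocity[mask] = v.peak_velocity * (1.0 - r2[mask] / v.radius ** 2)
        rois.append(mask)

    phase = np.pi * velocity / venc
    if noise_sd:
        rng = np.random.default_rng(seed)
        phase = phase + rng.normal(0.0, noise_sd, phase.shape)
    return wrap_phase(phase), [v.true_flow for v in vessels], rois


def generate_sbo_phantom(svo2_true: float,
                         hct: float,
                         theta_deg: float = 0.0,
                         b0: float = 3.0,
                         te1: float = 8.07,
                         te2: float = 17.77,
                         noise_sd: float = 0.0,
                         seed: int | None = None,
                         tissue_rate: float = 20.0,
                         size: int = 64):
    """Dual-echo phase images of a sagittal-sinus cross-section in tissue.

    The sinus accrues phase faster than tissue by the forward
    infinite-cylinder rate for deoxygenated blood at the given Hct and
    saturation; both ROIs share a background phase evolution
    (``tissue_rate``, rad/s).  Phases are wrapped into (-pi, pi].

    Returns
    -------
    (phase_te1, phase_te2) : 2-D arrays, rad
    sinus_roi, tissue_roi : 2-D bool arrays (disjoint)
    truth : dict with the noise-free inter-echo phase offset ``dphi``.
    """
    if not 0.0 <= svo2_true <= 1.0:
        raise ValueError("svo2_true must lie in [0, 1]")
    if te2 <= te1:
        raise ValueError("te2 must exceed te1")
    acq = SboAcquisition(b0=b0, te1=te1, te2=te2, theta_deg=theta_deg)
    blood = BloodModel(hct=hct)
    dphi = sbo_phase_offset(svo2_true, acq, blood)
    domega = dphi / acq.dte_s       # rad/s

    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    sinus_roi = r2 <= 4 ** 2
    tissue_roi = (r2 >= 8 ** 2) & (r2 <= 14 ** 2)

    rng = np.random.default_rng(seed)
    imgs = []
    for te_ms in (te1, te2):
        rate = np.where(sinus_roi, tissue_rate + domega, tissue_rate)
        ph = rate * te_ms * 1e-3
        if noise_sd:
            ph = ph + rng.normal(0.0, noise_sd, ph.shape)
        imgs.append(wrap_phase(ph))
    return (imgs[0], imgs[1]), sinus_roi, tissue_roi, {"dphi": dphi,
                                                       "svo2": svo2_true}


def generate_mrs_observation(lactate_true: float,
                             gm_frac: float,
                             wm_frac: float,
                             csf_frac: float,
                             te: float = 288.0,
                             noise_sd: float = 0.0,
                             seed: int | None = None,
                             table: RelaxationTable | None = None,
                             gain: float = 1.0) -> MRSObservation:
    """Forward-simulate fitted lactate and water amplitudes for one voxel.

    Signal model per species: concentration x proton count x exp(-TE/T2),
    times an arbitrary receiver gain common to both peaks.  The
    water amplitude pools the GM/WM/CSF compartments weighted by tissue
    fraction and compartment water content.  ``noise_sd`` is relative to
    the lactate amplitude scale.
    """
    fracs = (gm_frac, wm_frac, csf_frac)
    if any(f < 0 for f in fracs):
        raise ValueError("tissue fractions must be non-negative")
    if abs(sum(fracs) - 1.0) > 1e-6:
        raise ValueError(f"tissue fractions must sum to 1, got {sum(fracs):.6f}")
    if lactate_true < 0:
        raise ValueError("lactate concentration must be non-negative")
    tab = table or RelaxationTable()
    contents = (tab.water_content_gm, tab.water_content_wm, tab.water_content_csf)
    t2s = (tab.t2_water_gm, tab.t2_water_wm, tab.t2_water_csf)

    a_water = gain * 2.0 * tab.pure_water_molarity * sum(
        f * w * np.exp(-te / t2) for f, w, t2 in zip(fracs, contents, t2s))
    a_lac = gain * 3.0 * lactate_true * np.exp(-te / tab.t2_lactate)
    if noise_sd:
        rng = np.random.default_rng(seed)
        a_lac += gain * rng.normal(0.0, noise_sd)
        a_water *= 1.0 + rng.normal(0.0, noise_sd * 1e-3)
        a_lac = max(a_lac, 0.0)
    return MRSObservation(lactate_amplitude=float(a_lac),
                          water_amplitude=float(a_water), te=te,
                          gm_frac=gm_frac, wm_frac=wm_frac, csf_frac=csf_frac,
                          truth={"lactate": lactate_true})


def generate_label_map(gm_ml: float, wm_ml: float, csf_ml: float,
                       voxel_mm: float = 0.70) -> np.ndarray:
    """3-D label volume (0 background, 1 GM, 2 WM, 3 CSF) with voxel counts
    matching the requested volumes to the nearest voxel."""
    for name, v in (("gm", gm_ml), ("wm", wm_ml), ("csf", csf_ml)):
        if v < 0:
            raise ValueError(f"negative {name} volume")
    vox_vol = voxel_mm ** 3
    counts = [int(round(v * 1000.0 / vox_vol)) for v in (gm_ml, wm_ml, csf_ml)]
    total = sum(counts)
    side = max(int(np.ceil((total + 1) ** (1.0 / 3.0))) + 2, 4)
    flat = np.zeros(side ** 3, dtype=np.int16)
    pos = 0
    for label, cnt in zip((1, 2, 3), counts):
        flat[pos:pos + cnt] = label
        pos += cnt
    return flat.reshape((side, side, side))
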
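"""Hypoxic-challenge physiology traces.

SaO2 follows an exponential approach from baseline to the hypoxic
plateau after the onset of hypoxic-air inhalation; end-tidal CO2 falls
(hypoxic hyperventilation) and heart rate rises modestly on the same
time scale.  Noise is temporally smoothed to mimic the slow
physiological fluctuations a pulse oximeter reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d


@dataclass
class PhysioTrace:
    time: np.ndarray          # s
    sao2: np.ndarray          # %
    petco2: np.ndarray        # mmHg
    heart_rate: np.ndarray    # beats/min
    hypoxia_onset: float      # s


def generate_physio_trace(baseline_sao2: float = 98.0,
                          plateau_sao2: float = 78.0,
                          onset: float = 300.0,
                          duration: float = 1800.0,
                          noise_sd: float = 1.5,
                          seed: int | None = None,
                          tau: float = 120.0,
                          dt: float = 1.0,
                          petco2_baseline: float = 40.0,
                          petco2_drop: float = 5.0,
                          hr_baseline: float = 65.0,
                          hr_rise: float = 8.0,
                          noise_smooth_s: float = 5.0) -> PhysioTrace:
    """Simulate SaO2, PetCO2 and heart-rate traces for one subject.

    Parameters
    ----------
    baseline_sao2, plateau_sao2 : %
        Pre-challenge saturation and the hypoxic plateau it approaches.
    onset, duration : s
        Start of hypoxic-air inhalation and total trace length.
    noise_sd : %
        Amplitude of the (smoothed) SaO2 fluctuations.
    tau : s
        Time constant of the exponential approach to the plateau.
    """
    if plateau_sao2 >= baseline_sao2:
        raise ValueError("plateau SaO2 must be below baseline SaO2")
    if duration <= onset:
        raise ValueError("duration must exceed hypoxia onset")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    post = t >= onset
    step = np.where(post, 1.0 - np.exp(-(t - onset) / tau), 0.0)

    def noisy(base: np.ndarray, sd: float) -> np.ndarray:
        if sd == 0.0:
            return base
        raw = rng.normal(0.0, 1.0, t.size)
        sm = gaussian_filter1d(raw, sigma=noise_smooth_s / dt, mode="reflect")
        sm *= sd / max(sm.std(), 1e-12)
        return base + sm

    sao2 = noisy(baseline_sao2 + (plateau_sao2 - baseline_sao2) * step, noise_sd)
    petco2 = noisy(petco2_baseline - petco2_drop * step, noise_sd * 0.4)
    hr = noisy(hr_baseline + hr_rise * step, noise_sd * 1.2)
    return PhysioTrace(time=t, sao2=np.clip(sao2, 50.0, 100.0),
                       petco2=petco2, heart_rate=hr, hypoxia_onset=onset)


def cohort_mean_sao2_trace(records, noise_sd: float = 1.5,
                           seed: int = 0, **kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Average the per-subject SaO2 traces of a cohort at each time point.

    Each subject's trace runs from their measured normoxia SaO2 to their
    measured hypoxia SaO2.  Returns (time, mean trace).
    """
    traces = []
    for i, r in enumerate(records):
        tr = generate_physio_trace(baseline_sao2=r.sao2["normoxia"],
                                   plateau_sao2=r.sao2["hypoxia"],
                                   noise_sd=noise_sd, seed=seed + i, **kwargs)
        traces.append(tr.sao2)
    return tr.time, np.mean(traces, axis=0)
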
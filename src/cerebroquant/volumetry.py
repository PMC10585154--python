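"""Brain volumetry from segmentation label maps.

Volumes are voxel counts times the voxel volume; orientation and
topology are irrelevant.  Labels: 0 background, 1 gray matter, 2 white
matter, 3 CSF.  Total brain volume is GM + WM; intracranial volume is
all nonbackground voxels (ventricular and sulcal CSF are not
distinguished); the brain parenchymal fraction BPF = TBV / ICV is the
atrophy index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LABELS = {"background": 0, "gm": 1, "wm": 2, "csf": 3}


@dataclass
class BrainVolumes:
    gm: float     # ml
    wm: float     # ml
    csf: float    # ml
    tbv: float    # ml
    icv: float    # ml
    bpf: float    # unitless

    def as_dict(self) -> dict:
        return {"gm_ml": self.gm, "wm_ml": self.wm, "csf_ml": self.csf,
                "tbv_ml": self.tbv, "icv_ml": self.icv, "bpf": self.bpf}


def volumes_from_labels(label_map: np.ndarray,
                        voxel_volume: float = 0.70 ** 3) -> BrainVolumes:
    """Compute brain volumes (ml) from a label map.

    Parameters
    ----------
    label_map
        Integer array with values in {0, 1, 2, 3}.
    voxel_volume
        Volume of one voxel in mm^3.
    """
    if voxel_volume <= 0:
        raise ValueError("voxel volume must be positive")
    labels = np.asarray(label_map)
    vals = np.unique(labels)
    if not np.isin(vals, list(LABELS.values())).all():
        bad = vals[~np.isin(vals, list(LABELS.values()))]
        raise ValueError(f"unknown label values: {bad.tolist()}")
    counts = {name: int((labels == v).sum()) for name, v in LABELS.items()}
    nonbg = counts["gm"] + counts["wm"] + counts["csf"]
    if nonbg == 0:
        raise ValueError("label map contains no brain voxels")
    ml = voxel_volume / 1000.0
    gm, wm, csf = counts["gm"] * ml, counts["wm"] * ml, counts["csf"] * ml
    tbv = gm + wm
    icv = nonbg * ml
    return BrainVolumes(gm=gm, wm=wm, csf=csf, tbv=tbv, icv=icv,
                        bpf=tbv / icv)
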
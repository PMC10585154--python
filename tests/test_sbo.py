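"""Susceptibility-based oximetry and Fick CMRO2."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerebroquant.sbo import (
    BloodModel,
    SboAcquisition,
    cmro2_fick,
    hct_from_hgb,
    hgb_gdl_to_mmol_l,
    interecho_phase_difference,
    sbo_phase_offset,
    svo2_from_phase,
)
from cerebroquant.synthetic.phantoms import generate_sbo_phantom
from cerebroquant.utils import wrap_phase

ACQ = SboAcquisition(b0=3.0, te1=8.07, te2=17.77)
BLOOD = BloodModel(hct=0.42)


class TestPhaseDifference:
    def test_identical_evolution_gives_zero(self):
        p1 = np.full((16, 16), 0.3)
        p2 = np.full((16, 16), 1.1)
        sinus = np.zeros((16, 16), bool)
        tissue = np.zeros((16, 16), bool)
        sinus[4:6, 4:6] = True
        tissue[10:12, 10:12] = True
        assert interecho_phase_difference(p1, p2, sinus, tissue) == pytest.approx(0.0)

    def test_phantom_offset_recovered_noise_free(self):
        (p1, p2), sroi, troi, truth = generate_sbo_phantom(0.64, 0.42)
        dphi = interecho_phase_difference(p1, p2, sroi, troi)
        assert dphi == pytest.approx(truth["dphi"], abs=1e-10)

    def test_single_wrap_in_difference_is_undone(self):
        sinus = np.zeros((8, 8), bool)
        tissue = np.zeros((8, 8), bool)
        sinus[1:3, 1:3] = True
        tissue[5:7, 5:7] = True
        p1 = np.zeros((8, 8))
        p2 = np.zeros((8, 8))
        p2[sinus] = wrap_phase(1.33 + 2.0 * np.pi)   # recorded wrapped
        assert interecho_phase_difference(p1, p2, sinus, tissue) == pytest.approx(
            1.33, abs=1e-12)

    def test_empty_and_overlapping_rois_rejected(self):
        p = np.zeros((8, 8))
        full = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="empty"):
            interecho_phase_difference(p, p, np.zeros((8, 8), bool), full)
        with pytest.raises(ValueError, match="disjoint"):
            interecho_phase_difference(p, p, full, full)


class TestSvo2Inversion:
    def test_zero_offset_is_full_saturation(self):
        svo2, clipped = svo2_from_phase(0.0, ACQ, BLOOD)
        assert svo2 == 1.0 and not clipped

    def test_reference_inversion(self):
        svo2, _ = svo2_from_phase(1.33, ACQ, BLOOD)
        assert svo2 == pytest.approx(0.64, abs=0.005)

    @pytest.mark.parametrize("svo2_true", [0.3, 0.5, 0.64, 0.8, 0.95])
    def test_forward_inverse_roundtrip(self, svo2_true):
        dphi = sbo_phase_offset(svo2_true, ACQ, BLOOD)
        svo2, _ = svo2_from_phase(dphi, ACQ, BLOOD)
        assert svo2 == pytest.approx(svo2_true, abs=1e-10)

    def test_monotone_decreasing_in_dphi(self):
        vals = [svo2_from_phase(d, ACQ, BLOOD)[0] for d in (0.2, 0.6, 1.0, 1.4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_offset_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            svo2, clipped = svo2_from_phase(10.0, ACQ, BLOOD)
        assert svo2 == 0.0 and clipped

    def test_magic_angle_and_hct_validation(self):
        with pytest.raises(ValueError, match="magic angle"):
            SboAcquisition(theta_deg=60.0)
        with pytest.raises(ValueError, match="hematocrit"):
            BloodModel(hct=1.2)


class TestHgbConversions:
    def test_hct_from_hgb_reference_values(self):
        assert hct_from_hgb(8.9) == pytest.approx(0.430, abs=5e-4)
        assert hct_from_hgb(8.6) == pytest.approx(0.416, abs=5e-4)

    def test_small_hgb_limit(self):
        assert hct_from_hgb(1e-6) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(ValueError):
            hct_from_hgb(0.0)

    def test_gdl_unit_path_consistent(self):
        """CMRO2 via g/dl input converted to mmol/l agrees within 0.5%."""
        hgb_gdl = 14.34
        hgb_mm = hgb_gdl_to_mmol_l(hgb_gdl)
        a = cmro2_fick(8.9, 42.0, 0.98, 0.646)
        b = cmro2_fick(hgb_mm, 42.0, 0.98, 0.646)
        assert b == pytest.approx(a, rel=0.005)


class TestFick:
    def test_healthy_reference_cmro2(self):
        # group-mean Hgb 8.9 mmol/l, CBF 42.0, saturation difference 0.334
        assert cmro2_fick(8.9, 42.0, 0.98, 0.98 - 0.334) == pytest.approx(
            124.8, abs=0.05)

    def test_albuminuria_reference_cmro2(self):
        assert cmro2_fick(8.6, 39.3, 0.98, 0.98 - 0.348) == pytest.approx(
            117.6, abs=0.05)

    def test_no_extraction_is_zero(self):
        assert cmro2_fick(8.9, 42.0, 0.9, 0.9) == 0.0

    def test_inconsistent_saturations_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            cmro2_fick(8.9, 42.0, 0.6, 0.7)

    @settings(max_examples=40, deadline=None)
    @given(hgb=st.floats(5.0, 12.0), cbf=st.floats(20.0, 70.0),
           diff=st.floats(0.05, 0.5), eps=st.floats(0.01, 0.2))
    def test_strictly_increasing_in_each_argument(self, hgb, cbf, diff, eps):
        base = cmro2_fick(hgb, cbf, 0.98, 0.98 - diff)
        assert cmro2_fick(hgb + eps, cbf, 0.98, 0.98 - diff) > base
        assert cmro2_fick(hgb, cbf + eps, 0.98, 0.98 - diff) > base
        if diff + eps / 4 < 0.97:
            assert cmro2_fick(hgb, cbf, 0.98, 0.98 - diff - eps / 4) > base
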
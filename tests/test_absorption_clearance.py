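"""Closed-form derivations: permeability calibration, absorption, the
well-stirred model, Michaelis-Menten clearance, Qgut availability and the
retrograde inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pbpkddi as p
from pbpkddi.absorption_clearance import (
    derive_absorption,
    fg_qgut,
    mm_clint,
    predict_ka_fa,
    predict_peff,
    retrograde_clint,
    well_stirred_cl,
)
from pbpkddi.vocab import scale_clint


class TestPeff:
    def test_caco2_calibration_reproduces_reported_jejunal_peff(
        self, soticlestat, system
    ):
        peff = predict_peff(
            23.4, soticlestat.absorption.calibrators, system.peff_reference
        )
        assert peff == pytest.approx(3.76, rel=0.02)

    def test_calibrator_papp_maps_to_its_own_reference(self, soticlestat, system):
        peff = predict_peff(
            27.8, soticlestat.absorption.calibrators, system.peff_reference
        )
        assert peff == pytest.approx(system.peff_reference["propranolol"], rel=1e-9)

    def test_monotone_in_papp(self, soticlestat, system):
        grid = np.geomspace(0.1, 100, 40)
        vals = [
            predict_peff(x, soticlestat.absorption.calibrators, system.peff_reference)
            for x in grid
        ]
        assert np.all(np.diff(vals) > 0)

    def test_no_reference_scale_demands_explicit_peff(self):
        with pytest.raises(ValueError, match="peff_man"):
            predict_peff(10.0, [("drugX", 1.0, None)], None)


class TestKaFa:
    def test_reported_peff_gives_near_complete_absorption(self, system):
        ka, fa = predict_ka_fa(3.76, system)
        assert fa >= 0.95
        assert 1.0 < ka < 2.0

    def test_vanishing_permeability_limit(self, system):
        ka, fa = predict_ka_fa(1e-8, system)
        assert ka < 1e-6 and fa < 1e-6

    def test_fa_nondecreasing_in_peff(self, system):
        grid = np.geomspace(1e-3, 10, 50)
        fas = [predict_ka_fa(x, system)[1] for x in grid]
        assert np.all(np.diff(fas) >= 0)

    def test_explicit_file_values_override_prediction(self, soticlestat, system):
        peff, ka, fa = derive_absorption(soticlestat, system)
        assert (ka, fa) == (1.2, 0.98)


class TestWellStirred:
    def test_zero_intrinsic_clearance(self):
        assert well_stirred_cl(0.0, 0.1, 90.0) == 0.0

    def test_flow_limit(self):
        assert well_stirred_cl(1e12, 0.1, 90.0) == pytest.approx(90.0, rel=1e-9)

    def test_restrictive_limit_matches_series_expansion(self):
        # fu*CLu << Q: CL ~= fu*CLu within 1%
        q, fu = 90.0, 0.1
        clu = q / 100 / fu
        assert well_stirred_cl(clu, fu, q) == pytest.approx(fu * clu, rel=0.01)


class TestMMClint:
    @pytest.mark.parametrize(
        "vmax,km,expected",
        [(20.345, 5.0, 4.069), (2.78, 5.0, 0.556), (150.0, 5.0, 30.0)],
    )
    def test_low_concentration_limit_is_vmax_over_km(self, vmax, km, expected):
        assert mm_clint(vmax, km, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_half_saturation(self):
        assert mm_clint(20.345, 5.0, 5.0) == pytest.approx(4.069 / 2)

    def test_decreasing_in_concentration(self):
        cus = np.linspace(0, 50, 20)
        vals = [mm_clint(10, 5, c) for c in cus]
        assert np.all(np.diff(vals) < 0)


class TestFgQgut:
    def test_no_gut_metabolism_gives_full_availability(self):
        assert fg_qgut(2.5, 1.0, 0.0) == 1.0

    def test_symmetry_point(self):
        assert fg_qgut(2.5, 1.0, 2.5) == 0.5

    def test_monotone_decreasing_in_gut_clint(self):
        grid = np.linspace(0, 30, 40)
        vals = [fg_qgut(2.5, 1.0, c) for c in grid]
        assert np.all(np.diff(vals) < 0)


class TestRetrograde:
    def test_reported_per_isoform_intrinsic_clearances(self, soticlestat, system):
        d = retrograde_clint(
            28.7, 0.22, soticlestat.fu_blood, soticlestat.elimination.fm_map,
            system, compound=soticlestat, bp_ratio=soticlestat.bp_ratio,
        )
        assert d.per_enzyme_clu_int["UGT2B4"] == pytest.approx(4.069, rel=0.10)
        assert d.per_enzyme_clu_int["UGT1A9"] == pytest.approx(0.556, rel=0.10)
        assert d.per_enzyme_clu_int["CYP3A4"] == pytest.approx(0.161, rel=0.10)
        assert 0 <= d.fg <= 1 and 0 <= d.fh <= 1
        assert d.cl_hepatic < system.q_hepatic

    def test_single_enzyme_carries_whole_hepatic_pool(self, system, soticlestat):
        d = retrograde_clint(
            10.0, 0.0, 0.1, {"CYP3A4": 1.0}, system,
        )
        total = scale_clint(
            d.per_enzyme_clu_int["CYP3A4"], system.total_pmol("CYP3A4", "liver")
        )
        assert total == pytest.approx(d.clu_int_hepatic, rel=1e-9)

    def test_forward_recomputation_recovers_target_to_1e8(self, system, soticlestat):
        d = retrograde_clint(
            28.7, 0.22, soticlestat.fu_blood, soticlestat.elimination.fm_map,
            system, compound=soticlestat, bp_ratio=soticlestat.bp_ratio,
        )
        fwd = d.cl_hepatic + d.cl_renal_metabolic
        target = (28.7 - 0.22) / soticlestat.bp_ratio
        assert abs(fwd - target) / target < 1e-8

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        clu=st.floats(1.0, 5000.0),
        fu_b=st.floats(0.01, 1.0),
    )
    def test_forward_then_retrograde_round_trip(self, system, clu, fu_b):
        """Invent a hepatic CLu_int, push it through the well-stirred model,
        and check the retrograde inversion recovers it to 1e-8."""
        cl_b = well_stirred_cl(clu, fu_b, system.q_hepatic)
        d = retrograde_clint(cl_b, 0.0, fu_b, {"CYP2D6": 1.0}, system)
        assert d.clu_int_hepatic == pytest.approx(clu, rel=1e-8)

    def test_flow_exceeded_is_an_error(self, system):
        with pytest.raises(ValueError, match="blood flow"):
            retrograde_clint(500.0, 0.0, 0.1, {"CYP3A4": 1.0}, system)

    def test_cl_iv_must_exceed_renal(self, system):
        with pytest.raises(ValueError, match="exceed"):
            retrograde_clint(1.0, 2.0, 0.1, {}, system)


def test_unit_chain_ul_min_pmol_to_l_h():
    """1 uL/min/pmol over a 1e6-pmol pool is 1e6 uL/min = 1 L/min = 60 L/h."""
    assert scale_clint(1.0, 1e6) == pytest.approx(60.0, rel=1e-12)
    # the major-isoform hepatic chain (per-pmol value x abundance x MPPGL x
    # liver weight) lands in the range the well-stirred inversion demands
    assert 500 < scale_clint(4.069, 36.2 * 40 * 1650) < 700
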
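"""Drug forcing: pharmacokinetics, Hill inhibition, redox cycling, iron."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitotoxsim import (DoseSchedule, DoxEffects, ETCInhibitionParams,
                        IronModel, PKParams, PathwaySwitches,
                        RedoxCyclingParams, compose_effects, dox_concentration,
                        etc_activity_scale, iron_level, mg_per_kg_to_um,
                        redox_cycling_source)

PK = PKParams()
ETC = ETCInhibitionParams()
RC = RedoxCyclingParams()
IRON = IronModel()


class TestPharmacokinetics:
    def test_zero_before_first_event(self):
        sched = DoseSchedule(((10.0, 30.0),))
        assert dox_concentration(5.0, sched, PK) == 0.0

    def test_peak_normalization_hits_nominal_dose(self):
        """At the analytic peak time of the two-exponential curve the
        concentration equals the nominal dose."""
        sched = DoseSchedule(((0.0, 30.0),))
        t_max = math.log(PK.ka / PK.ke) / (PK.ka - PK.ke)
        c_peak = dox_concentration(t_max, sched, PK)
        assert c_peak == pytest.approx(30.0, rel=1e-12)
        # dense numeric check that this is the maximum
        ts = np.linspace(1e-4, 72.0, 20000)
        cs = [dox_concentration(t, sched, PK) for t in ts]
        assert max(cs) <= c_peak * (1 + 1e-6)

    def test_elimination_half_time_governs_decay(self):
        """One elimination half-time past the peak the concentration has
        halved (absorption long over)."""
        sched = DoseSchedule(((0.0, 30.0),))
        t_max = PK.t_peak
        ratio = dox_concentration(t_max + 24.0, sched, PK) \
            / dox_concentration(t_max, sched, PK)
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_superposition_is_additive(self):
        one = DoseSchedule(((0.0, 30.0),))
        two = DoseSchedule(((48.0, 10.0),))
        both = DoseSchedule(((0.0, 30.0), (48.0, 10.0)))
        for t in (1.0, 47.9, 50.0, 120.0):
            assert dox_concentration(t, both, PK) == pytest.approx(
                dox_concentration(t, one, PK) + dox_concentration(t, two, PK))

    @given(st.floats(0.0, 400.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_curve_nonnegative(self, t):
        sched = DoseSchedule(((0.0, 30.0), (168.0, 30.0)))
        assert dox_concentration(t, sched, PK) >= 0.0

    def test_single_peak_per_dose(self):
        sched = DoseSchedule(((0.0, 30.0),))
        ts = np.linspace(1e-3, 168.0, 5000)
        cs = np.array([dox_concentration(t, sched, PK) for t in ts])
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(cs)))) > 0)
        assert sign_changes == 1

    def test_constant_mode_overrides_pk(self):
        sched = DoseSchedule(constant_um=42.0)
        assert dox_concentration(0.0, sched, PK) == 42.0
        assert dox_concentration(1e4, sched, PK) == 42.0

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            DoseSchedule(((10.0, 30.0), (5.0, 30.0)))
        with pytest.raises(ValueError):
            DoseSchedule(((0.0, -1.0),))
        with pytest.raises(ValueError):
            PKParams(t_half_abs_min=0.0)


class TestETCInhibition:
    def test_zero_dose_full_activity(self):
        assert etc_activity_scale("I", 0.0, ETC) == 1.0

    def test_hill_midpoint(self):
        for c in ("I", "II", "III", "IV"):
            assert etc_activity_scale(c, ETC.ic50(c), ETC) == pytest.approx(0.5)

    def test_midpoint_independent_of_hill_and_one_third_at_double(self):
        p2 = ETCInhibitionParams(ic50_I=100.0, hill_I=4.5)
        assert etc_activity_scale("I", 100.0, p2) == pytest.approx(0.5)
        p1 = ETCInhibitionParams(ic50_I=100.0, hill_I=1.0)
        assert etc_activity_scale("I", 200.0, p1) == pytest.approx(1.0 / 3.0)

    def test_unknown_complex_rejected(self):
        with pytest.raises(ValueError):
            etc_activity_scale("V", 10.0, ETC)

    @given(st.floats(0.01, 2000.0), st.floats(0.01, 2000.0))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_strictly_monotone_in_dose(self, d1, d2):
        s1 = etc_activity_scale("III", d1, ETC)
        s2 = etc_activity_scale("III", d2, ETC)
        if d1 < d2:
            assert s1 > s2
        elif d1 > d2:
            assert s1 < s2
        else:
            assert s1 == s2


class TestRedoxCycling:
    def test_zero_dose_zero_source(self):
        assert redox_cycling_source(0.0, 0.4, 0.4, RC) == 0.0

    def test_source_proportional_to_dose(self):
        s1 = redox_cycling_source(10.0, 0.4, 0.4, RC)
        s2 = redox_cycling_source(20.0, 0.4, 0.4, RC)
        assert s2 == pytest.approx(2.0 * s1)

    def test_source_gated_by_nadh(self):
        assert redox_cycling_source(10.0, 0.0, 0.4, RC) == 0.0


class TestDoseConversion:
    @pytest.mark.parametrize("mg_kg,um", [(1.0, 30.0), (0.8, 24.0), (15.0, 450.0)])
    def test_body_dose_to_mitochondrial_concentration(self, mg_kg, um):
        assert mg_per_kg_to_um(mg_kg) == pytest.approx(um)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            mg_per_kg_to_um(-1.0)


class TestIron:
    def test_no_drug_baseline_iron(self):
        assert iron_level(0.0, 0.0, IRON) == IRON.fe0

    def test_clamped_inside_chelation_window(self):
        m = IronModel(k_fe=0.01, chelation_windows=((0.0, 100.0),))
        assert iron_level(50.0, 500.0, m) == m.fe0

    def test_linear_rise_outside_window(self):
        m = IronModel(k_fe=0.01)
        assert iron_level(0.0, 1.0 / m.k_fe, m) == pytest.approx(2.0 * m.fe0)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            IronModel(chelation_windows=((0.0, 10.0), (5.0, 20.0)))


class TestComposeEffects:
    def test_all_pathways_off_is_identity_at_any_dose(self):
        sched = DoseSchedule(constant_um=300.0)
        eff = compose_effects(0.0, sched, PK, ETC, RC, IRON,
                              PathwaySwitches.none())
        assert eff.scale_c1 == eff.scale_c3 == eff.scale_c4 == 1.0
        assert eff.v_rc == 0.0

    def test_rc_only_leaves_activity_untouched(self):
        sched = DoseSchedule(constant_um=10.0)
        eff = compose_effects(0.0, sched, PK, ETC, RC, IRON,
                              PathwaySwitches.only("redox_cycling"))
        assert eff.scale_c1 == 1.0 and eff.scale_c4 == 1.0
        assert eff.v_rc > 0.0

    def test_zero_dose_is_identity_with_everything_on(self):
        sched = DoseSchedule(((10.0, 30.0),))
        eff = compose_effects(1.0, sched, PK, ETC, RC, IRON, PathwaySwitches())
        assert eff == DoxEffects.identity()

    def test_disabling_pathways_reproduces_baseline_trajectory(self, core):
        """With every pathway disabled a dosed run equals the no-dose run
        bit for bit (same solver settings)."""
        from mitotoxsim.simulate import DoxToxicityModel, simulate_protocol

        m = DoxToxicityModel(core=core, switches=PathwaySwitches.none())
        m.qss_map()
        dosed = simulate_protocol(m, DoseSchedule(((0.0, 100.0),)), 24.0,
                                  mode="full")
        blank = simulate_protocol(m, DoseSchedule(((0.0, 0.0),)), 24.0,
                                  mode="full")
        for k in ("dpsi", "nadh", "atp", "superoxide", "m"):
            assert np.array_equal(dosed.raw[k], blank.raw[k]), k
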
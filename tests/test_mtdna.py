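"""mtDNA damage/repair balance, phase plane, bifurcation, attribution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitotoxsim import (AttributionResult, MtDNAParams, NoBifurcationError,
                        attribute_damage, derive_beta, dmtdna_dt,
                        find_bifurcation, phase_curve)

P = MtDNAParams()


class TestBalanceEquation:
    def test_baseline_balance_is_exact(self):
        """Repair equals damage at baseline content with normalized ROS."""
        assert dmtdna_dt(P.m0, 1.0, 0.0, P) == pytest.approx(0.0, abs=1e-15)

    def test_beta_from_balance(self):
        assert P.beta == pytest.approx(
            P.alpha * (1 - P.m0) / (((1 - P.m0) + P.kappa) * P.m0))

    def test_full_content_leaves_only_damage(self):
        """At m = 1 the repair term vanishes: dm/dt = -beta*oh_n."""
        oh = 1.7
        assert dmtdna_dt(1.0, oh, 0.0, P) == pytest.approx(-P.beta * oh)

    def test_hand_substitution(self):
        """Direct arithmetic on the three-term balance."""
        m, oh, dox = 0.5, 2.0, 10.0
        expected = (P.alpha * 0.5 / (0.5 + P.kappa)
                    - P.beta * 2.0 * 0.5
                    - P.gamma * 10.0 * 0.5)
        assert dmtdna_dt(m, oh, dox, P) == pytest.approx(expected, rel=1e-12)

    def test_repair_saturates_below_alpha(self):
        """Repair term monotone decreasing in m; its m->0 limit is
        alpha/(1+kappa) < alpha."""
        repair = lambda m: dmtdna_dt(m, 0.0, 0.0,
                                     MtDNAParams(alpha=P.alpha, kappa=P.kappa,
                                                 gamma=0.0))
        # with oh_n = 0 and gamma = 0 only the repair term remains
        ms = np.linspace(0.0, 0.99, 25)
        vals = [repair(m) for m in ms]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(P.alpha / (1 + P.kappa))
        assert vals[0] < P.alpha

    @given(st.floats(0.1, 1.0), st.floats(0.0, 5.0), st.floats(0.0, 5.0),
           st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_damage_terms_superpose_linearly(self, m, oh1, oh2, d1, d2):
        """dm/dt is linear in the hydroxyl level and in the drug
        concentration at fixed content."""
        base = dmtdna_dt(m, 0.0, 0.0, P)
        f = lambda oh, d: dmtdna_dt(m, oh, d, P) - base
        assert f(oh1 + oh2, 0.0) == pytest.approx(f(oh1, 0) + f(oh2, 0),
                                                  rel=1e-9, abs=1e-15)
        assert f(0.0, d1 + d2) == pytest.approx(f(0, d1) + f(0, d2),
                                                rel=1e-9, abs=1e-15)

    def test_validation(self):
        with pytest.raises(ValueError):
            dmtdna_dt(1.2, 1.0, 0.0, P)
        with pytest.raises(ValueError):
            dmtdna_dt(0.5, -1.0, 0.0, P)
        with pytest.raises(ValueError):
            MtDNAParams(m0=1.5)
        with pytest.raises(ValueError):
            derive_beta(0.01, 0.1, 0.0)


class TestPhasePlane:
    def test_signs_around_baseline(self, model):
        pts = {p.m: p for p in phase_curve([0.70, 0.74, 0.75, 0.76],
                                           model.core, model.mtdna)}
        assert pts[0.75].dmdt_per_week == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(1.0, abs=1e-6)
                   for v in pts[0.75].indices.values())
        assert pts[0.74].dmdt_per_week > 0.0   # stable recovery band
        assert pts[0.76].dmdt_per_week < 0.0   # repair attenuated above baseline
        assert pts[0.70].dmdt_per_week < 0.0   # vicious cycle below the root

    def test_grid_validation(self, model):
        with pytest.raises(ValueError):
            phase_curve([1.2], model.core, model.mtdna)

    def test_bifurcation_invariant_to_gamma(self, model):
        """The drug term is absent from the drug-free phase analysis."""
        m1 = find_bifurcation(model.core, model.mtdna)
        p2 = MtDNAParams(alpha=P.alpha, kappa=P.kappa, gamma=10 * P.gamma)
        m2 = find_bifurcation(model.core, p2)
        assert m1 == pytest.approx(m2, abs=2e-4)

    def test_no_unstable_root_when_excess_ros_damage_removed(self, model):
        """With the hydroxyl level entering the damage term capped at its
        baseline, oxidative damage never exceeds what repair balances:
        repair wins at every content and the bisection reports failure."""
        weak = MtDNAParams(alpha=P.alpha, kappa=P.kappa, gamma=P.gamma,
                           oh_ceiling=1.0)
        with pytest.raises(NoBifurcationError):
            find_bifurcation(model.core, weak, m_min=0.62)

    def test_bistability_by_long_integration(self, model):
        """Contents inside (m*, m0] relax to baseline; below m* the decline
        is monotone (self-sustaining vicious cycle)."""
        from scipy.integrate import solve_ivp
        from mitotoxsim.pathways import DoseSchedule

        m_star = model.bifurcation_content
        schedule = DoseSchedule()

        def rhs(t, y):
            return model._slow_rhs(t, y, schedule)

        # start inside the recovery band
        sol_up = solve_ivp(rhs, (0.0, 600 * 168.0), [m_star + 0.008, 1.0],
                           method="LSODA", rtol=1e-9, atol=1e-12)
        m_up = sol_up.y[0]
        assert m_up[-1] > m_star + 0.012           # moved toward baseline
        assert np.all(np.diff(m_up) > -1e-9)       # monotone recovery
        # start just below the unstable root
        sol_dn = solve_ivp(rhs, (0.0, 600 * 168.0), [m_star - 0.008, 1.0],
                           method="LSODA", rtol=1e-9, atol=1e-12)
        m_dn = sol_dn.y[0]
        assert np.all(np.diff(m_dn) < 1e-9)        # monotone decline
        assert m_dn[-1] < 0.5


class TestAttribution:
    def _traj(self, oh, dox, n=400, t_end=160.0):
        t = np.linspace(0.0, t_end, n)
        m = np.full(n, 0.74)
        return t, m, np.full(n, oh), np.full(n, dox)

    def test_baseline_ros_gives_pure_direct_attribution(self):
        t, m, oh, dox = self._traj(oh=1.0, dox=5.0)
        att = attribute_damage(t, m, oh, dox, P, (0.0, 160.0))
        assert att.fraction_direct == 1.0
        assert att.oxidative_excess_integral == 0.0

    def test_no_drug_gives_zero_direct_fraction(self):
        t, m, oh, dox = self._traj(oh=1.5, dox=0.0)
        att = attribute_damage(t, m, oh, dox, P, (0.0, 160.0))
        assert att.fraction_direct == 0.0
        assert att.oxidative_excess_integral > 0.0

    def test_empty_window_rejected(self):
        t, m, oh, dox = self._traj(oh=1.0, dox=1.0)
        with pytest.raises(ValueError):
            attribute_damage(t, m, oh, dox, P, (500.0, 600.0))

    def test_trapezoid_matches_fine_riemann_sum(self, model):
        """Attribution integrals on a simulated single-dose trajectory agree
        with a fine-grid left Riemann sum within 1%."""
        from mitotoxsim.experiments import dynamic_run
        from mitotoxsim.pathways import DoseSchedule

        res = dynamic_run(model, DoseSchedule(((0.0, 30.0),)),
                          horizon_h=200.0)
        oh_n = res.raw["hydroxyl"] / model.core.baseline.hydroxyl
        window = (0.0, model.acute_window_h)
        att = attribute_damage(res.time_h, res.raw["m"], oh_n, res.raw["dox"],
                               model.mtdna, window)
        # Riemann oracle on a 20x refined grid (linear interpolation)
        tf = np.linspace(window[0], window[1], 20 * res.time_h.size)
        mf = np.interp(tf, res.time_h, res.raw["m"])
        ohf = np.interp(tf, res.time_h, oh_n)
        doxf = np.interp(tf, res.time_h, res.raw["dox"])
        dt = (tf[1] - tf[0]) / 168.0
        direct = np.sum(model.mtdna.gamma * doxf[:-1] * mf[:-1]) * dt
        oxid = np.sum(model.mtdna.beta
                      * np.maximum(ohf[:-1] - 1.0, 0.0) * mf[:-1]) * dt
        assert att.direct_integral == pytest.approx(direct, rel=0.01)
        assert att.oxidative_excess_integral == pytest.approx(oxid, rel=0.01)
        frac_oracle = direct / (direct + oxid)
        assert att.fraction_direct == pytest.approx(frac_oracle, abs=0.01)
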
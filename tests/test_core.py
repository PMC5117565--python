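"""Bioenergetic core: baseline fixed point, flux balances, collapse."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mitotoxsim import (BioenergeticCore, DoxEffects, MitoState,
                        default_core_params, scale_densities)


def uniform_inhibition(u: float) -> DoxEffects:
    return DoxEffects(scale_c1=u, scale_c2=u, scale_c3=u, scale_c4=u)


class TestBaseline:
    def test_baseline_is_fixed_point(self, core, baseline):
        d = core.derivatives(baseline, DoxEffects.identity())
        assert np.max(np.abs(d)) < 1e-9

    def test_baseline_ros_normalized_to_one(self, baseline):
        assert baseline.superoxide == pytest.approx(1.0)
        assert baseline.h2o2 == pytest.approx(1.0)
        assert baseline.hydroxyl == pytest.approx(1.0)

    def test_steady_state_identity_effects_normalizes_to_one(self, core):
        ss = core.solve_steady_state(DoxEffects.identity())
        assert ss.converged and not ss.collapsed
        for name, val in ss.normalized.items():
            assert val == pytest.approx(1.0, abs=1e-6), name

    def test_return_from_ten_percent_perturbation(self, core, baseline):
        """The drug-free baseline is a stable node."""
        y0 = baseline.as_array() * 1.10
        y0[1] = min(y0[1], 1.0)
        sol = solve_ivp(lambda t, y: core._rhs(y, core.params, DoxEffects.identity()),
                        (0.0, 30.0), y0, method="BDF", rtol=1e-10, atol=1e-12)
        assert sol.success
        assert np.allclose(sol.y[:, -1], baseline.as_array(), rtol=1e-6)


class TestDerivatives:
    def test_doubled_superoxide_drives_peroxide_production(self, core, baseline):
        """Hand-evaluated ROS chain balance at a displaced point."""
        p = core.params
        state = dataclasses.replace(baseline, superoxide=2.0)
        d = core.derivatives(state, DoxEffects.identity())
        # superoxide: production still 1 (bioenergetics at baseline), so
        # d[SO] = sod_rate*(1 - 2); peroxide: d[H2O2] = clear*(2 - 1)
        assert d[3] == pytest.approx(-p.sod_rate, rel=1e-9)
        assert d[4] == pytest.approx(p.h2o2_clear_rate * (2.0 - 1.0), rel=1e-9)
        assert d[4] > 0

    def test_zero_densities_kill_flux_and_potential(self, core, baseline):
        from mitotoxsim.simulate import _ScaledView

        p = scale_densities(core.params, 0.0)
        fl = _ScaledView(core, p).fluxes(baseline, DoxEffects.identity())
        assert fl.v_etc == 0.0
        assert fl.v_syn == 0.0
        d = core._rhs(baseline.as_array(), p, DoxEffects.identity())
        assert d[0] < 0.0  # potential decays without pumping

    def test_negative_activity_scale_rejected(self, core, baseline):
        with pytest.raises(ValueError):
            core.derivatives(baseline, DoxEffects(scale_c1=-0.1))

    def test_nonfinite_state_raises(self, core, baseline):
        y = baseline.as_array()
        y[0] = np.nan
        from mitotoxsim.core import SolverBlowupError
        with pytest.raises(SolverBlowupError):
            core._rhs(y, core.params, DoxEffects.identity())


class TestScaleDensities:
    @pytest.mark.parametrize("mtdna,scale", [(0.75, 1.0), (0.0, 0.0), (0.375, 0.5)])
    def test_linear_scaling(self, core, mtdna, scale):
        p = scale_densities(core.params, mtdna)
        for f in ("rho_c1", "rho_c3", "rho_c4", "rho_syn"):
            assert getattr(p, f) == pytest.approx(getattr(core.params, f) * scale)

    def test_other_fields_unchanged(self, core):
        p = scale_densities(core.params, 0.6)
        assert p.k_etc == core.params.k_etc
        assert p.sod_rate == core.params.sod_rate

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_out_of_range_content_rejected(self, core, bad):
        with pytest.raises(ValueError):
            scale_densities(core.params, bad)


class TestSteadyState:
    def test_full_etc_block_collapses(self, core):
        ss = core.solve_steady_state(uniform_inhibition(0.0))
        assert ss.collapsed
        assert ss.normalized["dpsi"] < 0.05
        assert ss.normalized["atp"] < 0.05
        assert ss.normalized["v_o2"] < 0.05  # residual oxygen consumption

    def test_reduced_mtdna_raises_superoxide(self, core):
        """Density loss shifts superoxide production to Complex III: the
        combined production rises monotonically as content falls (checked
        across the functioning range, above the collapse content)."""
        vals = [core.solve_steady_state(DoxEffects.identity(), mtdna=m)
                .normalized["superoxide"] for m in (0.75, 0.71, 0.68, 0.65)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 1.0

    def test_monotone_degradation_under_uniform_inhibition(self, core):
        """Up to the collapse point: potential and ATP fall, peroxide rises."""
        us = [1.0, 0.95, 0.9, 0.85, 0.8]
        rows = [core.solve_steady_state(uniform_inhibition(u)) for u in us]
        assert not any(r.collapsed for r in rows)
        dpsi = [r.normalized["dpsi"] for r in rows]
        atp = [r.normalized["atp"] for r in rows]
        h2o2 = [r.normalized["h2o2"] for r in rows]
        assert all(a >= b - 1e-9 for a, b in zip(dpsi, dpsi[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(atp, atp[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(h2o2, h2o2[1:]))

    def test_inhibition_collapse_is_discontinuous(self, core):
        """A fold: past a critical uniform inhibition no high-potential
        steady state exists, and the branch jump is large."""
        lo, hi = 0.2, 0.8  # collapsed at 0.2, functioning at 0.8
        assert core.solve_steady_state(uniform_inhibition(lo)).collapsed
        assert not core.solve_steady_state(uniform_inhibition(hi)).collapsed
        while hi - lo > 1e-3:
            mid = 0.5 * (lo + hi)
            if core.solve_steady_state(uniform_inhibition(mid)).collapsed:
                lo = mid
            else:
                hi = mid
        above = core.solve_steady_state(uniform_inhibition(hi + 2e-3))
        below = core.solve_steady_state(uniform_inhibition(lo - 2e-3))
        assert above.normalized["dpsi"] - below.normalized["dpsi"] > 0.3

    def test_adaptive_solver_matches_fixed_step_rk4(self, core, baseline):
        """Stiff trajectory agrees with explicit RK4 at small step."""
        y0 = baseline.as_array() * np.array([0.95, 1.05, 0.95, 1.1, 1.0, 1.0])
        eff = DoxEffects.identity()
        t_end = 1.0 / 60.0  # one minute
        sol = solve_ivp(lambda t, y: core._rhs(y, core.params, eff),
                        (0.0, t_end), y0, method="BDF",
                        rtol=1e-10, atol=1e-12)
        y = y0.copy()
        dt = 1e-5
        n = int(round(t_end / dt))
        for _ in range(n):
            k1 = core._rhs(y, core.params, eff)
            k2 = core._rhs(y + 0.5 * dt * k1, core.params, eff)
            k3 = core._rhs(y + 0.5 * dt * k2, core.params, eff)
            k4 = core._rhs(y + dt * k3, core.params, eff)
            y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert np.max(np.abs(y - sol.y[:, -1]) / np.abs(sol.y[:, -1])) < 1e-3

    def test_adenine_pool_bounded_along_trajectory(self, core, baseline):
        """ATP never exceeds the conserved adenine pool (ADP = A_tot - ATP)."""
        eff = uniform_inhibition(0.5)
        sol = solve_ivp(lambda t, y: core._rhs(y, core.params, eff),
                        (0.0, 5.0), baseline.as_array(), method="BDF",
                        rtol=1e-8, atol=1e-10, dense_output=True)
        atp = sol.sol(np.linspace(0, 5.0, 200))[2]
        assert np.all(atp >= -1e-9)
        assert np.all(atp <= core.params.a_tot + 1e-9)


class TestParams:
    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            BioenergeticCore(default_core_params(sod_rate=-1.0))

    def test_inverse_design_hits_requested_baseline(self):
        p = default_core_params(dpsi_base=140.0, nadh_base=0.5, atp_base=6.0)
        c = BioenergeticCore(p)
        assert c.baseline.dpsi == pytest.approx(140.0, rel=1e-6)
        assert c.baseline.nadh == pytest.approx(0.5, rel=1e-6)
        assert c.baseline.atp == pytest.approx(6.0, rel=1e-6)
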
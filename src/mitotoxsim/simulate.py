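"""Coupled drug/bioenergetics/mtDNA simulation engine.

Two integration strategies are provided for dosing protocols:

* **brute force** — the full nine-quantity system (six core states, mtDNA
  content, free iron, with the drug concentration an analytic forcing) is
  integrated with a stiff solver over the whole horizon; exact but slow for
  multi-month protocols.
* **hybrid multiscale** (default for chronic runs) — bioenergetics
  equilibrate within minutes while mtDNA content moves over weeks, so the
  full system is integrated only inside acute windows (each dose until the
  drug falls below 1% of its peak) and, between windows, content and iron
  are advanced on the slow clock with the core held at its quasi-steady
  state (interpolated from a cached content -> steady-state map).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .core import (BioenergeticCore, CoreParams, MTDNA_REF, default_core_params,
                   scale_densities)
from .mtdna import HOURS_PER_WEEK, MtDNAParams, dmtdna_dt, find_bifurcation
from .pathways import (DoseSchedule, DoxEffects, ETCInhibitionParams, IronModel,
                       PKParams, PathwaySwitches, RedoxCyclingParams,
                       compose_effects, dox_concentration)

__all__ = ["DoxToxicityModel", "SimulationResult", "simulate_protocol"]

STATE_NAMES = ("dpsi", "nadh", "atp", "superoxide", "h2o2", "hydroxyl")
INDEX_NAMES = STATE_NAMES + ("v_o2",)


@dataclass
class SimulationResult:
    """Time-indexed trajectories of a dosing protocol.

    ``raw`` holds the state variables in model units plus content ``m``,
    drug ``dox`` (uM) and iron ``fe``; ``normalized`` holds the function
    indices relative to the drug-free baseline.  ``outcome`` is one of
    ``recovered`` / ``progressing`` / ``collapsed``.
    """

    time_h: np.ndarray
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    outcome: str
    collapse_time_h: float | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        cols = {"time_h": self.time_h}
        for k in sorted(self.raw):
            cols[k] = self.raw[k]
        for k in sorted(self.normalized):
            cols[f"norm_{k}"] = self.normalized[k]
        return pd.DataFrame(cols)


@dataclass
class DoxToxicityModel:
    """Bundle of the bioenergetic core, acute pathways and mtDNA dynamics."""

    core: BioenergeticCore = field(default_factory=BioenergeticCore)
    pk: PKParams = field(default_factory=PKParams)
    etc: ETCInhibitionParams = field(default_factory=ETCInhibitionParams)
    rc: RedoxCyclingParams = field(default_factory=RedoxCyclingParams)
    iron: IronModel = field(default_factory=IronModel)
    mtdna: MtDNAParams = field(default_factory=MtDNAParams)
    switches: PathwaySwitches = field(default_factory=PathwaySwitches)

    def __post_init__(self):
        self._qss = None
        self._m_star = None

    # -- convenience -------------------------------------------------------

    def with_switches(self, switches: PathwaySwitches) -> "DoxToxicityModel":
        m = DoxToxicityModel(core=self.core, pk=self.pk, etc=self.etc,
                             rc=self.rc, iron=self.iron, mtdna=self.mtdna,
                             switches=switches)
        m._qss = self._qss          # caches are switch-independent (no drug)
        m._m_star = self._m_star
        return m

    def with_iron(self, iron: IronModel) -> "DoxToxicityModel":
        m = DoxToxicityModel(core=self.core, pk=self.pk, etc=self.etc,
                             rc=self.rc, iron=iron, mtdna=self.mtdna,
                             switches=self.switches)
        m._qss = self._qss
        m._m_star = self._m_star
        return m

    def effects_at(self, t: float, schedule: DoseSchedule,
                   fe: float | None = None) -> DoxEffects:
        return compose_effects(t, schedule, self.pk, self.etc, self.rc,
                               self.iron, self.switches, fe=fe)

    @property
    def acute_window_h(self) -> float:
        """Length of a dose's acute window: until [DOX] < 1% of its peak."""
        return math.log(100.0) / self.pk.ke + self.pk.t_peak

    @property
    def bifurcation_content(self) -> float:
        if self._m_star is None:
            self._m_star = find_bifurcation(self.core, self.mtdna)
        return self._m_star

    # -- quasi-steady-state cache -------------------------------------------

    def qss_map(self):
        """Content -> drug-free steady-state indices, and the collapse content.

        Returns ``(interpolators, m_collapse)`` where ``interpolators`` maps
        each normalized index name to a monotone cubic interpolant over the
        functioning range (contents above the collapse content).
        """
        if self._qss is not None:
            return self._qss
        grid = np.unique(np.round(np.concatenate([
            np.arange(0.30, 0.60, 0.02),
            np.arange(0.60, 0.70, 0.01),
            np.arange(0.70, 0.78, 0.0025),
            np.arange(0.78, 1.0001, 0.02),
        ]), 6))
        identity = DoxEffects.identity()
        rows, collapsed_mask = [], []
        for m in grid:
            ss = self.core.solve_steady_state(identity, mtdna=m)
            rows.append([ss.normalized[k] for k in INDEX_NAMES])
            collapsed_mask.append(ss.collapsed)
        collapsed_mask = np.array(collapsed_mask)
        # collapse content: refine the boundary between the highest collapsed
        # grid point and the lowest functioning one
        if collapsed_mask.any():
            i_hi = int(np.max(np.nonzero(collapsed_mask)))
            lo, hi = grid[i_hi], grid[min(i_hi + 1, len(grid) - 1)]
            while hi - lo > 1e-3:
                mid = 0.5 * (lo + hi)
                if self.core.solve_steady_state(identity, mtdna=mid).collapsed:
                    lo = mid
                else:
                    hi = mid
            m_collapse = hi
        else:
            m_collapse = 0.0
        ok = ~collapsed_mask
        data = np.array(rows)
        interp = {name: PchipInterpolator(grid[ok], data[ok, i],
                                          extrapolate=True)
                  for i, name in enumerate(INDEX_NAMES)}
        self._qss = (interp, float(m_collapse))
        return self._qss

    # -- full (brute-force) right-hand side ---------------------------------

    def _full_rhs(self, t: float, y: np.ndarray,
                  schedule: DoseSchedule) -> np.ndarray:
        m = min(max(y[6], 0.0), 1.0)
        fe = max(y[7], 1e-9)
        eff = self.effects_at(t, schedule, fe=fe)
        p_scaled = scale_densities(self.core.params, m)
        dy6 = self.core._rhs(y[:6], p_scaled, eff)
        oh_n = y[5] / self.core.baseline.hydroxyl
        dm = dmtdna_dt(m, max(oh_n, 0.0), eff.dox, self.mtdna,
                       ros_damage=self.switches.ros_mtdna_damage,
                       direct_damage=self.switches.direct_mtdna_damage)
        dm /= HOURS_PER_WEEK
        if (m <= 0.0 and dm < 0.0) or (m >= 1.0 and dm > 0.0):
            dm = 0.0
        fe_target = self.iron.fe0 if self.iron.in_window(t) \
            else self.iron.fe0 * (1.0 + self.iron.k_fe * eff.dox)
        dfe = self.iron.k_clear * (fe_target - fe)
        return np.concatenate([dy6, [dm, dfe]])

    def _full_y0(self, m: float, fe: float) -> np.ndarray:
        interp, m_c = self.qss_map()
        b = self.core.baseline
        scales = np.array([b.dpsi, b.nadh, b.atp, 1.0, 1.0, b.hydroxyl])
        if abs(m - MTDNA_REF) < 1e-9:
            y6 = b.as_array()
        else:
            y6 = np.array([float(interp[k](m)) for k in STATE_NAMES]) * scales
        y6[5] *= fe / self.iron.fe0   # hydroxyl tracks iron linearly
        return np.concatenate([y6, [m, fe]])

    # -- slow (quasi-steady) right-hand side --------------------------------

    def _slow_rhs(self, t: float, y: np.ndarray,
                  schedule: DoseSchedule) -> np.ndarray:
        interp, m_c = self._qss
        m = min(max(y[0], 0.0), 1.0)
        fe = max(y[1], 1e-9)
        dox = dox_concentration(t, schedule, self.pk) \
            if self.switches.any_active else 0.0
        fe_used = self.iron.fe0 if self.iron.in_window(t) else fe
        if m <= m_c:
            oh_n = self.mtdna.oh_ceiling
        else:
            h_n = float(interp["h2o2"](m))
            rc_term = self.rc.eta * dox if self.switches.redox_cycling else 0.0
            oh_n = (fe_used / self.iron.fe0) * (h_n + rc_term)
        dm = dmtdna_dt(m, oh_n, dox, self.mtdna,
                       ros_damage=self.switches.ros_mtdna_damage,
                       direct_damage=self.switches.direct_mtdna_damage)
        dm /= HOURS_PER_WEEK
        if (m <= 0.0 and dm < 0.0) or (m >= 1.0 and dm > 0.0):
            dm = 0.0
        fe_target = self.iron.fe0 if self.iron.in_window(t) \
            else self.iron.fe0 * (1.0 + self.iron.k_fe * dox)
        dfe = self.iron.k_clear * (fe_target - fe)
        return np.array([dm, dfe])


# ---------------------------------------------------------------------------
# protocol integration


def _acute_windows(schedule: DoseSchedule, window_h: float,
                   horizon_h: float) -> list[tuple[float, float]]:
    """Merged [start, end] acute windows of all dose events."""
    spans = [(t0, min(t0 + window_h, horizon_h))
             for t0, d in schedule.events if d > 0 and t0 < horizon_h]
    spans.sort()
    merged: list[list[float]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _collapse_event(model: DoxToxicityModel):
    thresh = 0.2 * model.core.baseline.dpsi

    def ev(t, y, *args):
        return y[0] - thresh

    ev.terminal = True
    ev.direction = -1
    return ev


def _full_segment(model: DoxToxicityModel, schedule: DoseSchedule,
                  t0: float, t1: float, y0: np.ndarray, n_out: int = 240):
    t_eval = np.linspace(t0, t1, n_out)
    sol = solve_ivp(model._full_rhs, (t0, t1), y0, method="BDF",
                    args=(schedule,), t_eval=t_eval,
                    events=_collapse_event(model), rtol=1e-7,
                    atol=[1e-7, 1e-9, 1e-8, 1e-9, 1e-9, 1e-9, 1e-10, 1e-10],
                    max_step=(t1 - t0))
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"stiff integration failed on [{t0}, {t1}] h: "
                           f"{sol.message}; last state {sol.y[:, -1] if sol.y.size else y0}")
    collapsed_at = float(sol.t_events[0][0]) if sol.t_events[0].size else None
    return sol.t, sol.y, collapsed_at


def _slow_segment(model: DoxToxicityModel, schedule: DoseSchedule,
                  t0: float, t1: float, m0: float, fe0: float,
                  n_out: int = 120):
    interp, m_c = model.qss_map()

    def hit_collapse(t, y, *args):
        return y[0] - m_c
    hit_collapse.terminal = True
    hit_collapse.direction = -1

    t_eval = np.linspace(t0, t1, max(int(n_out * (t1 - t0) / HOURS_PER_WEEK), 8))
    sol = solve_ivp(model._slow_rhs, (t0, t1), np.array([m0, fe0]),
                    method="LSODA", args=(schedule,), t_eval=t_eval,
                    events=hit_collapse, rtol=1e-8, atol=1e-10)
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"slow integration failed on [{t0}, {t1}] h: {sol.message}")
    collapsed_at = float(sol.t_events[0][0]) if sol.t_events[0].size else None
    return sol.t, sol.y, collapsed_at


def _assemble(model: DoxToxicityModel, schedule: DoseSchedule,
              parts: list[tuple[np.ndarray, dict[str, np.ndarray]]],
              outcome: str, collapse_time: float | None,
              meta: dict) -> SimulationResult:
    t = np.concatenate([p[0] for p in parts])
    raw = {k: np.concatenate([p[1][k] for p in parts])
           for k in parts[0][1]}
    keep = np.concatenate([[True], np.diff(t) > 0])
    t = t[keep]
    raw = {k: v[keep] for k, v in raw.items()}
    b = model.core.baseline
    bfl = model.core.baseline_fluxes
    normalized = {
        "dpsi": raw["dpsi"] / b.dpsi,
        "nadh": raw["nadh"] / b.nadh,
        "atp": raw["atp"] / b.atp,
        "superoxide": raw["superoxide"],
        "h2o2": raw["h2o2"],
        "hydroxyl": raw["hydroxyl"] / b.hydroxyl,
        "v_o2": raw["v_o2"] / bfl.v_o2,
        "m": raw["m"] / model.mtdna.m0,
        "fe": raw["fe"] / model.iron.fe0,
    }
    return SimulationResult(time_h=t, raw=raw, normalized=normalized,
                            outcome=outcome, collapse_time_h=collapse_time,
                            meta=meta)


def _raw_from_full(model: DoxToxicityModel, schedule: DoseSchedule,
                   t: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    from .core import MitoState

    v_o2 = np.empty(t.size)
    for i, ti in enumerate(t):
        eff = model.effects_at(ti, schedule, fe=y[7, i])
        p_scaled = scale_densities(model.core.params, min(max(y[6, i], 0.0), 1.0))
        scaled = _ScaledView(model.core, p_scaled)
        v_o2[i] = scaled.fluxes(MitoState.from_array(y[:6, i]), eff).v_o2
    dox = np.array([dox_concentration(ti, schedule, model.pk) for ti in t])
    return {"dpsi": y[0], "nadh": y[1], "atp": y[2], "superoxide": y[3],
            "h2o2": y[4], "hydroxyl": y[5], "m": np.clip(y[6], 0.0, 1.0),
            "fe": y[7], "dox": dox, "v_o2": v_o2}


class _ScaledView:
    """Parameter-scaled flux view sharing the parent's normalization."""

    def __init__(self, parent: BioenergeticCore, params: CoreParams):
        self.params = params
        self.nadh_base = parent.nadh_base
        self.vetc_base = parent.vetc_base
        self._norm_c1 = parent._norm_c1
        self._norm_c3 = parent._norm_c3

    _g = BioenergeticCore._g
    _h_syn = BioenergeticCore._h_syn
    _chain_conductance = staticmethod(BioenergeticCore._chain_conductance)
    _density_amp = staticmethod(BioenergeticCore._density_amp)
    _so_sources = BioenergeticCore._so_sources
    fluxes = BioenergeticCore.fluxes


def _raw_from_slow(model: DoxToxicityModel, schedule: DoseSchedule,
                   t: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    interp, m_c = model.qss_map()
    b = model.core.baseline
    m = np.clip(y[0], 0.0, 1.0)
    fe = y[1]
    dox = np.array([dox_concentration(ti, schedule, model.pk) for ti in t])
    fe_used = np.array([model.iron.fe0 if model.iron.in_window(ti) else fe[i]
                        for i, ti in enumerate(t)])
    idx = {k: np.array([float(interp[k](mi)) for mi in m]) for k in INDEX_NAMES}
    return {
        "dpsi": idx["dpsi"] * b.dpsi,
        "nadh": idx["nadh"] * b.nadh,
        "atp": idx["atp"] * b.atp,
        "superoxide": idx["superoxide"],
        "h2o2": idx["h2o2"],
        "hydroxyl": idx["hydroxyl"] * b.hydroxyl * fe_used / model.iron.fe0,
        "m": m, "fe": fe, "dox": dox,
        "v_o2": idx["v_o2"] * model.core.baseline_fluxes.v_o2,
    }


def _classify(model: DoxToxicityModel, schedule: DoseSchedule,
              collapse_time: float | None, t_end: float,
              m_end: float, fe_end: float) -> str:
    if collapse_time is not None:
        return "collapsed"
    if not (model.switches.direct_mtdna_damage or model.switches.ros_mtdna_damage):
        return "recovered"
    try:
        m_star = model.bifurcation_content
    except Exception:
        m_star = 0.0
    dm = model._slow_rhs(t_end, np.array([m_end, fe_end]), schedule)[0]
    if m_end > m_star and (dm >= -1e-12 or abs(m_end - model.mtdna.m0) < 0.005):
        return "recovered"
    return "progressing"


def simulate_protocol(model: DoxToxicityModel, schedule: DoseSchedule,
                      horizon_h: float, mode: str = "hybrid") -> SimulationResult:
    """Integrate a dosing protocol from the drug-free baseline.

    ``mode='hybrid'`` alternates full stiff integration inside acute dose
    windows with quasi-steady slow integration between them;
    ``mode='full'`` integrates the complete system throughout (the oracle
    the hybrid is verified against).
    """
    if mode not in ("hybrid", "full"):
        raise ValueError("mode must be 'hybrid' or 'full'")
    if schedule.constant_um is not None:
        mode = "full"

    model.qss_map()
    m, fe = model.mtdna.m0, model.iron.fe0
    parts: list[tuple[np.ndarray, dict[str, np.ndarray]]] = []
    collapse_time: float | None = None

    if mode == "full":
        y0 = model._full_y0(m, fe)
        n_out = max(int(240 * min(horizon_h / model.acute_window_h, 10)), 240)
        t, y, collapse_time = _full_segment(model, schedule, 0.0, horizon_h,
                                            y0, n_out=n_out)
        parts.append((t, _raw_from_full(model, schedule, t, y)))
        m_end, fe_end = float(np.clip(y[6, -1], 0, 1)), float(y[7, -1])
        t_end = float(t[-1])
    else:
        windows = _acute_windows(schedule, model.acute_window_h, horizon_h)
        t_cursor = 0.0
        m_end, fe_end, t_end = m, fe, horizon_h
        segments: list[tuple[str, float, float]] = []
        for a, b in windows:
            if a > t_cursor:
                segments.append(("slow", t_cursor, a))
            segments.append(("full", a, b))
            t_cursor = b
        if t_cursor < horizon_h:
            segments.append(("slow", t_cursor, horizon_h))
        for kind, a, b in segments:
            if kind == "full":
                y0 = model._full_y0(m, fe)
                t, y, collapsed_at = _full_segment(model, schedule, a, b, y0)
                parts.append((t, _raw_from_full(model, schedule, t, y)))
                m, fe = float(np.clip(y[6, -1], 0, 1)), float(y[7, -1])
            else:
                t, y, collapsed_at = _slow_segment(model, schedule, a, b, m, fe)
                parts.append((t, _raw_from_slow(model, schedule, t, y)))
                m, fe = float(np.clip(y[0, -1], 0, 1)), float(y[1, -1])
            if collapsed_at is not None:
                collapse_time = collapsed_at
                break
        m_end, fe_end, t_end = m, fe, float(parts[-1][0][-1])

    outcome = _classify(model, schedule, collapse_time, t_end, m_end, fe_end)
    return _assemble(model, schedule, parts, outcome, collapse_time,
                     meta={"mode": mode, "horizon_h": horizon_h})
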
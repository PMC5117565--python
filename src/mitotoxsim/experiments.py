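"""In-silico experiment pipelines.

The four study designs built on the simulation engine:

* :func:`acute_sweep` — constant-concentration steady-state dose sweep per
  pathway arm, with collapse thresholds and the ROS crossover concentration;
* :func:`dynamic_run` — pharmacokinetically forced transient simulation;
* :func:`chronic_protocol` — weekly dosing with multi-week follow-up and
  outcome classification against the mtDNA bifurcation;
* :func:`chelation_experiment` — chronic dosing with iron clamped at
  baseline over a chelation window of configurable extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mtdna import HOURS_PER_WEEK
from .pathways import DoseSchedule, IronModel, PathwaySwitches
from .simulate import DoxToxicityModel, SimulationResult, simulate_protocol

__all__ = [
    "SweepResult",
    "acute_sweep",
    "collapse_threshold",
    "ros_crossover",
    "dynamic_run",
    "chronic_protocol",
    "chelation_experiment",
    "ARMS",
]

ARMS = {
    "etc": PathwaySwitches.only("etc_inhibition"),
    "rc": PathwaySwitches.only("redox_cycling"),
    "both": PathwaySwitches.only("etc_inhibition", "redox_cycling"),
}


@dataclass
class SweepResult:
    """Steady-state dose sweep over pathway arms."""

    dox_grid: np.ndarray
    indices: dict[str, dict[str, np.ndarray]]   # arm -> index name -> values
    collapsed: dict[str, np.ndarray]            # arm -> bool per dose
    thresholds: dict[str, float]                # arm -> collapse threshold (uM)
    ros_crossover_um: float | None


def _steady_at(model: DoxToxicityModel, dox: float, arm: str):
    m = model.with_switches(ARMS[arm])
    eff = m.effects_at(0.0, DoseSchedule(constant_um=dox))
    return model.core.solve_steady_state(eff)


def total_ros_index(normalized: dict[str, float]) -> float:
    """Aggregate normalized ROS burden: superoxide + peroxide + hydroxyl."""
    return (normalized["superoxide"] + normalized["h2o2"]
            + normalized["hydroxyl"])


def collapse_threshold(model: DoxToxicityModel, arm: str,
                       lo: float = 0.0, hi: float = 800.0,
                       precision_um: float = 1.0) -> float:
    """Smallest constant concentration whose steady state is collapsed.

    Bisection on the collapse flag to ``precision_um``; returns ``inf`` if
    even ``hi`` does not collapse the model.
    """
    if not _steady_at(model, hi, arm).collapsed:
        return math.inf
    while hi - lo > precision_um:
        mid = 0.5 * (lo + hi)
        if _steady_at(model, mid, arm).collapsed:
            hi = mid
        else:
            lo = mid
    return hi


def ros_crossover(model: DoxToxicityModel, lo: float = 5.0,
                  hi: float | None = None,
                  precision_um: float = 1.0) -> float | None:
    """Concentration where ETC-driven ROS increase overtakes the RC-driven one.

    Both single-pathway arms are evaluated at the same constant
    concentration; the crossover is the lowest concentration at which the
    ETC-only increase in total ROS exceeds the RC-only increase, bisected to
    ``precision_um``.  Returns ``None`` when no crossover exists below the
    ETC-arm collapse threshold.
    """
    if hi is None:
        thr = collapse_threshold(model, "etc")
        hi = (thr if math.isfinite(thr) else 800.0) - 2.0

    def gap(d: float) -> float:
        se = _steady_at(model, d, "etc")
        if se.collapsed:
            return math.inf
        sr = _steady_at(model, d, "rc")
        return (total_ros_index(se.normalized)
                - total_ros_index(sr.normalized))

    if gap(lo) > 0 or gap(hi) < 0:
        return None
    while hi - lo > precision_um:
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def acute_sweep(model: DoxToxicityModel, dox_grid, arms=("etc", "rc", "both"),
                threshold_hi: float = 800.0) -> SweepResult:
    """Constant-concentration steady-state sweep per pathway arm."""
    dox_grid = np.asarray(dox_grid, dtype=float)
    if np.any(np.diff(dox_grid) <= 0) or np.any(dox_grid < 0):
        raise ValueError("dose grid must be non-negative and increasing")
    indices: dict[str, dict[str, np.ndarray]] = {}
    collapsed: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    for arm in arms:
        rows, coll = [], []
        for d in dox_grid:
            ss = _steady_at(model, float(d), arm)
            if not ss.converged and not ss.collapsed:
                raise RuntimeError(
                    f"steady state did not converge for arm {arm} at {d} uM")
            rows.append(ss.normalized)
            coll.append(ss.collapsed)
        indices[arm] = {k: np.array([r[k] for r in rows])
                        for k in rows[0]}
        collapsed[arm] = np.array(coll)
        thresholds[arm] = collapse_threshold(model, arm, hi=threshold_hi)
    xo = ros_crossover(model) if {"etc", "rc"} <= set(arms) else None
    return SweepResult(dox_grid=dox_grid, indices=indices, collapsed=collapsed,
                       thresholds=thresholds, ros_crossover_um=xo)


def dynamic_run(model: DoxToxicityModel, schedule: DoseSchedule,
                switches: PathwaySwitches | None = None,
                horizon_h: float | None = None,
                mode: str = "full") -> SimulationResult:
    """Pharmacokinetically forced transient simulation.

    The default horizon extends ten elimination half-lives past the last
    dose so recovery can be assessed.  With mtDNA damage disabled every
    sub-threshold protocol must return to baseline ("recovered").
    """
    m = model.with_switches(switches) if switches is not None else model
    if horizon_h is None:
        horizon_h = schedule.last_dose_time + 10.0 * m.pk.t_half_elim_h
    res = simulate_protocol(m, schedule, horizon_h, mode=mode)
    if res.outcome != "collapsed":
        # transient runs are judged on return-to-baseline of the function
        # indices, not only on mtDNA content
        dev = max(abs(res.normalized[k][-1] - 1.0)
                  for k in ("dpsi", "nadh", "atp", "superoxide", "h2o2"))
        dev_m = abs(res.raw["m"][-1] - m.mtdna.m0) / m.mtdna.m0
        res.outcome = "recovered" if max(dev, dev_m) < 0.01 else "progressing"
    return res


def chronic_protocol(model: DoxToxicityModel, n_doses: int, dose_um: float,
                     spacing_h: float = HOURS_PER_WEEK,
                     follow_up_weeks: float = 40.0,
                     mode: str = "hybrid") -> SimulationResult:
    """Weekly dosing protocol with long follow-up.

    ``follow_up_weeks`` is the total simulated horizon from the first dose.
    Outcome: ``recovered`` if content ends above the bifurcation and trends
    back to baseline, ``collapsed`` if bioenergetic collapse is reached, and
    ``progressing`` otherwise.
    """
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    schedule = DoseSchedule.weekly(n_doses, dose_um, spacing_h=spacing_h)
    horizon_h = follow_up_weeks * HOURS_PER_WEEK
    res = simulate_protocol(model, schedule, horizon_h, mode=mode)
    res.meta.update(n_doses=n_doses, dose_um=dose_um)
    return res


def chelation_experiment(model: DoxToxicityModel, n_doses: int = 7,
                         dose_um: float = 24.0,
                         chelation_mode: str = "none",
                         follow_up_weeks: float = 37.0,
                         spacing_h: float = HOURS_PER_WEEK,
                         mode: str = "hybrid") -> SimulationResult:
    """Chronic dosing with iron-chelator co-treatment.

    ``chelation_mode``: ``none`` (no chelation), ``during`` (iron clamped at
    baseline over the treatment span), ``2x`` / ``3x`` (window extended to
    two / three times the treatment duration from the first dose).
    ``follow_up_weeks`` counts from the end of treatment.
    """
    factors = {"none": 0.0, "during": 1.0, "2x": 2.0, "3x": 3.0}
    if chelation_mode not in factors:
        raise ValueError(f"unknown chelation mode {chelation_mode!r}")
    treatment_h = n_doses * spacing_h
    factor = factors[chelation_mode]
    windows = ((0.0, factor * treatment_h),) if factor > 0 else ()
    iron = IronModel(fe0=model.iron.fe0, k_fe=model.iron.k_fe,
                     chelation_windows=windows,
                     clear_half_time_h=model.iron.clear_half_time_h)
    m = model.with_iron(iron)
    schedule = DoseSchedule.weekly(n_doses, dose_um, spacing_h=spacing_h)
    horizon_h = treatment_h + follow_up_weeks * HOURS_PER_WEEK
    res = simulate_protocol(m, schedule, horizon_h, mode=mode)
    res.meta.update(n_doses=n_doses, dose_um=dose_um,
                    chelation_mode=chelation_mode)
    return res
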
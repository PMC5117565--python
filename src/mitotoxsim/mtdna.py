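"""mtDNA damage and repair dynamics.

Mass-action model of mitochondrial DNA content ``m`` (unitless, normalized;
baseline 0.75):

    dm/dt = alpha * (1-m) / ((1-m) + kappa)        (enzymatic repair, saturating)
          - beta  * [OH]_n * m                      (oxidative damage)
          - gamma * [DOX]  * m                      (direct drug damage)

``[OH]_n`` is the core's hydroxyl radical concentration normalized to
baseline.  At baseline (``[OH]_n = 1``, no drug) damage balances repair,
which pins ``beta`` given ``alpha``, ``kappa`` and the baseline content —
``beta`` is therefore a derived quantity, not a free parameter.

The module also provides the phase-plane analysis (content held fixed,
bioenergetics at quasi-steady state), bisection for the bifurcation content
below which the ROS -> mtDNA damage -> protein loss -> ROS vicious cycle is
self-sustaining, and the attribution of net content loss between the direct
and oxidative damage terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import BioenergeticCore, MTDNA_REF
from .pathways import DoxEffects

__all__ = [
    "MtDNAParams",
    "PhasePoint",
    "AttributionResult",
    "derive_beta",
    "dmtdna_dt",
    "phase_curve",
    "find_bifurcation",
    "attribute_damage",
    "NoBifurcationError",
]

HOURS_PER_WEEK = 168.0


class NoBifurcationError(RuntimeError):
    """Raised when the phase curve admits no unstable root below baseline."""


def derive_beta(alpha: float, kappa: float, m0: float) -> float:
    """ROS damage coefficient from the baseline balance.

    At baseline content ``m0`` with normalized hydroxyl 1 and no drug,
    repair equals damage: ``alpha (1-m0)/((1-m0)+kappa) = beta m0``.
    """
    if not 0.0 < m0 < 1.0:
        raise ValueError("m0 must lie in (0, 1)")
    return alpha * (1.0 - m0) / (((1.0 - m0) + kappa) * m0)


@dataclass(frozen=True)
class MtDNAParams:
    """Coefficients of the damage/repair balance (rates per week)."""

    alpha: float = 0.0045   # maximum repair rate, 1/week
    kappa: float = 0.05     # repair half-saturation, content units
    gamma: float = 0.00165  # direct DOX damage, 1/(uM week)
    m0: float = MTDNA_REF   # baseline content
    oh_ceiling: float = 1e3 # cap on normalized hydroxyl entering the damage term

    def __post_init__(self):
        for name in ("alpha", "kappa", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"mtdna.{name} must be non-negative")
        if not 0.0 < self.m0 < 1.0:
            raise ValueError("mtdna.m0 must lie in (0, 1)")

    @property
    def beta(self) -> float:
        """ROS damage coefficient (1/week per normalized hydroxyl), derived
        from the baseline balance."""
        return derive_beta(self.alpha, self.kappa, self.m0)


def dmtdna_dt(m: float, oh_n: float, dox: float, p: MtDNAParams,
              ros_damage: bool = True, direct_damage: bool = True) -> float:
    """Rate of change of mtDNA content, per week.

    ``oh_n`` is the normalized hydroxyl concentration, ``dox`` the drug
    concentration in uM.  The pathway flags zero the corresponding damage
    term (baseline oxidative damage is part of the balance, so disabling
    ``ros_damage`` also removes the repair offset it balances — both flags
    off with no drug leaves ``m`` frozen only at ``m0``).
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("mtDNA content must lie in [0, 1]")
    if oh_n < 0 or dox < 0:
        raise ValueError("oh_n and dox must be non-negative")
    repair = p.alpha * (1.0 - m) / ((1.0 - m) + p.kappa)
    oh_eff = min(oh_n, p.oh_ceiling) if ros_damage else 1.0
    damage_ros = p.beta * oh_eff * m
    damage_direct = p.gamma * dox * m if direct_damage else 0.0
    return repair - damage_ros - damage_direct


@dataclass(frozen=True)
class PhasePoint:
    """One point of the content phase curve at quasi-steady bioenergetics."""

    m: float
    dmdt_per_week: float
    indices: dict[str, float]   # normalized steady-state function indices
    collapsed: bool
    converged: bool


def phase_curve(m_grid: Sequence[float], core: BioenergeticCore,
                p: MtDNAParams) -> list[PhasePoint]:
    """Evaluate dm/dt across a grid of contents with no drug present.

    For each content the complex densities are scaled, the core relaxed to
    steady state, and the damage/repair balance evaluated with the resulting
    normalized hydroxyl level.  Non-convergence is marked per point rather
    than raised.
    """
    identity = DoxEffects.identity()
    points = []
    for m in m_grid:
        if not 0.0 <= m <= 1.0:
            raise ValueError("phase grid must lie within [0, 1]")
        ss = core.solve_steady_state(identity, mtdna=m)
        oh_n = p.oh_ceiling if ss.collapsed else ss.normalized["hydroxyl"]
        rate = dmtdna_dt(m, oh_n, 0.0, p)
        points.append(PhasePoint(m=m, dmdt_per_week=rate,
                                 indices=dict(ss.normalized),
                                 collapsed=ss.collapsed,
                                 converged=ss.converged))
    return points


def _dmdt_at(core: BioenergeticCore, p: MtDNAParams, m: float) -> float:
    ss = core.solve_steady_state(DoxEffects.identity(), mtdna=m)
    oh_n = p.oh_ceiling if ss.collapsed else ss.normalized["hydroxyl"]
    return dmtdna_dt(m, oh_n, 0.0, p)


def find_bifurcation(core: BioenergeticCore, p: MtDNAParams,
                     m_min: float = 0.40, xtol: float = 1e-4,
                     scan_step: float = 0.005) -> float:
    """Locate the unstable root of the phase curve below baseline.

    Scans downward from just under ``m0`` for the first sign change of
    dm/dt (positive in the stable recovery band, negative once the vicious
    cycle dominates) and bisects it to ``xtol`` content precision.
    """
    hi = p.m0 - 1e-3
    g_hi = _dmdt_at(core, p, hi)
    m = hi
    while m - scan_step > m_min:
        m_next = m - scan_step
        g = _dmdt_at(core, p, m_next)
        if g_hi > 0.0 >= g:
            lo, hi_b = m_next, m
            while hi_b - lo > xtol:
                mid = 0.5 * (lo + hi_b)
                if _dmdt_at(core, p, mid) > 0.0:
                    hi_b = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi_b)
        m, g_hi = m_next, g
    raise NoBifurcationError(
        "phase curve has no unstable root below baseline: repair dominates "
        "at all contents down to m_min (is beta/oxidative damage too weak?)")


@dataclass(frozen=True)
class AttributionResult:
    """Split of net mtDNA loss between direct and excess-oxidative damage.

    Oxidative damage is counted in excess of baseline (``max(oh_n - 1, 0)``):
    baseline ROS damage is balanced by repair and causes no net reduction.
    """

    direct_integral: float
    oxidative_excess_integral: float
    fraction_direct: float
    window: tuple[float, float]


def attribute_damage(t_h: np.ndarray, m: np.ndarray, oh_n: np.ndarray,
                     dox: np.ndarray, p: MtDNAParams,
                     window: tuple[float, float]) -> AttributionResult:
    """Integrate the Eq-balance damage terms over an acute window.

    ``t_h`` in hours; trapezoid rule on the trajectory grid.  The window is
    clipped to the trajectory support and must be non-empty.
    """
    t0, t1 = window
    sel = (t_h >= t0) & (t_h <= t1)
    if sel.sum() < 2:
        raise ValueError(f"attribution window ({t0}, {t1}) h selects fewer "
                         "than two trajectory samples")
    tw = t_h[sel] / HOURS_PER_WEEK
    mw, ohw, dw = m[sel], oh_n[sel], dox[sel]
    direct = float(np.trapezoid(p.gamma * dw * mw, tw))
    excess = np.maximum(np.minimum(ohw, p.oh_ceiling) - 1.0, 0.0)
    oxid = float(np.trapezoid(p.beta * excess * mw, tw))
    total = direct + oxid
    frac = direct / total if total > 0 else (1.0 if direct > 0 else 0.0)
    return AttributionResult(direct_integral=direct,
                             oxidative_excess_integral=oxid,
                             fraction_direct=frac, window=(t0, t1))
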
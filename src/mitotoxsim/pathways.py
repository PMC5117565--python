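"""Acute doxorubicin mechanisms.

Pharmacokinetic forcing (one-compartment, first-order absorption and
elimination), per-complex ETC inhibition (Hill curves on activity),
redox-cycling superoxide production at Complex I, dose-unit conversion and
the free-iron / chelation model, composed into a :class:`DoxEffects` bundle
consumed by the bioenergetics core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PKParams",
    "DoseSchedule",
    "ETCInhibitionParams",
    "RedoxCyclingParams",
    "IronModel",
    "PathwaySwitches",
    "DoxEffects",
    "dox_concentration",
    "etc_activity_scale",
    "redox_cycling_source",
    "mg_per_kg_to_um",
    "iron_level",
    "compose_effects",
]

UM_PER_MG_KG = 30.0  # mitochondrial uM per mg/kg body dose (rat)

COMPLEXES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class PKParams:
    """One-compartment pharmacokinetics of mitochondrial DOX.

    Fast absorption (half-time minutes) and slow elimination (half-time
    hours); with ``peak_norm`` each dose's two-exponential curve is scaled so
    its maximum equals the nominal dose in uM.
    """

    t_half_abs_min: float = 5.0
    t_half_elim_h: float = 24.0
    peak_norm: bool = True

    def __post_init__(self):
        if self.t_half_abs_min <= 0 or self.t_half_elim_h <= 0:
            raise ValueError("pk half-times must be positive")
        if self.t_half_abs_min / 60.0 >= self.t_half_elim_h:
            raise ValueError("absorption half-time must be shorter than elimination")

    @property
    def ka(self) -> float:
        """Absorption rate constant, 1/h."""
        return math.log(2.0) / (self.t_half_abs_min / 60.0)

    @property
    def ke(self) -> float:
        """Elimination rate constant, 1/h."""
        return math.log(2.0) / self.t_half_elim_h

    @property
    def t_peak(self) -> float:
        """Time of the concentration maximum after a single dose, hours."""
        return math.log(self.ka / self.ke) / (self.ka - self.ke)

    @property
    def peak_factor(self) -> float:
        """Value of (e^-ke t - e^-ka t) at its maximum."""
        t = self.t_peak
        return math.exp(-self.ke * t) - math.exp(-self.ka * t)


@dataclass(frozen=True)
class DoseSchedule:
    """Dosing events as (time in hours, dose in uM) pairs.

    ``constant_um`` overrides the pharmacokinetics with a fixed concentration
    (used for steady-state dose sweeps).
    """

    events: tuple[tuple[float, float], ...] = ()
    constant_um: float | None = None

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose event times must be non-decreasing")
        if any(d < 0 for _, d in self.events):
            raise ValueError("doses must be non-negative")
        if self.constant_um is not None and self.constant_um < 0:
            raise ValueError("constant concentration must be non-negative")

    @staticmethod
    def weekly(n_doses: int, dose_um: float, spacing_h: float = 168.0,
               start_h: float = 0.0) -> "DoseSchedule":
        return DoseSchedule(tuple((start_h + i * spacing_h, dose_um)
                                  for i in range(n_doses)))

    @property
    def last_dose_time(self) -> float:
        return self.events[-1][0] if self.events else 0.0


def dox_concentration(t: float, schedule: DoseSchedule, pk: PKParams) -> float:
    """Mitochondrial DOX concentration (uM) at time ``t`` hours.

    Superposition over dose events of the two-exponential absorption /
    elimination curve; in ``constant_um`` mode the fixed value is returned.
    """
    if schedule.constant_um is not None:
        return schedule.constant_um
    c = 0.0
    norm = 1.0 / pk.peak_factor if pk.peak_norm else 1.0
    for t0, dose in schedule.events:
        tau = t - t0
        if tau <= 0.0 or dose == 0.0:
            continue
        c += dose * norm * (math.exp(-pk.ke * tau) - math.exp(-pk.ka * tau))
    return c


@dataclass(frozen=True)
class ETCInhibitionParams:
    """Hill inhibition of each ETC complex by DOX (activity scaling)."""

    ic50_I: float = 784.4
    ic50_II: float = 941.3
    ic50_III: float = 470.6
    ic50_IV: float = 1019.7
    hill_I: float = 2.25
    hill_II: float = 2.25
    hill_III: float = 2.25
    hill_IV: float = 2.25

    def __post_init__(self):
        for c in COMPLEXES:
            if getattr(self, f"ic50_{c}") <= 0:
                raise ValueError(f"etc_inhibition.ic50_{c} must be positive")
            if getattr(self, f"hill_{c}") <= 0:
                raise ValueError(f"etc_inhibition.hill_{c} must be positive")

    def ic50(self, complex_id: str) -> float:
        return getattr(self, f"ic50_{complex_id}")

    def hill(self, complex_id: str) -> float:
        return getattr(self, f"hill_{complex_id}")


def etc_activity_scale(complex_id: str, dox: float,
                       p: ETCInhibitionParams) -> float:
    """Fractional activity of an ETC complex at a DOX concentration (uM)."""
    if complex_id not in COMPLEXES:
        raise ValueError(f"unknown ETC complex {complex_id!r}; expected one of {COMPLEXES}")
    if dox < 0:
        raise ValueError("dox concentration must be non-negative")
    if dox == 0.0:
        return 1.0
    return 1.0 / (1.0 + (dox / p.ic50(complex_id)) ** p.hill(complex_id))


@dataclass(frozen=True)
class RedoxCyclingParams:
    """Superoxide source gain of DOX redox cycling at Complex I.

    ``eta`` is the normalized superoxide source per uM DOX at baseline NADH;
    the default is calibrated so that a constant 10 uM exposure produces a
    7% steady-state superoxide increase.
    """

    eta: float = 0.007276

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("redox_cycling.eta must be non-negative")


def redox_cycling_source(dox: float, nadh: float, nadh_base: float,
                         p: RedoxCyclingParams) -> float:
    """Redox-cycling superoxide source, gated by Complex I electron supply."""
    if dox < 0:
        raise ValueError("dox concentration must be non-negative")
    return p.eta * dox * nadh / nadh_base


def mg_per_kg_to_um(dose_mg_kg: float) -> float:
    """Convert a body dose in mg/kg to the equivalent mitochondrial uM."""
    if dose_mg_kg < 0:
        raise ValueError("dose must be non-negative")
    return dose_mg_kg * UM_PER_MG_KG


@dataclass(frozen=True)
class IronModel:
    """Free-iron response to DOX with optional chelation windows.

    Quasi-steady iron is ``fe0 * (1 + k_fe * dox)`` outside chelation windows
    and exactly ``fe0`` inside one (chelator clamps iron at baseline).
    Dynamic runs relax iron toward the quasi-steady value with half-time
    ``clear_half_time_h`` (iron released by DOX is cleared slowly, so the
    benefit of chelation can extend past the end of dosing).
    """

    fe0: float = 1.0
    k_fe: float = 0.01
    chelation_windows: tuple[tuple[float, float], ...] = ()
    clear_half_time_h: float = 336.0

    def __post_init__(self):
        if self.fe0 <= 0:
            raise ValueError("iron.fe0 must be positive")
        if self.k_fe < 0:
            raise ValueError("iron.k_fe must be non-negative")
        if self.clear_half_time_h <= 0:
            raise ValueError("iron.clear_half_time_h must be positive")
        ws = sorted(self.chelation_windows)
        if any(e <= s for s, e in ws):
            raise ValueError("chelation windows must have end > start")
        if any(w2[0] < w1[1] for w1, w2 in zip(ws, ws[1:])):
            raise ValueError("chelation windows must not overlap")

    @property
    def k_clear(self) -> float:
        return math.log(2.0) / self.clear_half_time_h

    def in_window(self, t: float) -> bool:
        return any(s <= t < e for s, e in self.chelation_windows)


def iron_level(t: float, dox: float, m: IronModel) -> float:
    """Quasi-steady normalized free iron at time ``t`` (hours)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if m.in_window(t):
        return m.fe0
    return m.fe0 * (1.0 + m.k_fe * dox)


@dataclass(frozen=True)
class PathwaySwitches:
    """Independent enable/disable flags for the toxicity pathways."""

    etc_inhibition: bool = True
    redox_cycling: bool = True
    direct_mtdna_damage: bool = True
    ros_mtdna_damage: bool = True

    @staticmethod
    def none() -> "PathwaySwitches":
        return PathwaySwitches(False, False, False, False)

    @staticmethod
    def only(*names: str) -> "PathwaySwitches":
        return PathwaySwitches(**{n: (n in names) for n in (
            "etc_inhibition", "redox_cycling",
            "direct_mtdna_damage", "ros_mtdna_damage")})

    @property
    def any_active(self) -> bool:
        return (self.etc_inhibition or self.redox_cycling
                or self.direct_mtdna_damage or self.ros_mtdna_damage)


@dataclass(frozen=True)
class DoxEffects:
    """Snapshot of the acute drug effects fed to the core.

    ``v_rc`` is the redox-cycling superoxide source at baseline NADH
    (the core gates it by the instantaneous NADH fraction).
    """

    scale_c1: float = 1.0
    scale_c2: float = 1.0
    scale_c3: float = 1.0
    scale_c4: float = 1.0
    scale_syn: float = 1.0
    v_rc: float = 0.0
    fe: float = 1.0
    dox: float = 0.0

    @staticmethod
    def identity() -> "DoxEffects":
        return DoxEffects()

    def validate(self) -> None:
        for name in ("scale_c1", "scale_c2", "scale_c3", "scale_c4", "scale_syn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"activity {name} must lie in [0, 1], got {v}")
        if self.v_rc < 0:
            raise ValueError("redox-cycling source must be non-negative")
        if self.fe <= 0:
            raise ValueError("iron level must be positive")


def compose_effects(
    t: float,
    schedule: DoseSchedule,
    pk: PKParams,
    etc_p: ETCInhibitionParams,
    rc_p: RedoxCyclingParams,
    iron_m: IronModel,
    switches: PathwaySwitches,
    fe: float | None = None,
) -> DoxEffects:
    """Evaluate all acute drug effects at time ``t``.

    Disabled pathways contribute identity (activity 1, source 0).  ``fe``
    overrides the quasi-steady iron level (used when iron is integrated as a
    dynamic state); chelation windows clamp it to baseline either way.
    """
    dox = dox_concentration(t, schedule, pk)
    if not switches.any_active:
        # all toxicity pathways disabled: the drug has no effect at all,
        # iron included (guarantees the no-drug baseline trajectory exactly)
        dox_eff = 0.0
    else:
        dox_eff = dox
    if switches.etc_inhibition and dox_eff > 0:
        scales = {c: etc_activity_scale(c, dox_eff, etc_p) for c in COMPLEXES}
    else:
        scales = {c: 1.0 for c in COMPLEXES}
    v_rc = rc_p.eta * dox_eff if switches.redox_cycling else 0.0
    if iron_m.in_window(t):
        fe_val = iron_m.fe0
    elif fe is not None:
        fe_val = fe
    else:
        fe_val = iron_level(t, dox_eff, iron_m)
    return DoxEffects(scale_c1=scales["I"], scale_c2=scales["II"],
                      scale_c3=scales["III"], scale_c4=scales["IV"],
                      scale_syn=1.0, v_rc=v_rc, fe=fe_val, dox=dox_eff)
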
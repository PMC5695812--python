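"""Two-step covalent inactivation kinetics and the coupled-assay signal model.

Mechanism: the inhibitor I binds the enzyme reversibly (dissociation scale
``K_I``) and the complex then reacts irreversibly at rate ``k_inact``::

    E + I  <-->  E.I  -->  E-I (dead)

Under pseudo-first-order conditions the observed inactivation rate is the
hyperbola ``kobs(I) = k_inact * I / (K_I + I)`` and residual activity after
pre-incubation time t is ``exp(-kobs(I) * t)``. An optional glutathione
scavenger depletes free inhibitor exponentially (pseudo-first-order in I,
GSH in excess), in which case the exposure integral is evaluated by
adaptive quadrature.

The readout model mirrors an NADPH-coupled spectrophotometric assay: the
enzyme turns over its disulfide substrate, a coupling reductase regenerates
the thiol at the expense of NADPH (1:1), and A340 falls linearly at
epsilon * l * (consumption rate) until NADPH or the disulfide substrate is
exhausted. The coupling enzyme is in excess and never modeled as limiting.

Units: inhibitor concentrations in uM, assay reagents in mM, time in
minutes, activities in milliunits (nmol substrate/min).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "InactivationParams",
    "InactivationObservation",
    "ScavengerSpec",
    "AssayMix",
    "ProgressCurve",
    "NonLinearCurveWarning",
    "kobs",
    "residual_fraction",
    "simulate_progress_curve",
    "rate_from_curve",
    "percent_inhibition",
]


class NonLinearCurveWarning(UserWarning):
    """Progress curve leaves the linear regime before the second sample."""


@dataclass(frozen=True)
class InactivationParams:
    """Mechanism parameters: K_I in uM (>0), k_inact in 1/min (>=0)."""

    K_I: float
    k_inact: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.K_I) and math.isfinite(self.k_inact)):
            raise ValueError("K_I and k_inact must be finite")
        if self.K_I <= 0:
            raise ValueError(f"K_I must be strictly positive, got {self.K_I}")
        if self.k_inact < 0:
            raise ValueError(f"k_inact must be non-negative, got {self.k_inact}")


@dataclass(frozen=True)
class InactivationObservation:
    """One pre-incubation measurement: (I uM, E0, Et activities, t min)."""

    I: float
    E0: float
    Et: float
    t: float

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError(f"E0 must be positive, got {self.E0}")
        if self.t <= 0:
            raise ValueError(f"t must be positive, got {self.t}")
        if self.Et < 0:
            raise ValueError(f"Et must be non-negative, got {self.Et}")
        if self.I < 0:
            raise ValueError(f"I must be non-negative, got {self.I}")


@dataclass(frozen=True)
class ScavengerSpec:
    """Electrophile scavenger: concentration in mM, k2 in 1/(M min)."""

    concentration: float
    k2: float

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.k2 < 0:
            raise ValueError("scavenger concentration and k2 must be non-negative")

    @property
    def pseudo_first_order_rate(self) -> float:
        """Decay rate of free inhibitor, 1/min (k2 [M^-1 min^-1] x conc [M])."""
        return self.k2 * self.concentration * 1e-3


@dataclass(frozen=True)
class AssayMix:
    """Coupled-assay composition; concentrations mM, blank drift AU/min.

    epsilon340 is the NADPH molar absorptivity (M^-1 cm^-1); 6220 is the
    standard literature value.
    """

    nadph_mM: float = 0.2
    gsh_mM: float = 0.5
    gr_units_per_ml: float = 2.0
    cyssg_mM: float = 0.1
    path_cm: float = 1.0
    epsilon340: float = 6220.0
    blank_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nadph_mM", "gsh_mM", "gr_units_per_ml", "cyssg_mM", "path_cm", "epsilon340"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ProgressCurve:
    """Timestamped A340 reads; times in min starting at 0, strictly increasing."""

    times: tuple[float, ...]
    A340: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        a340 = tuple(float(a) for a in self.A340)
        if len(times) != len(a340):
            raise ValueError("times and A340 must have equal length")
        if not times or times[0] != 0:
            raise ValueError("times must start at 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "A340", a340)


def kobs(params: InactivationParams, I: float) -> float:
    """Observed pseudo-first-order inactivation rate at inhibitor concentration I (uM)."""
    if I < 0:
        raise ValueError(f"inhibitor concentration must be non-negative, got {I}")
    return params.k_inact * I / (params.K_I + I)


def residual_fraction(
    params: InactivationParams,
    I: float,
    t: float,
    scavenger: ScavengerSpec | None = None,
) -> float:
    """Fraction of activity remaining after pre-incubating with I for t minutes.

    Without a scavenger this is the closed form exp(-kobs(I) t). With an
    active scavenger the free inhibitor decays as I exp(-k2 [GSH] s) and
    the exposure integral k_inact * int_0^t I(s)/(K_I + I(s)) ds is
    evaluated by adaptive quadrature (relative tolerance 1e-8).
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if t == 0:
        return 1.0
    decay = scavenger.pseudo_first_order_rate if scavenger is not None else 0.0
    if decay == 0.0:
        return math.exp(-kobs(params, I) * t)

    def occupancy(s: float) -> float:
        conc = I * math.exp(-decay * s)
        return conc / (params.K_I + conc)

    exposure, _err = quad(occupancy, 0.0, t, epsrel=1e-8, epsabs=0.0, limit=200)
    return math.exp(-params.k_inact * exposure)


def simulate_progress_curve(
    mix: AssayMix,
    grx_activity: float,
    reaction_volume_ml: float,
    duration: float,
    n_points: int,
    A340_start: float | None = None,
) -> ProgressCurve:
    """Deterministic A340 trace of the coupled assay.

    grx_activity is the enzyme activity in the cuvette in milliunits
    (nmol substrate/min); each substrate turnover consumes one NADPH, so
    the NADPH consumption rate is grx_activity nmol/min. The trace is
    linear until the limiting species (NADPH or the disulfide substrate,
    1:1) is exhausted, then flat apart from the blank drift; absorbance is
    clipped at 0. The starting absorbance defaults to epsilon*l*[NADPH]0.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_points < 2:
        raise ValueError("need at least 2 sample points")
    if reaction_volume_ml <= 0:
        raise ValueError("reaction volume must be positive")
    if grx_activity < 0:
        raise ValueError("activity must be non-negative")

    times = np.linspace(0.0, duration, n_points)
    volume_l = reaction_volume_ml * 1e-3
    limiting_mol = min(mix.nadph_mM, mix.cyssg_mM) * 1e-3 * volume_l
    rate_mol_per_min = grx_activity * 1e-9  # nmol/min -> mol/min

    if rate_mol_per_min > 0 and limiting_mol > 0:
        t_depleted = limiting_mol / rate_mol_per_min
    else:
        t_depleted = math.inf
    if t_depleted < times[1]:
        warnings.warn(
            f"substrate depleted at t={t_depleted:.3g} min, before the second sample "
            f"point (t={times[1]:.3g} min): curve is non-linear",
            NonLinearCurveWarning,
            stacklevel=2,
        )

    a0 = mix.epsilon340 * mix.path_cm * mix.nadph_mM * 1e-3 if A340_start is None else A340_start
    consumed_mol = rate_mol_per_min * np.minimum(times, t_depleted)
    delta_conc = consumed_mol / volume_l  # mol/L consumed
    a340 = a0 - mix.epsilon340 * mix.path_cm * delta_conc - mix.blank_rate * times
    a340 = np.clip(a340, 0.0, None)
    return ProgressCurve(tuple(times), tuple(a340))


def rate_from_curve(curve: ProgressCurve, window: tuple[float, float] | None = None) -> float:
    """OLS slope of A340 vs time (AU/min) over the given time window."""
    times = np.asarray(curve.times)
    a340 = np.asarray(curve.A340)
    if window is not None:
        lo, hi = window
        mask = (times >= lo) & (times <= hi)
        times, a340 = times[mask], a340[mask]
    if times.size < 2:
        raise ValueError("need at least 2 points in the window to fit a slope")
    slope, _intercept = np.polyfit(times, a340, 1)
    return float(slope)


def percent_inhibition(rate_treated: float, rate_control: float, rate_blank: float = 0.0) -> float:
    """Percent inhibition from blank-corrected rates.

    100 * (1 - (treated - blank)/(control - blank)). Not clipped: noisy
    inputs may give values below 0 or above 100; clipping is a
    reporting-layer choice.
    """
    denom = rate_control - rate_blank
    if denom == 0:
        raise ValueError("control rate equals blank rate: percent inhibition undefined")
    return 100.0 * (1.0 - (rate_treated - rate_blank) / denom)
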
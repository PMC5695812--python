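"""Parameter estimation: Kitz-Wilson (K_I, k_inact) fits and log-linear IC50.

The Kitz-Wilson analysis linearizes the inactivation hyperbola
``y = kobs = k_inact I / (K_I + I)`` by plotting 1/y against 1/I::

    1/y = (K_I / k_inact) (1/I) + 1/k_inact

so the y-intercept of the double-reciprocal plot is 1/k_inact and the
slope is K_I/k_inact. A non-zero intercept is the kinetic signature of a
saturable (reversible) binding step before the covalent chemistry. The
reciprocal fit is the default method, matching how such plots are
conventionally presented; a direct nonlinear least-squares fit of the
hyperbola, initialized from the reciprocal solution, is offered as the
cross-check (reciprocal transforms are known to inflate the influence of
small-y noise).

IC50 estimation uses the log-linear model % inhibition = a + b log10(I)
restricted to a response window (default 10-90%), inverted at 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .kinetics import InactivationObservation, InactivationParams, ScavengerSpec, residual_fraction

__all__ = [
    "KitzWilsonFit",
    "ConcentrationResponseFit",
    "kw_transform",
    "fit_kitz_wilson",
    "fit_ic50",
    "predict_concentration_response",
]

KWMethod = Literal["reciprocal", "nonlinear"]


@dataclass(frozen=True)
class KitzWilsonFit:
    """Result of a Kitz-Wilson fit.

    slope/intercept are the double-reciprocal regression coefficients
    (K_I/k_inact in uM min, and 1/k_inact in min); for the reciprocal
    method they determine params exactly.
    """

    params: InactivationParams
    slope: float
    intercept: float
    r_squared: float
    method: KWMethod
    n_points: int
    saturation_detected: bool = True


@dataclass(frozen=True)
class ConcentrationResponseFit:
    """Log-linear concentration-response fit and its IC50 (uM)."""

    ic50: float
    slope: float  # % inhibition per log10(concentration) unit
    intercept: float
    r_squared: float
    n_points: int
    extrapolated: bool


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def kw_transform(
    observations: Sequence[InactivationObservation],
) -> list[tuple[float, float, bool]]:
    """Map each observation to (I, y, flagged) with y = ln(E0/Et)/t.

    Observations with Et >= E0 give y <= 0; they are retained but flagged
    (the hyperbolic model cannot produce them, so fits exclude them).
    Et = 0 would give infinite y and is rejected.
    """
    points: list[tuple[float, float, bool]] = []
    for i, obs in enumerate(observations):
        if obs.Et == 0:
            raise ValueError(
                f"observation {i} (I={obs.I}) has Et=0: ln(E0/Et)/t is infinite; "
                "re-measure with shorter pre-incubation"
            )
        y = math.log(obs.E0 / obs.Et) / obs.t
        points.append((obs.I, y, y <= 0))
    return points


def _hyperbola(I: np.ndarray, K_I: float, k_inact: float) -> np.ndarray:
    return k_inact * I / (K_I + I)


def fit_kitz_wilson(
    points: Sequence[tuple[float, float] | tuple[float, float, bool]],
    method: KWMethod = "reciprocal",
) -> KitzWilsonFit:
    """Fit (K_I, k_inact) to (I, kobs) points.

    reciprocal: unweighted OLS of 1/y on 1/I; k_inact = 1/intercept,
    K_I = slope/intercept. nonlinear: least squares on the hyperbola,
    initialized from the reciprocal solution. Points with y <= 0 or I <= 0
    are outside the model and excluded. A non-positive reciprocal
    intercept means no saturation is detectable; the fit is returned with
    ``saturation_detected=False`` and NaN parameters.
    """
    used = [(p[0], p[1]) for p in points if p[0] > 0 and p[1] > 0]
    if len(used) < 2:
        raise ValueError("need at least 2 points with I > 0 and y > 0")
    I = np.array([p[0] for p in used])
    y = np.array([p[1] for p in used])
    if np.unique(I).size < 2:
        raise ValueError("all inhibitor concentrations are equal: singular design")

    # reciprocal solution always computed: it is the fit (reciprocal) or the
    # initialization (nonlinear)
    slope, intercept = np.polyfit(1.0 / I, 1.0 / y, 1)
    if intercept <= 0:
        return KitzWilsonFit(
            params=_nan_params(),
            slope=float(slope),
            intercept=float(intercept),
            r_squared=_r_squared(1.0 / y, slope / I + intercept),
            method=method,
            n_points=len(used),
            saturation_detected=False,
        )
    k_inact0 = 1.0 / intercept
    K_I0 = slope / intercept

    if method == "reciprocal":
        r2 = _r_squared(1.0 / y, slope / I + intercept)
        return KitzWilsonFit(
            params=InactivationParams(K_I=float(K_I0), k_inact=float(k_inact0)),
            slope=float(slope),
            intercept=float(intercept),
            r_squared=r2,
            method="reciprocal",
            n_points=len(used),
        )
    if method == "nonlinear":
        popt, _pcov = curve_fit(
            _hyperbola, I, y, p0=[max(K_I0, 1e-9), max(k_inact0, 1e-12)], maxfev=10000
        )
        K_I_hat, k_inact_hat = float(popt[0]), float(popt[1])
        r2 = _r_squared(y, _hyperbola(I, K_I_hat, k_inact_hat))
        return KitzWilsonFit(
            params=InactivationParams(K_I=K_I_hat, k_inact=k_inact_hat),
            slope=K_I_hat / k_inact_hat,
            intercept=1.0 / k_inact_hat,
            r_squared=r2,
            method="nonlinear",
            n_points=len(used),
        )
    raise ValueError(f"unknown method {method!r}")


class _NanParams(InactivationParams):
    """Sentinel for a fit with no detectable saturation."""

    def __init__(self) -> None:
        object.__setattr__(self, "K_I", math.nan)
        object.__setattr__(self, "k_inact", math.nan)


def _nan_params() -> InactivationParams:
    return _NanParams()


def fit_ic50(
    pairs: Sequence[tuple[float, float]],
    window: tuple[float, float] = (10.0, 90.0),
) -> ConcentrationResponseFit:
    """Log-linear IC50 fit on (concentration uM, % inhibition) pairs.

    OLS of % inhibition on log10(I) over points inside the response
    window; IC50 = 10**((50 - intercept)/slope). The used points must
    bracket 50% inhibition — silent extrapolation is refused. Non-monotone
    data are accepted (OLS absorbs them) with the R2 reporting the misfit.
    """
    lo, hi = window
    used = [(c, p) for c, p in pairs if lo <= p <= hi and c > 0]
    if len(used) < 2:
        raise ValueError(f"need at least 2 pairs with inhibition in [{lo}, {hi}]% and I > 0")
    conc = np.array([c for c, _ in used])
    pct = np.array([p for _, p in used])
    if np.unique(conc).size < 2:
        raise ValueError("all concentrations equal: cannot fit a concentration response")
    if not (pct.min() <= 50.0 <= pct.max()):
        raise ValueError(
            f"in-window responses span {pct.min():.1f}-{pct.max():.1f}% and do not "
            "bracket 50%: IC50 would be an extrapolation"
        )
    logc = np.log10(conc)
    slope, intercept = np.polyfit(logc, pct, 1)
    if slope == 0:
        raise ValueError("zero slope: response does not depend on concentration")
    ic50 = 10.0 ** ((50.0 - intercept) / slope)
    r2 = _r_squared(pct, slope * logc + intercept)
    extrapolated = not (conc.min() <= ic50 <= conc.max())
    return ConcentrationResponseFit(
        ic50=float(ic50),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points=len(used),
        extrapolated=extrapolated,
    )


def predict_concentration_response(
    params: InactivationParams,
    t_preinc: float,
    grid: Sequence[float],
    scavenger: ScavengerSpec | None = None,
) -> list[tuple[float, float]]:
    """Mechanism-implied % inhibition after t_preinc minutes at each concentration."""
    if t_preinc <= 0:
        raise ValueError("pre-incubation time must be positive")
    return [
        (I, 100.0 * (1.0 - residual_fraction(params, I, t_preinc, scavenger))) for I in grid
    ]
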
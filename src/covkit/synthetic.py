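"""Seeded generators emulating the statistical structure of each experiment.

Every generator is a pure function of its spec and seed, so fixtures are
bit-reproducible and no data files are needed. A single global seed is
expanded into independent per-generator substreams (via fixed spawn keys),
so adding a generator never perturbs the draws of an existing one.

What is emulated: pre-incubation inactivation series with multiplicative
lognormal activity noise; log-linear concentration-response reads; full
384-well endpoint-screen plate sets (compound libraries with a
non-inhibitor mass and lognormal potency tails, per-well progress curves,
in-plate controls and blanks); and Poisson spectral-count tables for
treated-vs-control pulldowns. What is not: plate edge effects, carryover,
instrument drift, or count saturation — see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    AssayMix,
    InactivationObservation,
    InactivationParams,
    ProgressCurve,
    ScavengerSpec,
    residual_fraction,
    simulate_progress_curve,
)
from .screening import PlateLayout, WellSpec

__all__ = [
    "NoiseSpec",
    "LibrarySpec",
    "gen_inactivation_observations",
    "gen_concentration_response",
    "gen_screen_plates",
    "gen_count_table",
]

# fixed spawn keys: one independent substream per generator
_STREAMS = {"inactivation": 11, "response": 12, "screen": 13, "counts": 14, "library": 15}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: multiplicative lognormal (scale = CV) or
    additive Gaussian (scale = SD), with the seed that makes it reproducible."""

    model: Literal["multiplicative-lognormal", "additive-gaussian"] = "multiplicative-lognormal"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("noise scale must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Perturb values; scale 0 returns them unchanged (rng not consumed)."""
        if self.scale == 0:
            return np.asarray(values, dtype=float)
        values = np.asarray(values, dtype=float)
        if self.model == "multiplicative-lognormal":
            # mean-one lognormal factor with coefficient of variation = scale
            sigma = math.sqrt(math.log1p(self.scale**2))
            factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=values.shape)
            return values * factors
        return values + rng.normal(0.0, self.scale, size=values.shape)


def gen_inactivation_observations(
    params: InactivationParams,
    concentrations: Sequence[float],
    t: float,
    E0: float,
    noise: NoiseSpec,
    scavenger: ScavengerSpec | None = None,
) -> list[InactivationObservation]:
    """Pre-incubation series: Et = E0 * residual_fraction * noise factor."""
    if not concentrations:
        raise ValueError("need at least one concentration")
    rng = _rng(noise.seed, "inactivation")
    residuals = np.array(
        [residual_fraction(params, I, t, scavenger) for I in concentrations]
    )
    et = noise.apply(E0 * residuals, rng)
    return [
        InactivationObservation(I=float(I), E0=float(E0), Et=float(e), t=float(t))
        for I, e in zip(concentrations, et)
    ]


def gen_concentration_response(
    ic50: float,
    slope: float,
    grid: Sequence[float],
    noise: NoiseSpec,
    clip: bool = True,
) -> list[tuple[float, float]]:
    """Log-linear % inhibition reads: 50 + slope*log10(I/IC50) + noise.

    Values are clipped to [0, 100] for reporting realism unless
    ``clip=False``. The grid must span the IC50.
    """
    grid = list(grid)
    if not grid or not (min(grid) <= ic50 <= max(grid)):
        raise ValueError(f"concentration grid must span the IC50 ({ic50} uM)")
    rng = _rng(noise.seed, "response")
    pct = np.array([50.0 + slope * math.log10(I / ic50) for I in grid])
    if noise.scale > 0:
        if noise.model == "additive-gaussian":
            pct = noise.apply(pct, rng)
        else:
            pct = noise.apply(np.clip(pct, 1e-9, None), rng)
    if clip:
        pct = np.clip(pct, 0.0, 100.0)
    return [(float(I), float(p)) for I, p in zip(grid, pct)]


@dataclass(frozen=True)
class LibrarySpec:
    """An electrophile screening library with a weak-potency background.

    Most library electrophiles are far weaker warheads than an optimized
    lead: a ``frac_inactive`` mass has k_inact = 0 and the rest draw
    lognormal (K_I, k_inact) pairs with medians/geometric SDs typical of
    unoptimized thiol-reactive fragments. ``planted`` maps compound ids to
    exact parameters, overriding the draw (used to embed known positives).
    """

    n_compounds: int = 504
    frac_inactive: float = 0.8
    K_I_median_uM: float = 150.0
    K_I_gsd: float = 2.0
    k_inact_median: float = 0.02
    k_inact_gsd: float = 2.5
    planted: Mapping[str, InactivationParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("library must have at least one compound")
        if not 0 <= self.frac_inactive <= 1:
            raise ValueError("frac_inactive must be in [0, 1]")
        object.__setattr__(self, "planted", dict(self.planted))

    def compound_ids(self) -> list[str]:
        width = len(str(self.n_compounds))
        return [f"CMPD-{i + 1:0{width}d}" for i in range(self.n_compounds)]

    def draw_params(self, seed: int) -> dict[str, InactivationParams]:
        """True (K_I, k_inact) per compound; planted entries override."""
        rng = _rng(seed, "library")
        ids = self.compound_ids()
        truth: dict[str, InactivationParams] = {}
        for cid in ids:
            inactive = rng.random() < self.frac_inactive
            K_I = float(
                self.K_I_median_uM * math.exp(rng.normal(0.0, math.log(self.K_I_gsd)))
            )
            k_inact = 0.0 if inactive else float(
                self.k_inact_median * math.exp(rng.normal(0.0, math.log(self.k_inact_gsd)))
            )
            truth[cid] = InactivationParams(K_I=K_I, k_inact=k_inact)
        for cid, params in self.planted.items():
            if cid not in truth:
                raise ValueError(f"planted compound {cid!r} not in library id range")
            truth[cid] = params
        return truth


_ROWS = "ABCDEFGHIJKLMNOP"
_CONTROL_COL, _BLANK_COL = 23, 24
_COMPOUND_COLS = list(range(1, 23))


def _plate_wells() -> list[str]:
    return [f"{r}{c}" for c in _COMPOUND_COLS for r in _ROWS]


def gen_screen_plates(
    library: LibrarySpec,
    noise: NoiseSpec,
    concentrations: Sequence[float] = (40.0, 120.0),
    t_preinc: float = 30.0,
    assay: AssayMix | None = None,
    scavenger: ScavengerSpec | None = None,
    control_activity: float = 0.2,
    well_volume_ml: float = 0.05,
    read_interval: float = 4.0,
    n_reads: int = 6,
) -> tuple[list[tuple[dict[str, ProgressCurve], PlateLayout]], pd.DataFrame]:
    """Simulate a full endpoint screen: plates of progress curves plus truth.

    Each compound is pre-incubated with the enzyme at every concentration
    for ``t_preinc`` minutes; its well's residual activity follows the
    covalent mechanism and is converted into an A340 progress curve read
    every ``read_interval`` minutes. Columns 23/24 of each plate hold
    vehicle controls and no-enzyme blanks. Multiplicative noise perturbs
    well activities; additive noise perturbs individual A340 reads.

    Returns (plates, truth) where plates is a list of (readings, layout)
    pairs and truth is a provenance table with each compound's generated
    parameters and analytic % inhibition per concentration.
    """
    assay = assay or AssayMix()
    rng = _rng(noise.seed, "screen")
    truth_params = library.draw_params(noise.seed)
    duration = read_interval * (n_reads - 1)

    # enumerate compound-concentration pairs and chunk them onto plates
    pairs = [
        (cid, float(conc)) for cid in library.compound_ids() for conc in concentrations
    ]
    wells_per_plate = len(_plate_wells())
    plates: list[tuple[dict[str, ProgressCurve], PlateLayout]] = []
    truth_rows: list[dict] = []

    def make_curve(activity: float) -> ProgressCurve:
        curve = simulate_progress_curve(
            assay, activity, well_volume_ml, duration, n_reads
        )
        if noise.model == "additive-gaussian" and noise.scale > 0:
            a340 = noise.apply(np.asarray(curve.A340), rng)
            return ProgressCurve(curve.times, tuple(a340))
        return curve

    for plate_idx in range(0, len(pairs), wells_per_plate):
        chunk = pairs[plate_idx : plate_idx + wells_per_plate]
        plate_id = f"P{plate_idx // wells_per_plate + 1:02d}"
        wells: dict[str, WellSpec] = {}
        readings: dict[str, ProgressCurve] = {}

        for well, (cid, conc) in zip(_plate_wells(), chunk):
            residual = residual_fraction(truth_params[cid], conc, t_preinc, scavenger)
            activity = control_activity * residual
            if noise.model == "multiplicative-lognormal" and noise.scale > 0:
                activity = float(noise.apply(np.array([activity]), rng)[0])
            wells[well] = WellSpec(role="compound", compound_id=cid, conc_uM=conc)
            readings[well] = make_curve(activity)

        for row in _ROWS:
            ctrl_well, blank_well = f"{row}{_CONTROL_COL}", f"{row}{_BLANK_COL}"
            ctrl_activity = control_activity
            if noise.model == "multiplicative-lognormal" and noise.scale > 0:
                ctrl_activity = float(noise.apply(np.array([ctrl_activity]), rng)[0])
            wells[ctrl_well] = WellSpec(role="control")
            readings[ctrl_well] = make_curve(ctrl_activity)
            wells[blank_well] = WellSpec(role="blank")
            readings[blank_well] = make_curve(0.0)

        plates.append((readings, PlateLayout(plate_id=plate_id, wells=wells)))

    for cid in library.compound_ids():
        row = {
            "compound_id": cid,
            "K_I_uM": truth_params[cid].K_I,
            "k_inact_per_min": truth_params[cid].k_inact,
        }
        for conc in concentrations:
            residual = residual_fraction(truth_params[cid], float(conc), t_preinc, scavenger)
            row[f"true_pct_inh_{conc:g}"] = 100.0 * (1.0 - residual)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return plates, truth


def gen_count_table(
    n_adducted: int,
    n_decoy: int,
    lam_treated: float,
    lam_control: float,
    replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Poisson spectral-count table for a treated-vs-control pulldown.

    Adducted proteins draw treated counts at rate ``lam_treated`` and
    control counts at ``lam_control``; decoys draw both conditions at
    ``lam_control``. Returns (table, truth) with truth a boolean Series
    (indexed by protein id) marking the adducted proteins.
    """
    if lam_treated < 0 or lam_control < 0:
        raise ValueError("Poisson rates must be non-negative")
    rng = _rng(seed, "counts")
    rows = []
    truth = {}
    width = len(str(n_adducted + n_decoy))
    for i in range(n_adducted + n_decoy):
        adducted = i < n_adducted
        pid = f"PROT{i + 1:0{width}d}"
        t_rate = lam_treated if adducted else lam_control
        row = {"protein_id": pid, "description": ("adducted" if adducted else "decoy") + f" protein {i + 1}"}
        for r in range(replicates):
            row[f"t_rep{r + 1}"] = int(rng.poisson(t_rate))
        for r in range(replicates):
            row[f"c_rep{r + 1}"] = int(rng.poisson(lam_control))
        rows.append(row)
        truth[pid] = adducted
    return pd.DataFrame(rows), pd.Series(truth, name="adducted")
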
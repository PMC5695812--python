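"""Endpoint screening of electrophile libraries in 384-well plates.

Each plate carries compound wells (one compound at one nominal
concentration), vehicle-control wells (enzyme, no compound) and no-enzyme
blank wells. Per-well rates come from the slope of the A340 progress
curve; control and blank rates are averaged within each plate (plate-wise
normalization guards against plate effects), and percent inhibition is
computed per compound-concentration. Hit calling ranks compounds by
inhibition at a reference concentration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .kinetics import ProgressCurve, percent_inhibition, rate_from_curve

__all__ = ["WellRole", "WellSpec", "PlateLayout", "ScreenResult", "score_plate", "call_hits"]

WellRole = Literal["compound", "control", "blank"]
ScoreMode = Literal["slope", "endpoint"]

_WELL_RE = re.compile(r"^([A-P])([1-9]|1[0-9]|2[0-4])$")


@dataclass(frozen=True)
class WellSpec:
    role: WellRole
    compound_id: str | None = None
    conc_uM: float | None = None

    def __post_init__(self) -> None:
        if self.role == "compound":
            if self.compound_id is None or self.conc_uM is None:
                raise ValueError("compound wells need compound_id and conc_uM")
            if self.conc_uM <= 0:
                raise ValueError("compound concentration must be positive")


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of well id (A1..P24) to its role on one 384-well plate."""

    plate_id: str
    wells: Mapping[str, WellSpec]

    def __post_init__(self) -> None:
        for well in self.wells:
            if not _WELL_RE.match(well):
                raise ValueError(f"invalid 384-well id: {well!r} (expected A1..P24)")
        roles = {spec.role for spec in self.wells.values()}
        if "control" not in roles:
            raise ValueError(f"plate {self.plate_id}: no vehicle-control well")
        if "blank" not in roles:
            raise ValueError(f"plate {self.plate_id}: no no-enzyme blank well")
        object.__setattr__(self, "wells", dict(self.wells))


@dataclass
class ScreenResult:
    """Per-compound % inhibition keyed by tested concentration, plus ranking."""

    inhibition: dict[str, dict[float, float]]
    ranks: dict[str, int] = field(default_factory=dict)
    hits: dict[str, bool] = field(default_factory=dict)
    reference_conc: float | None = None
    threshold: float | None = None

    def merge(self, other: "ScreenResult") -> "ScreenResult":
        merged = {cid: dict(v) for cid, v in self.inhibition.items()}
        for cid, by_conc in other.inhibition.items():
            merged.setdefault(cid, {}).update(by_conc)
        return ScreenResult(inhibition=merged)


def _well_rate(curve: ProgressCurve, mode: ScoreMode) -> float:
    if mode == "slope":
        return rate_from_curve(curve)
    # endpoint: secant between first and last read
    return (curve.A340[-1] - curve.A340[0]) / (curve.times[-1] - curve.times[0])


def score_plate(
    readings: Mapping[str, ProgressCurve],
    layout: PlateLayout,
    mode: ScoreMode = "slope",
) -> ScreenResult:
    """Score one plate: per-well rates, plate-mean control/blank, % inhibition."""
    missing = [w for w in layout.wells if w not in readings]
    if missing:
        raise ValueError(f"plate {layout.plate_id}: no reading for wells {sorted(missing)}")

    rates = {well: _well_rate(readings[well], mode) for well in layout.wells}
    control_rates = [rates[w] for w, s in layout.wells.items() if s.role == "control"]
    blank_rates = [rates[w] for w, s in layout.wells.items() if s.role == "blank"]
    control = float(np.mean(control_rates))
    blank = float(np.mean(blank_rates))
    if control == blank:
        raise ValueError(
            f"plate {layout.plate_id}: control rate equals blank rate; assay window collapsed"
        )

    inhibition: dict[str, dict[float, float]] = {}
    for well, spec in layout.wells.items():
        if spec.role != "compound":
            continue
        pct = percent_inhibition(rates[well], control, blank)
        by_conc = inhibition.setdefault(spec.compound_id, {})
        if spec.conc_uM in by_conc:
            # replicate wells of the same compound/concentration: average
            by_conc[spec.conc_uM] = (by_conc[spec.conc_uM] + pct) / 2.0
        else:
            by_conc[spec.conc_uM] = pct
    return ScreenResult(inhibition=inhibition)


def score_plates(
    plates: Iterable[tuple[Mapping[str, ProgressCurve], PlateLayout]],
    mode: ScoreMode = "slope",
) -> ScreenResult:
    """Score several plates and merge per-compound results."""
    result = ScreenResult(inhibition={})
    for readings, layout in plates:
        result = result.merge(score_plate(readings, layout, mode))
    return result


def call_hits(
    result: ScreenResult,
    reference_conc: float = 40.0,
    threshold: float = 50.0,
) -> ScreenResult:
    """Rank compounds by inhibition at the reference concentration.

    Descending inhibition at the reference concentration; ties broken by
    inhibition at the highest secondary concentration (descending), then
    compound id. A compound is a hit when its reference-concentration
    inhibition meets the threshold.
    """
    missing = [cid for cid, by_conc in result.inhibition.items() if reference_conc not in by_conc]
    if missing:
        raise ValueError(
            f"{len(missing)} compounds lack a reading at the reference concentration "
            f"{reference_conc} uM (e.g. {sorted(missing)[:3]})"
        )

    def sort_key(cid: str) -> tuple[float, float, str]:
        by_conc = result.inhibition[cid]
        secondary_concs = sorted((c for c in by_conc if c != reference_conc), reverse=True)
        secondary = by_conc[secondary_concs[0]] if secondary_concs else float("-inf")
        return (-by_conc[reference_conc], -secondary, cid)

    ordered = sorted(result.inhibition, key=sort_key)
    ranks = {cid: i + 1 for i, cid in enumerate(ordered)}
    hits = {cid: result.inhibition[cid][reference_conc] >= threshold for cid in ordered}
    return ScreenResult(
        inhibition=result.inhibition,
        ranks=ranks,
        hits=hits,
        reference_conc=reference_conc,
        threshold=threshold,
    )
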
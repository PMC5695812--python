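"""Spectral-count post-processing for covalent-probe pulldown proteomics.

Input is a protein x replicate table of spectral counts from a
treated-vs-vehicle pulldown experiment (by default 2 biological replicates
per condition), as exported by a database-search/filtering pipeline. The
upstream peptide-spectrum matching and FDR filtering are properties of the
input, not recomputed here; an optional boolean ``fdr_pass`` column is
honored if present.

The analysis is deliberately simple, matching how probe-enrichment
datasets are triaged: keep proteins averaging at least a minimum spectral
count in the treated replicates, compute the treated/control fold change
(with a floor on the control mean so zero-control proteins stay finite and
ordered), rank descending, and flag members of an annotation panel (e.g.
NF-kB pathway proteins) by name match.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PANEL",
    "validate_count_table",
    "filter_min_counts",
    "fold_change_rank",
    "flag_panel",
]

#: inflammatory-target panel: the screen's target enzyme plus NF-kB
#: pathway members found adducted by the probe
DEFAULT_PANEL: tuple[str, ...] = ("glutaredoxin-1", "p100", "p105/p50", "IKKβ", "MyD88")

TREATED_PREFIX = "t_rep"
CONTROL_PREFIX = "c_rep"


def _replicate_cols(table: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"count table has no replicate columns with prefix {prefix!r}")
    return cols


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check invariants and apply the upstream FDR flag if present.

    Requires ``protein_id`` (unique), ``description``, and at least one
    treated (``t_rep*``) and one control (``c_rep*``) column of
    non-negative integer counts. Rows with ``fdr_pass == False`` are
    dropped with a logged count.
    """
    for col in ("protein_id", "description"):
        if col not in table.columns:
            raise ValueError(f"count table missing required column {col!r}")
    dupes = table["protein_id"][table["protein_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate protein ids: {sorted(dupes.unique())[:5]}")
    t_cols = _replicate_cols(table, TREATED_PREFIX)
    c_cols = _replicate_cols(table, CONTROL_PREFIX)
    counts = table[t_cols + c_cols]
    if (counts < 0).any().any():
        raise ValueError("negative spectral counts")
    if not ((counts % 1) == 0).all().all():
        raise ValueError("spectral counts must be integers")
    if "fdr_pass" in table.columns:
        failing = (~table["fdr_pass"].astype(bool)).sum()
        if failing:
            logger.info("dropping %d rows failing the upstream FDR filter", failing)
        table = table[table["fdr_pass"].astype(bool)].drop(columns=["fdr_pass"])
    return table.reset_index(drop=True)


def filter_min_counts(table: pd.DataFrame, min_avg: float = 10.0) -> pd.DataFrame:
    """Keep proteins whose mean treated-replicate count is >= min_avg.

    The boundary is inclusive (an average of exactly min_avg is retained)
    and control counts are not consulted.
    """
    table = validate_count_table(table)
    t_cols = _replicate_cols(table, TREATED_PREFIX)
    keep = table[t_cols].mean(axis=1) >= min_avg
    return table[keep].reset_index(drop=True)


def fold_change_rank(table: pd.DataFrame, control_floor: float = 1.0) -> pd.DataFrame:
    """Rank an already-filtered table by treated/control fold change.

    fold_change = mean(treated) / max(mean(control), control_floor); the
    floor keeps zero-control proteins finite and monotone in their treated
    counts. Sorted by fold change descending, ties broken by treated mean
    descending then protein id, so the output is deterministic. Adds a
    1-based ``rank`` column.
    """
    table = validate_count_table(table)
    t_cols = _replicate_cols(table, TREATED_PREFIX)
    c_cols = _replicate_cols(table, CONTROL_PREFIX)
    out = table.copy()
    out["avg_treated"] = out[t_cols].mean(axis=1)
    out["avg_control"] = out[c_cols].mean(axis=1)
    out["fold_change"] = out["avg_treated"] / out["avg_control"].clip(lower=control_floor)
    out = out.sort_values(
        by=["fold_change", "avg_treated", "protein_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def flag_panel(
    ranked: pd.DataFrame,
    panel: Iterable[str] = DEFAULT_PANEL,
    exact: bool = False,
) -> pd.DataFrame:
    """Flag rows whose id or description matches a panel entry.

    Matching is case-insensitive; by default a panel entry matching as a
    substring of the protein id or description counts, with ``exact=True``
    requiring a full (case-insensitive) match of either field.
    """
    panel_lc = [p.lower() for p in panel]
    out = ranked.copy()

    def matches(row: pd.Series) -> bool:
        fields = [str(row["protein_id"]).lower(), str(row["description"]).lower()]
        if exact:
            return any(f == p for p in panel_lc for f in fields)
        return any(p in f for p in panel_lc for f in fields)

    out["panel_flag"] = out.apply(matches, axis=1) if len(out) else pd.Series(dtype=bool)
    return out


def rank_targets(
    table: pd.DataFrame,
    min_avg: float = 10.0,
    control_floor: float = 1.0,
    panel: Sequence[str] = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Full post-processing chain: filter, fold-change rank, panel flag."""
    return flag_panel(fold_change_rank(filter_min_counts(table, min_avg), control_floor), panel)
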
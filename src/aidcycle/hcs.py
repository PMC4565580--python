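"""Per-cell HCS quantification.

Takes per-cell feature tables (compartment areas and total intensities plus
total DAPI) and produces gated, phase-labelled, bleed-corrected per-cell
quantities and grouped population summaries:

* compartment average signals (total intensity / area) and the N/C ratio;
* two-sided signal gating — a low gate at a quantile of the mock-transduction
  control and a high gate at mean + 5 SD of the surviving population;
* cell-cycle phase assignment by DNA-content rank: cells are ranked by total
  DAPI and split into equal-count bins, with the bottom bins called G1, a
  middle band S and the top bins G2/M;
* the bleed-through baseline (ordinary least squares of nuclear on
  cytoplasmic average over untreated cells) and the corrected nuclear signal
  obtained by subtracting it;
* per-group (construct, treatment, phase, time) mean / SEM / n summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "GateReport",
    "BaselineFit",
    "compute_compartment_averages",
    "whole_cell_average",
    "gate_population",
    "assign_phase",
    "fit_bleed_baseline",
    "correct_nuclear_signal",
    "summarize_population",
    "PHASE_RANK_WINDOWS",
]

#: Rank-bin windows (1-based, inclusive) assigned to each phase out of 24
#: DNA-content rank bins; bins outside these windows are left unassigned.
PHASE_RANK_WINDOWS = {"G1": (1, 4), "S": (10, 16), "G2M": (21, 24)}


class GatingError(ValueError):
    """A gate removed every cell, or gating inputs are unusable."""


@dataclass(frozen=True)
class GateConfig:
    """Two-sided signal gate parameters.

    The low gate is a quantile of the mock-transduction control's whole-cell
    signal (removing untransduced/dim cells); the high gate removes cells more
    than ``high_sd_multiplier`` SD above the mean of the surviving population.
    ``signal`` selects whether gating operates on the whole-cell average
    intensity (default) or the whole-cell total.
    """

    low_threshold_quantile_of_mock: float = 0.995
    high_sd_multiplier: float = 5.0
    signal: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 < self.low_threshold_quantile_of_mock < 1.0:
            raise ValueError("low_threshold_quantile_of_mock must be in (0, 1)")
        if self.high_sd_multiplier <= 0:
            raise ValueError("high_sd_multiplier must be > 0")
        if self.signal not in ("average", "total"):
            raise ValueError("signal must be 'average' or 'total'")


@dataclass(frozen=True)
class GateReport:
    low_threshold: float
    high_threshold: float
    n_input: int
    n_low_removed: int
    n_high_removed: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_low_removed - self.n_high_removed

    def to_dict(self) -> dict:
        return {
            "low_threshold": self.low_threshold,
            "high_threshold": self.high_threshold,
            "n_input": self.n_input,
            "n_low_removed": self.n_low_removed,
            "n_high_removed": self.n_high_removed,
            "n_kept": self.n_kept,
        }


@dataclass(frozen=True)
class BaselineFit:
    """OLS fit of nuclear on cytoplasmic average signal (untreated cells)."""

    slope: float
    intercept: float
    n_cells: int
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "n_cells": self.n_cells,
            "r_squared": self.r_squared,
        }


def compute_compartment_averages(cells: pd.DataFrame) -> pd.DataFrame:
    """Add ``nuclear_avg``, ``cyto_avg`` and ``nc_ratio`` columns.

    Averages are total intensity divided by compartment area.  Records with a
    non-positive area are invalid: they are excluded and their count logged.
    The N/C ratio is the ratio of the average signals (NaN where the
    cytoplasmic average is zero).
    """
    valid = (cells["nuclear_area"] > 0) & (cells["cyto_area"] > 0)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.warning("excluding %d records with non-positive compartment area", n_invalid)
    out = cells.loc[valid].copy()
    out["nuclear_avg"] = out["nuclear_total"] / out["nuclear_area"]
    out["cyto_avg"] = out["cyto_total"] / out["cyto_area"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["nc_ratio"] = np.where(out["cyto_avg"] > 0, out["nuclear_avg"] / out["cyto_avg"], np.nan)
    return out


def whole_cell_average(cells: pd.DataFrame) -> pd.Series:
    """Whole-cell average mCherry signal: summed totals over whole-cell area."""
    return (cells["nuclear_total"] + cells["cyto_total"]) / cells["cell_area"]


def _gate_signal(cells: pd.DataFrame, cfg: GateConfig) -> pd.Series:
    if cfg.signal == "average":
        return whole_cell_average(cells)
    return cells["nuclear_total"] + cells["cyto_total"]


def gate_population(
    cells: pd.DataFrame, mock_cells: pd.DataFrame, cfg: GateConfig | None = None
) -> tuple[pd.DataFrame, GateReport]:
    """Remove cells with very low or very high signals.

    The low gate is the configured quantile of the mock control's whole-cell
    signal; cells below it are removed first.  The high gate is then
    mean + ``high_sd_multiplier`` x SD of the survivors' whole-cell signal.
    Raises :class:`GatingError`, naming the offending gate, if either gate
    empties the population.
    """
    cfg = cfg or GateConfig()
    if len(mock_cells) == 0:
        raise GatingError("mock control population is empty")
    low = float(_gate_signal(mock_cells, cfg).quantile(cfg.low_threshold_quantile_of_mock))
    signal = _gate_signal(cells, cfg)
    above_low = signal >= low
    survivors = cells.loc[above_low]
    if len(survivors) == 0:
        raise GatingError(f"low gate at {low:.4g} removed every cell")
    surv_signal = signal.loc[above_low]
    high = float(surv_signal.mean() + cfg.high_sd_multiplier * surv_signal.std(ddof=1))
    kept = survivors.loc[surv_signal <= high]
    if len(kept) == 0:
        raise GatingError(f"high gate at {high:.4g} removed every cell")
    report = GateReport(
        low_threshold=low,
        high_threshold=high,
        n_input=len(cells),
        n_low_removed=int((~above_low).sum()),
        n_high_removed=len(survivors) - len(kept),
    )
    return kept.copy(), report


def assign_phase(cells: pd.DataFrame, n_bins: int = 24) -> pd.DataFrame:
    """Assign cell-cycle phase by DNA-content rank.

    Cells are sorted by ``dapi_total`` (ties broken by ``cell_id`` for
    determinism) and split into ``n_bins`` equal-count rank bins.  With the
    default 24 bins, bins 1-4 are G1, 10-16 S and 21-24 G2/M; other bins get
    the label ``"unassigned"`` and are excluded from phase-resolved analyses.
    For other bin counts the same rank windows are scaled proportionally.
    """
    if len(cells) < n_bins:
        raise ValueError(f"need at least {n_bins} cells to form {n_bins} rank bins, got {len(cells)}")
    order = cells.sort_values(["dapi_total", "cell_id"], kind="stable").index
    ranks = pd.Series(np.arange(len(order)), index=order)  # 0-based rank
    bin_of = (ranks * n_bins) // len(order) + 1  # 1-based bin
    phase = pd.Series("unassigned", index=cells.index, dtype=object)
    for name, (lo, hi) in PHASE_RANK_WINDOWS.items():
        if n_bins != 24:
            lo = math.floor((lo - 1) * n_bins / 24) + 1
            hi = math.ceil(hi * n_bins / 24)
        phase.loc[bin_of[(bin_of >= lo) & (bin_of <= hi)].index] = name
    out = cells.copy()
    out["phase"] = phase
    return out


def fit_bleed_baseline(untreated_cells: pd.DataFrame, min_cells: int = 10) -> BaselineFit:
    """OLS regression of nuclear average on cytoplasmic average signal.

    Fit over gated untreated cells only; the resulting line is the per-cell
    baseline of apparent nuclear signal contributed by out-of-focus
    cytoplasmic fluorescence.
    """
    if "nuclear_avg" not in untreated_cells or "cyto_avg" not in untreated_cells:
        raise ValueError("run compute_compartment_averages first (nuclear_avg/cyto_avg missing)")
    n = len(untreated_cells)
    if n < min_cells:
        raise ValueError(f"need >= {min_cells} untreated cells for the baseline fit, got {n}")
    x = untreated_cells["cyto_avg"].to_numpy(dtype=float)
    y = untreated_cells["nuclear_avg"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: cytoplasmic average is constant")
    res = stats.linregress(x, y)
    return BaselineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_cells=n,
        r_squared=float(res.rvalue**2),
    )


def correct_nuclear_signal(cells: pd.DataFrame, fit: BaselineFit) -> pd.DataFrame:
    """Subtract the fitted cytoplasmic bleed-through baseline.

    corrected = nuclear_avg - (slope * cyto_avg + intercept).  Negative
    corrected values are retained (clipping would bias population means) and
    flagged in the boolean ``corrected_negative`` column.
    """
    out = cells.copy()
    out["nuclear_avg_corrected"] = out["nuclear_avg"] - (fit.slope * out["cyto_avg"] + fit.intercept)
    out["corrected_negative"] = out["nuclear_avg_corrected"] < 0
    return out


def summarize_population(
    cells: pd.DataFrame,
    value: str = "nuclear_avg",
    by: tuple = ("construct", "treatment", "phase", "time_hr"),
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Grouped mean, SEM and n of a per-cell value.

    SEM is sd/sqrt(n) with ddof=1; single-cell groups report SEM 0 (flagged by
    n == 1).  Phase-unassigned cells are dropped when grouping by phase unless
    ``include_unassigned``.  Empty input raises; empty groups simply do not
    appear.
    """
    if len(cells) == 0:
        raise ValueError("no cells to summarize")
    data = cells
    if "phase" in by and not include_unassigned and "phase" in cells:
        data = cells[cells["phase"] != "unassigned"]
    grouped = data.groupby(list(by), observed=True)[value]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = np.where(out["n"] > 1, out["sd"] / np.sqrt(out["n"]), 0.0)
    return out.drop(columns="sd")
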
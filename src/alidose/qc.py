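"""Control charting and dispersion statistics for the in-process controls.

Two plate-level controls are tracked across assay days: the incubator
negative control (cells never exposed) and the medium blank (reagents, no
cells).  Per-day means go on a Shewhart-style individuals chart with limits
at the grand mean +/- 3 sd of the per-day means; per-day coefficients of
variation (COV = 100 sd/mean across that day's wells) summarize pipetting
repeatability.  The positive control (detergent-killed cells) must be
statistically indistinguishable from the blank for the assay's dynamic range
to count as fully exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import HierarchicalConsensus

__all__ = [
    "ControlChart",
    "control_chart_series",
    "cov_series",
    "dynamic_range_check",
    "blank_fraction",
]


@dataclass
class ControlChart:
    points: pd.DataFrame  # date, mean, cov, n_wells, out_of_control
    center_line: float
    lower_limit: float
    upper_limit: float


def _daily_stats(readings: pd.DataFrame, value_col: str) -> pd.DataFrame:
    stats = (
        readings.groupby("date", as_index=False)
        .agg(mean=(value_col, "mean"), sd=(value_col, lambda s: s.std(ddof=1)), n_wells=(value_col, "size"))
    )
    stats["cov"] = np.where(stats["mean"] != 0, 100.0 * stats["sd"] / stats["mean"], np.nan)
    return stats


def control_chart_series(readings: pd.DataFrame, value_col: str = "abs450") -> ControlChart:
    """Individuals chart of per-date control means with +/- 3 sd limits.

    ``readings`` holds one control type's wells with columns ``date`` and
    ``value_col``; at least two distinct dates are required.
    """
    if "date" not in readings.columns or value_col not in readings.columns:
        raise ValueError(f"readings need 'date' and {value_col!r} columns")
    stats = _daily_stats(readings, value_col)
    if len(stats) < 2:
        raise ValueError("control charting needs at least 2 dates")
    center = float(stats["mean"].mean())
    spread = float(stats["mean"].std(ddof=1))
    lower, upper = center - 3.0 * spread, center + 3.0 * spread
    stats["out_of_control"] = (stats["mean"] < lower) | (stats["mean"] > upper)
    return ControlChart(points=stats, center_line=center, lower_limit=lower, upper_limit=upper)


def cov_series(readings: pd.DataFrame, value_col: str = "abs450") -> tuple[pd.DataFrame, float]:
    """Per-date COV (%) across wells and the mean COV over dates.

    Dates with fewer than two wells or a zero mean yield a missing COV and
    are excluded from the mean.
    """
    if "date" not in readings.columns or value_col not in readings.columns:
        raise ValueError(f"readings need 'date' and {value_col!r} columns")
    stats = _daily_stats(readings, value_col)
    stats.loc[stats["n_wells"] < 2, "cov"] = np.nan
    mean_cov = float(stats["cov"].mean(skipna=True))
    return stats[["date", "cov", "n_wells"]], mean_cov


def dynamic_range_check(
    viability_records: pd.DataFrame,
    positive_condition: str = "positive_control",
    blank_condition: str = "medium_blank",
    **consensus_params,
) -> tuple[bool, dict[str, tuple[float, float]]]:
    """Does the positive control reach the bottom of the assay range?

    ``viability_records`` must contain the detergent-killed positive-control
    inserts and the blank wells expressed on the same viability scale (blank
    wells normalized like any test well scatter around 0%).  Both are fitted
    with the consensus model and the check passes when the pairwise-equality
    call holds, i.e. the 95% interval of the consensus difference contains 0
    -- the killed cells are statistically indistinguishable from the blank.
    Returns the pass flag and each condition's consensus 95% bounds.
    """
    present = set(viability_records["condition"].unique())
    if positive_condition not in present:
        raise ValueError(f"no {positive_condition!r} records")
    if blank_condition not in present:
        raise ValueError(f"no {blank_condition!r} records on the viability scale")
    sub = viability_records[
        viability_records["condition"].isin([positive_condition, blank_condition])
    ]
    params = {"n_chains": 2, "n_iterations": 2000, **consensus_params}
    model = HierarchicalConsensus(**params).fit(sub)
    calls = {c.condition: c for c in model.significance_calls()}
    key = tuple(sorted([positive_condition, blank_condition]))
    passes = calls[positive_condition].pairwise_equality[key]
    bounds = {c: model.summaries_[c].consensus_bounds for c in (positive_condition, blank_condition)}
    return bool(passes), bounds


def blank_fraction(blank_mean: float, control_mean: float) -> float:
    """Medium-blank absorbance as % of the incubator-control absorbance."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * blank_mean / control_mean
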
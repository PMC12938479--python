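"""Salt-concentration trend statistics over replica summaries.

Each metric is regressed against NaCl concentration with one point per
replica (9 concentrations x 7 replicas = 63 points in the reference study
design), not per condition mean: the study's printed (r, p) pairs are
mutually consistent only with n near 63 under the standard t-test.  The
two-sided p-value uses the exact t reference distribution with n - 2 degrees
of freedom; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ReplicaSummary, summaries_to_frame

__all__ = [
    "TrendResult", "pearson_with_p", "p_from_r", "linear_fit",
    "trend_report", "evaluate_fit_at", "trend_table", "scatter_table",
    "nm_per_mM_to_pm_per_mM", "fraction_per_mM_to_pct_per_mM",
]

METRIC_COLUMNS = {
    "mean_rmsd": "mean_rmsd_nm",
    "mean_min_distance": "mean_min_distance_nm",
    "adsorption_time_ratio": "adsorption_time_ratio",
}


def nm_per_mM_to_pm_per_mM(slope: float) -> float:
    return slope * 1000.0


def fraction_per_mM_to_pct_per_mM(slope: float) -> float:
    return slope * 100.0


def _display(metric_name: str, slope: float) -> tuple[float, str]:
    if "ratio" in metric_name:
        return fraction_per_mM_to_pct_per_mM(slope), "%/mM"
    return nm_per_mM_to_pm_per_mM(slope), "pm/mM"


@dataclass
class TrendResult:
    metric_name: str
    slope: float          # metric base units (nm or fraction) per mM
    intercept: float      # metric base units
    pearson_r: float
    p_two_sided: float
    n_points: int
    n_dropped: int = 0
    peptide_id: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")

    @property
    def slope_display(self) -> float:
        return _display(self.metric_name, self.slope)[0]

    @property
    def slope_display_units(self) -> str:
        return _display(self.metric_name, self.slope)[1]


def p_from_r(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r under the t(n-2) null."""
    if n < 3:
        raise ValueError("need n >= 3 for a defined p-value")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with exact-t two-sided p; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(n)


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary least squares y = slope * x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points for a line")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def trend_report(summaries: Iterable[ReplicaSummary], metric_name: str,
                 level: Literal["replica", "condition"] = "replica",
                 ) -> TrendResult:
    """Concentration trend of one metric; one point per replica by default."""
    if metric_name not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric_name!r}; "
                         f"choose from {sorted(METRIC_COLUMNS)}")
    df = summaries_to_frame(list(summaries))
    if df.empty:
        raise ValueError("no replica summaries given")
    peptides = df["peptide_id"].unique()
    if len(peptides) > 1:
        raise ValueError("trend_report expects summaries of a single peptide")
    col = METRIC_COLUMNS[metric_name]
    if level == "condition":
        df = (df.groupby("nacl_mM", as_index=False)[col].mean()
              .assign(replica=0, peptide_id=peptides[0]))
    keep = df[col].notna()
    n_dropped = int((~keep).sum())
    df = df[keep]
    if df["nacl_mM"].nunique() < 3:
        raise ValueError("need >= 3 distinct concentrations for a trend")
    x = df["nacl_mM"].to_numpy()
    y = df[col].to_numpy()
    r, p, n = pearson_with_p(x, y)
    slope, intercept = linear_fit(x, y)
    return TrendResult(metric_name=metric_name, slope=slope,
                       intercept=intercept, pearson_r=r, p_two_sided=p,
                       n_points=n, n_dropped=n_dropped,
                       peptide_id=str(peptides[0]))


def evaluate_fit_at(result: TrendResult, concentration_mM: float) -> float:
    """Predicted metric change from 0 mM, in base units (nm or fraction)."""
    return result.slope * concentration_mM


def trend_table(results: Iterable[TrendResult]) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric_name,
            "peptide_id": r.peptide_id,
            "slope": r.slope,
            "slope_display": r.slope_display,
            "slope_display_units": r.slope_display_units,
            "intercept": r.intercept,
            "pearson_r": r.pearson_r,
            "p_two_sided": r.p_two_sided,
            "n_points": r.n_points,
            "n_dropped": r.n_dropped,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def scatter_table(summaries: Iterable[ReplicaSummary],
                  metric_name: str) -> pd.DataFrame:
    """Per-replica scatter points plus condition mean/SD, for plotting."""
    col = METRIC_COLUMNS[metric_name]
    df = summaries_to_frame(list(summaries))[["peptide_id", "nacl_mM",
                                              "replica", col]]
    df = df.rename(columns={col: "replica_value"})
    grp = df.groupby(["peptide_id", "nacl_mM"])["replica_value"]
    df["condition_mean"] = grp.transform("mean")
    df["condition_sd"] = grp.transform("std")
    df.insert(0, "metric", metric_name)
    return df


def write_trend_table(results: Iterable[TrendResult],
                      path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trend_table(results).to_csv(path, index=False, float_format="%.17g")
    return path
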
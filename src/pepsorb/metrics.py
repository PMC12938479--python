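"""Per-replica scalar adsorption metrics.

Three scalars per replica, following the study's conventions:

* mean backbone RMSD over frames with the peptide within 1 nm of the surface
  (the surface gate, so conformational stability is not confounded with bulk
  diffusion),
* mean whole-peptide minimum surface distance over the same gated frames,
* adsorption time ratio — the fraction of frames with the minimum distance
  below 0.3 nm.

Gating uses ``d <= gate`` and adsorption uses strict ``d < cutoff``; boundary
frames are measure-zero but the convention is fixed for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .series import DistanceSeries

__all__ = [
    "MetricsConfig", "ReplicaSummary", "gate_frames", "mean_min_distance",
    "adsorption_time_ratio", "mean_gated_rmsd", "summarize_replica",
    "summaries_to_frame", "write_replica_summaries",
]

RatioConvention = Literal["adsorbed_over_total", "adsorbed_over_nonadsorbed"]


@dataclass(frozen=True)
class MetricsConfig:
    gate_distance: float = 1.0        # nm
    adsorption_cutoff: float = 0.3    # nm
    ratio_convention: RatioConvention = "adsorbed_over_total"
    gate_mean_distance: bool = True   # apply the 1 nm gate to mean distance

    def __post_init__(self) -> None:
        if not 0.0 < self.adsorption_cutoff < self.gate_distance:
            raise ValueError("need 0 < adsorption_cutoff < gate_distance")


@dataclass
class ReplicaSummary:
    """One row of the replica-level summary table (NaN = undefined/missing)."""

    peptide_id: str
    nacl_mM: float
    replica: int
    mean_rmsd: float
    mean_min_distance: float
    adsorption_time_ratio: float
    n_frames_total: int
    n_frames_gated: int


def gate_frames(series: DistanceSeries, gate_distance: float) -> DistanceSeries:
    """Frames with d_min <= gate_distance, order and columns preserved.

    An all-excluded result is returned as an empty series (``is_empty``);
    downstream averages over it are reported as missing, not raised.
    """
    return series.subset(series.d_min <= gate_distance)


def mean_min_distance(series: DistanceSeries,
                      cfg: MetricsConfig = MetricsConfig()) -> float:
    gated = gate_frames(series, cfg.gate_distance) \
        if cfg.gate_mean_distance else series
    if gated.is_empty:
        warnings.warn("no frames within the surface gate; "
                      "mean minimum distance undefined", stacklevel=2)
        return float("nan")
    return float(gated.d_min.mean())


def adsorption_time_ratio(series: DistanceSeries,
                          cfg: MetricsConfig = MetricsConfig()) -> float:
    """Fraction of time adsorbed (d_min < cutoff), per the chosen convention."""
    if series.is_empty:
        warnings.warn("empty series; adsorption time ratio undefined",
                      stacklevel=2)
        return float("nan")
    adsorbed = int(np.sum(series.d_min < cfg.adsorption_cutoff))
    if cfg.ratio_convention == "adsorbed_over_total":
        return adsorbed / series.n_frames
    n_non = series.n_frames - adsorbed
    if n_non == 0:
        warnings.warn("no non-adsorbed frames; ratio undefined under "
                      "adsorbed_over_nonadsorbed", stacklevel=2)
        return float("nan")
    return adsorbed / n_non


def mean_gated_rmsd(series: DistanceSeries,
                    cfg: MetricsConfig = MetricsConfig()) -> float:
    if series.rmsd is None:
        raise ValueError("series carries no RMSD column")
    gated = gate_frames(series, cfg.gate_distance)
    if gated.is_empty:
        warnings.warn("no frames within the surface gate; "
                      "mean RMSD undefined", stacklevel=2)
        return float("nan")
    return float(gated.rmsd.mean())


def summarize_replica(series: DistanceSeries,
                      cfg: MetricsConfig = MetricsConfig()) -> ReplicaSummary:
    gated = gate_frames(series, cfg.gate_distance)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rmsd = mean_gated_rmsd(series, cfg) if series.rmsd is not None \
            else float("nan")
        dist = mean_min_distance(series, cfg)
        ratio = adsorption_time_ratio(series, cfg)
    return ReplicaSummary(
        peptide_id=series.condition.peptide_id,
        nacl_mM=series.condition.nacl_mM,
        replica=series.condition.replica,
        mean_rmsd=rmsd,
        mean_min_distance=dist,
        adsorption_time_ratio=ratio,
        n_frames_total=series.n_frames,
        n_frames_gated=gated.n_frames,
    )


def summaries_to_frame(summaries: Iterable[ReplicaSummary]) -> pd.DataFrame:
    rows = [
        {
            "peptide_id": s.peptide_id,
            "nacl_mM": s.nacl_mM,
            "replica": s.replica,
            "mean_rmsd_nm": s.mean_rmsd,
            "mean_min_distance_nm": s.mean_min_distance,
            "adsorption_time_ratio": s.adsorption_time_ratio,
            "n_frames_total": s.n_frames_total,
            "n_frames_gated": s.n_frames_gated,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def write_replica_summaries(summaries: Iterable[ReplicaSummary],
                            path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summaries_to_frame(summaries).to_csv(path, index=False,
                                         float_format="%.17g")
    return path
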
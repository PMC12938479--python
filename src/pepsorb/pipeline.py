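"""Config-driven orchestration of the full analysis.

``run_study`` executes simulate/extract -> per-replica metrics -> state
classification -> microstate tables -> concentration trends and persists a
report bundle: tidy CSV tables, publication-layout rendered tables, and JSON
diagnostics.  Identical config + seed reproduce the bundle byte for byte
(no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import MetricsConfig, ReplicaSummary, summarize_replica, \
    summaries_to_frame
from .series import DistanceSeries, read_study_dir
from .states import MicrostateTable, StateThresholds, TwoGaussianFit, \
    compare_conditions, derive_thresholds, fit_two_gaussian_layers, \
    labels_for_series, microstate_table, residue_distance_histogram, \
    write_fit_diagnostics
from .synthetic import SyntheticStudySpec, generate_study
from .trends import TrendResult, scatter_table, trend_report, trend_table

__all__ = ["StudyConfig", "ReportBundle", "run_study", "render_tables",
           "simulate_stage", "analyze_stage"]

_FLOAT_FMT = "%.17g"


class StageError(RuntimeError):
    """Failure of one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Everything needed to reproduce one report bundle."""

    mode: str = "simulate"                    # "simulate" | "extract"
    peptides: Sequence[str] = ("KRSR", "RGD")
    concentrations: Sequence[float] = (1, 25, 50, 75, 100, 125, 150, 175, 200)
    replicas: int = 7
    duration_ns: float = 50.0
    frame_interval_ps: float = 10.0
    seed: int = 0
    gate_nm: float = 1.0
    cutoff_nm: float = 0.3
    ratio_convention: str = "adsorbed_over_total"
    bin_width_nm: float = 0.01
    hist_range_nm: tuple[float, float] = (0.0, 1.0)
    fit_range_nm: tuple[float, float] = (0.0, 0.5)
    sn_boundary_nm: float = 0.5
    filter_threshold: float = 0.01
    comparison_filter_threshold: float = 0.02
    trend_level: str = "replica"              # "replica" | "condition"
    series_dir: str | None = None             # extract mode: existing series
    out_dir: str = "pepsorb_out"

    def __post_init__(self) -> None:
        if self.mode not in {"simulate", "extract"}:
            raise ValueError("mode must be 'simulate' or 'extract'")
        if self.mode == "extract" and not self.series_dir:
            raise ValueError("extract mode requires series_dir")
        self.peptides = [str(p).upper() for p in self.peptides]
        self.concentrations = [float(c) for c in self.concentrations]
        self.hist_range_nm = tuple(self.hist_range_nm)
        self.fit_range_nm = tuple(self.fit_range_nm)

    @property
    def metrics_config(self) -> MetricsConfig:
        return MetricsConfig(gate_distance=self.gate_nm,
                             adsorption_cutoff=self.cutoff_nm,
                             ratio_convention=self.ratio_convention)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_canonical_json(self) -> str:
        """Canonical form of the scientific configuration; output locations
        (out_dir, series_dir) are excluded so that the same study written to
        two places hashes identically."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("series_dir", None)
        d["peptides"] = list(self.peptides)
        d["concentrations"] = list(self.concentrations)
        d["hist_range_nm"] = list(self.hist_range_nm)
        d["fit_range_nm"] = list(self.fit_range_nm)
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()


@dataclass
class ReportBundle:
    config: StudyConfig
    summaries: list[ReplicaSummary]
    trends: list[TrendResult]
    fits: dict[str, TwoGaussianFit]
    thresholds: dict[str, StateThresholds]
    microstates: dict[tuple[str, str], MicrostateTable]   # (peptide, tag)
    comparisons: dict[str, pd.DataFrame]                  # peptide -> table
    out_dir: Path
    metadata: dict = field(default_factory=dict)

    def checksums(self) -> dict[str, str]:
        """SHA-256 of every persisted artifact, for determinism checks."""
        out = {}
        for p in sorted(self.out_dir.rglob("*")):
            if p.is_file():
                out[str(p.relative_to(self.out_dir))] = \
                    hashlib.sha256(p.read_bytes()).hexdigest()
        return out


# ------------------------------------------------------------------ stages

def simulate_stage(config: StudyConfig,
                   series_dir: Path | None = None) -> list[DistanceSeries]:
    """Generate the synthetic series for every configured peptide."""
    all_series: list[DistanceSeries] = []
    for pep in config.peptides:
        try:
            spec = SyntheticStudySpec.for_peptide(
                pep,
                concentrations=config.concentrations,
                replicas=config.replicas,
                duration_ns=config.duration_ns,
                frame_interval_ps=config.frame_interval_ps,
                master_seed=config.seed,
            )
        except KeyError as exc:
            raise StageError("simulate", f"unknown peptide {pep!r}") from exc
        series, _ = generate_study(spec, out_dir=series_dir)
        all_series.extend(series)
    return all_series


def _per_peptide(series: Sequence[DistanceSeries], pep: str) \
        -> list[DistanceSeries]:
    return [s for s in series if s.condition.peptide_id == pep]


def analyze_stage(config: StudyConfig, series: Sequence[DistanceSeries],
                  out_dir: Path) -> ReportBundle:
    """Metrics -> states -> trends over an in-memory series collection."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.metrics_config

    # ---- replica metrics
    summaries = [summarize_replica(s, cfg) for s in series]
    summaries_to_frame(summaries).to_csv(
        out_dir / "replica_summary.csv", index=False, float_format=_FLOAT_FMT)

    fits: dict[str, TwoGaussianFit] = {}
    thresholds: dict[str, StateThresholds] = {}
    micro: dict[tuple[str, str], MicrostateTable] = {}
    comparisons: dict[str, pd.DataFrame] = {}
    trend_results: list[TrendResult] = []

    for pep in config.peptides:
        pep_series = _per_peptide(series, pep)
        if not pep_series:
            raise StageError("states", f"no series found for peptide {pep}")
        residue_names = pep_series[0].residue_names

        # ---- state thresholds from the pooled histogram (one fit per peptide)
        hist = residue_distance_histogram(
            pep_series, bin_width=config.bin_width_nm,
            hist_range=config.hist_range_nm,
            pooling=f"{pep}: all residues/replicas/conditions")
        fit = fit_two_gaussian_layers(hist, fit_range=config.fit_range_nm)
        thr = derive_thresholds(fit, sn_boundary=config.sn_boundary_nm)
        fits[pep], thresholds[pep] = fit, thr
        write_fit_diagnostics(fit, thr, out_dir / f"fit_{pep}.json")

        # ---- microstate tables: pooled plus one per condition
        labels_all = labels_for_series(pep_series, thr)
        micro[(pep, "pooled")] = microstate_table(
            labels_all, config.filter_threshold, pep, residue_names)
        for c in config.concentrations:
            cond = [s for s in pep_series if s.condition.nacl_mM == c]
            micro[(pep, f"{c:g}mM")] = microstate_table(
                labels_for_series(cond, thr), config.filter_threshold,
                pep, residue_names)
        low, high = min(config.concentrations), max(config.concentrations)
        comp_low = micro[(pep, f"{low:g}mM")]
        comp_high = micro[(pep, f"{high:g}mM")]
        comparisons[pep] = compare_conditions(comp_low, comp_high)
        comparisons[pep].to_csv(out_dir / f"comparison_{pep}.csv",
                                index=False, float_format=_FLOAT_FMT)
        for tag in ("pooled", f"{low:g}mM", f"{high:g}mM"):
            _microstate_csv(micro[(pep, tag)],
                            out_dir / f"microstates_{pep}_{tag}.csv")

        # ---- trends
        pep_summaries = [s for s in summaries if s.peptide_id == pep]
        for metric in ("mean_rmsd", "mean_min_distance",
                       "adsorption_time_ratio"):
            try:
                trend_results.append(trend_report(
                    pep_summaries, metric, level=config.trend_level))
            except ValueError as exc:
                raise StageError("trends", f"{pep}/{metric}: {exc}") from exc
            scatter_table(pep_summaries, metric).to_csv(
                out_dir / f"scatter_{pep}_{metric}.csv", index=False,
                float_format=_FLOAT_FMT)

    trend_table(trend_results).to_csv(out_dir / "trends.csv", index=False,
                                      float_format=_FLOAT_FMT)
    metadata = {
        "pepsorb_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.to_canonical_json()),
        "n_series": len(series),
        "frame_counts": {
            "total": int(sum(s.n_frames_total for s in summaries)),
            "gated": int(sum(s.n_frames_gated for s in summaries)),
        },
    }
    (out_dir / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True))
    return ReportBundle(config=config, summaries=summaries,
                        trends=trend_results, fits=fits, thresholds=thresholds,
                        microstates=micro, comparisons=comparisons,
                        out_dir=out_dir, metadata=metadata)


def _microstate_csv(table: MicrostateTable, path: Path) -> None:
    df = pd.DataFrame({
        "microstate": list(table.microstates),
        "fraction": list(table.microstates.values()),
    })
    df["retained"] = df["fraction"] > table.filter_threshold
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_study(config: StudyConfig) -> ReportBundle:
    """Full pipeline: (simulate | read) -> analyze -> render."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.mode == "simulate":
        series = simulate_stage(config, series_dir=out_dir / "series")
    else:
        try:
            series = read_study_dir(config.series_dir)
        except (FileNotFoundError, ValueError) as exc:
            raise StageError("extract", str(exc)) from exc
    bundle = analyze_stage(config, series, out_dir)
    render_tables(bundle)
    return bundle


# ------------------------------------------------------------------ rendering

def render_tables(bundle: ReportBundle) -> list[Path]:
    """Write publication-layout tables: residue rows, one column per microstate,
    a closing rate row (percent, two decimals)."""
    missing = [k for k in ("microstates", "comparisons")
               if not getattr(bundle, k)]
    if missing:
        raise StageError("report", f"incomplete bundle, missing: {missing}")
    written = []
    table_dir = bundle.out_dir / "tables"
    table_dir.mkdir(parents=True, exist_ok=True)
    for (pep, tag), table in bundle.microstates.items():
        path = table_dir / f"table_{pep}_{tag}.csv"
        _render_one(table, path)
        written.append(path)
    for pep, comp in bundle.comparisons.items():
        table = bundle.microstates[(pep, "pooled")]
        path = table_dir / f"table_{pep}_comparison.csv"
        _render_comparison(comp, table, path,
                           bundle.config.comparison_filter_threshold)
        written.append(path)
    return written


def _residue_labels(table: MicrostateTable) -> list[str]:
    return list(table.residue_names) or \
        [f"res{i + 1}" for i in range(table.string_length)]


def _render_one(table: MicrostateTable, path: Path) -> None:
    states = list(table.filtered)
    rows = []
    for i, res in enumerate(_residue_labels(table)):
        rows.append([res] + [s[i] for s in states])
    rows.append(["Rates (%)"] + [f"{100 * table.filtered[s]:.2f}"
                                 for s in states])
    header = ["Residue"] + [f"state_{j + 1}" for j in range(len(states))]
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


def _render_comparison(comp: pd.DataFrame, table: MicrostateTable,
                       path: Path, filter_threshold: float) -> None:
    keep = comp[(comp["rate_low"] > filter_threshold)
                | (comp["rate_high"] > filter_threshold)]
    states = keep["microstate"].tolist()
    rows = []
    for i, res in enumerate(_residue_labels(table)):
        rows.append([res] + [s[i] for s in states])
    rows.append(["Rates (% low)"] + [f"{100 * v:.2f}"
                                     for v in keep["rate_low"]])
    rows.append(["Rates (% high)"] + [f"{100 * v:.2f}"
                                      for v in keep["rate_high"]])
    rows.append(["Delta (pp)"] + [f"{100 * v:.2f}" for v in keep["delta"]])
    header = ["Residue"] + [f"state_{j + 1}" for j in range(len(states))]
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)
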
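"""Per-replica distance series and its on-disk format.

A :class:`DistanceSeries` holds, for one production replica under one
(peptide, NaCl concentration) condition, the per-frame whole-peptide minimum
distance to the surface, the per-residue minimum distances, and optionally the
backbone RMSD.  All lengths are nanometres, all times picoseconds.

The on-disk representation is a tidy CSV (one row per frame) with columns
``time_ps, d_min_nm, d_res_<RES><i>_nm ..., rmsd_nm`` plus a sidecar JSON
manifest carrying the condition and provenance.  Floats are written with
``%.17g`` so a write/read round trip is bit exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Condition", "DistanceSeries", "read_series", "read_study_dir"]

_SCHEMA_VERSION = 1
_DMIN_ATOL = 1e-9  # nm; tolerance for the d_min == min(d_res) invariant
_RES_COL = re.compile(r"^d_res_(?P<name>.+?)(?P<idx>\d+)_nm$")


@dataclass(frozen=True)
class Condition:
    """One cell of the study design: which peptide, salt level and replica."""

    peptide_id: str
    nacl_mM: float
    replica: int

    def as_dict(self) -> dict:
        return {
            "peptide_id": self.peptide_id,
            "nacl_mM": float(self.nacl_mM),
            "replica": int(self.replica),
        }


@dataclass
class DistanceSeries:
    """Frame-wise surface distances (and optional RMSD) for one replica.

    Invariants enforced on construction: arrays share the frame count, all
    distances are non-negative, and ``d_min`` equals the row-wise minimum of
    ``d_res`` to within 1e-9 nm.
    """

    condition: Condition
    times: np.ndarray          # ps, shape (n,)
    d_min: np.ndarray          # nm, shape (n,)
    d_res: np.ndarray          # nm, shape (n, n_residues)
    residue_names: Sequence[str]
    rmsd: np.ndarray | None = None   # nm, shape (n,), optional
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d_min = np.asarray(self.d_min, dtype=float)
        self.d_res = np.asarray(self.d_res, dtype=float)
        if self.d_res.ndim != 2:
            raise ValueError("d_res must be a (frames, residues) matrix")
        n = self.times.shape[0]
        if self.d_min.shape != (n,) or self.d_res.shape[0] != n:
            raise ValueError("times, d_min and d_res disagree on frame count")
        if self.d_res.shape[1] != len(self.residue_names):
            raise ValueError("d_res column count must match residue_names")
        if self.rmsd is not None:
            self.rmsd = np.asarray(self.rmsd, dtype=float)
            if self.rmsd.shape != (n,):
                raise ValueError("rmsd must have one value per frame")
        if n:
            if not np.all(np.isfinite(self.times)) or np.any(self.times < 0):
                raise ValueError("frame times must be finite and non-negative")
            if np.any(self.d_res < 0) or np.any(self.d_min < 0):
                raise ValueError("distances must be non-negative")
            if not np.allclose(self.d_min, self.d_res.min(axis=1),
                               rtol=0.0, atol=_DMIN_ATOL):
                raise ValueError(
                    "d_min must equal the per-frame minimum over residues")
        self.residue_names = list(self.residue_names)

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def is_empty(self) -> bool:
        return self.n_frames == 0

    def subset(self, mask: np.ndarray) -> "DistanceSeries":
        """Frame subset (boolean mask or index array), order preserving."""
        mask = np.asarray(mask)
        return DistanceSeries(
            condition=self.condition,
            times=self.times[mask],
            d_min=self.d_min[mask],
            d_res=self.d_res[mask],
            residue_names=self.residue_names,
            rmsd=None if self.rmsd is None else self.rmsd[mask],
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O
    def residue_columns(self) -> list[str]:
        return [f"d_res_{name}{i + 1}_nm"
                for i, name in enumerate(self.residue_names)]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ps": self.times, "d_min_nm": self.d_min}
        for j, col in enumerate(self.residue_columns()):
            data[col] = self.d_res[:, j]
        if self.rmsd is not None:
            data["rmsd_nm"] = self.rmsd
        return pd.DataFrame(data)

    def write(self, csv_path: str | Path) -> Path:
        """Write the CSV plus its ``<stem>.manifest.json`` sidecar."""
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        manifest = {
            "schema_version": _SCHEMA_VERSION,
            **self.condition.as_dict(),
            "n_frames": self.n_frames,
            "residue_names": list(self.residue_names),
            "has_rmsd": self.rmsd is not None,
            **{k: v for k, v in sorted(self.meta.items())},
        }
        manifest_path = csv_path.with_suffix(".manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return csv_path


def _manifest_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".manifest.json")


def read_series(csv_path: str | Path) -> DistanceSeries:
    """Read a series CSV and its manifest back into a :class:`DistanceSeries`."""
    csv_path = Path(csv_path)
    manifest = json.loads(_manifest_path(csv_path).read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    res_cols = [c for c in df.columns if _RES_COL.match(c)]
    names = [_RES_COL.match(c)["name"] for c in res_cols]
    meta = {k: v for k, v in manifest.items()
            if k not in {"schema_version", "peptide_id", "nacl_mM", "replica",
                         "n_frames", "residue_names", "has_rmsd"}}
    return DistanceSeries(
        condition=Condition(manifest["peptide_id"], manifest["nacl_mM"],
                            manifest["replica"]),
        times=df["time_ps"].to_numpy(),
        d_min=df["d_min_nm"].to_numpy(),
        d_res=df[res_cols].to_numpy(),
        residue_names=names,
        rmsd=df["rmsd_nm"].to_numpy() if "rmsd_nm" in df.columns else None,
        meta=meta,
    )


def read_study_dir(directory: str | Path) -> list[DistanceSeries]:
    """Read every ``*.csv`` series (with manifest) in a directory, sorted."""
    directory = Path(directory)
    out = []
    for csv_path in sorted(directory.glob("*.csv")):
        if _manifest_path(csv_path).exists():
            out.append(read_series(csv_path))
    if not out:
        raise FileNotFoundError(f"no distance-series files found in {directory}")
    return out
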
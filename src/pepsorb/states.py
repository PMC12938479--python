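"""Residue contact-state classification and combinatorial microstates.

Pooled per-residue distance histograms show two near-surface layers — a
direct-contact peak near 0.2 nm and a solvent-separated peak near 0.4 nm —
on top of a bulk tail.  A two-component Gaussian fit to those peaks defines
the contact (C) / solvent-separated (S) boundary as the abscissa where the
two fitted components intersect; the S / non-adsorbed (N) boundary is fixed
at 0.5 nm.  Every residue in every frame is then labelled C, S or N, and the
frame-wise concatenation of labels (N- to C-terminal order) is the peptide's
microstate, tabulated by occurrence fraction.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .series import DistanceSeries

__all__ = [
    "DistanceHistogram", "TwoGaussianFit", "StateThresholds", "MicrostateTable",
    "residue_distance_histogram", "fit_two_gaussian_layers", "derive_thresholds",
    "assign_states", "microstate_table", "compare_conditions",
    "residue_marginals", "labels_for_series",
]

STATE_ALPHABET = ("C", "S", "N")
FALLBACK_CS = 0.3   # nm, fixed boundary used when the fit is degenerate
FALLBACK_SN = 0.5   # nm


@dataclass
class DistanceHistogram:
    bin_edges: np.ndarray       # nm, strictly increasing, len = n_bins + 1
    counts: np.ndarray          # non-negative ints per bin
    n_samples: int              # = counts.sum(); samples outside range dropped
    pooling: str                # human-readable descriptor of what was pooled

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.shape[0] != self.bin_edges.shape[0] - 1:
            raise ValueError("need one count per bin")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n_samples:
            raise ValueError("n_samples must equal sum(counts)")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class TwoGaussianFit:
    """Parameters of the two-layer Gaussian fit (mu_C < mu_S enforced)."""

    mu_C: float
    sigma_C: float
    amp_C: float
    mu_S: float
    sigma_S: float
    amp_S: float
    fit_range: tuple[float, float]
    residual_norm: float
    degenerate: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not self.mu_C < self.mu_S:
                raise ValueError("component means must satisfy mu_C < mu_S")
            if min(self.sigma_C, self.sigma_S) <= 0 or \
                    min(self.amp_C, self.amp_S) <= 0:
                raise ValueError("sigmas and amplitudes must be positive")

    def as_dict(self) -> dict:
        return {
            "mu_C_nm": self.mu_C, "sigma_C_nm": self.sigma_C,
            "amp_C": self.amp_C, "mu_S_nm": self.mu_S,
            "sigma_S_nm": self.sigma_S, "amp_S": self.amp_S,
            "fit_range_nm": list(self.fit_range),
            "residual_norm": self.residual_norm,
            "degenerate": self.degenerate, "message": self.message,
        }


@dataclass
class StateThresholds:
    cs_boundary: float            # nm
    sn_boundary: float = FALLBACK_SN
    provenance: str = "fitted"    # "fitted" | "fixed"
    fallback: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.cs_boundary < self.sn_boundary:
            raise ValueError("need 0 < cs_boundary < sn_boundary")


@dataclass
class MicrostateTable:
    """Occurrence fraction of each residue-state string for one pooling."""

    peptide_id: str
    microstates: dict[str, float]     # ordered by decreasing fraction
    n_frames: int
    filter_threshold: float = 0.01
    residue_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.microstates}
        if len(lengths) > 1:
            raise ValueError("microstate strings must share one length")
        if self.microstates:
            total = sum(self.microstates.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError("unfiltered fractions must sum to 1")
        self.microstates = dict(sorted(
            self.microstates.items(), key=lambda kv: (-kv[1], kv[0])))

    @property
    def string_length(self) -> int:
        return len(next(iter(self.microstates))) if self.microstates else 0

    @property
    def filtered(self) -> dict[str, float]:
        """Microstates whose occurrence exceeds the filter threshold."""
        return {s: f for s, f in self.microstates.items()
                if f > self.filter_threshold}


# ---------------------------------------------------------------- histograms

def residue_distance_histogram(series_set: Iterable[DistanceSeries],
                               bin_width: float = 0.01,
                               hist_range: tuple[float, float] = (0.0, 1.0),
                               residues: Sequence[int] | None = None,
                               pooling: str | None = None) -> DistanceHistogram:
    """Histogram of pooled (frame, residue) minimum-distance samples.

    ``residues`` restricts pooling to the given residue indices (default:
    all residues of every series).  Samples outside ``hist_range`` are
    excluded from both counts and ``n_samples``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = hist_range
    if not lo < hi:
        raise ValueError("histogram range must be non-empty")
    samples = []
    n_series = 0
    for s in series_set:
        n_series += 1
        block = s.d_res if residues is None else s.d_res[:, list(residues)]
        samples.append(block.ravel())
    if n_series == 0 or not any(len(a) for a in samples):
        raise ValueError("empty pool: no distance samples to histogram")
    data = np.concatenate(samples)
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(data, bins=edges)
    desc = pooling or (f"{n_series} series, "
                       f"residues={'all' if residues is None else list(residues)}")
    return DistanceHistogram(bin_edges=edges, counts=counts,
                             n_samples=int(counts.sum()), pooling=desc)


# ---------------------------------------------------------------- the fit

def _two_gaussians(x, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))


def _count_peaks(centers: np.ndarray, counts: np.ndarray) -> int:
    if counts.size < 5:
        return 0
    smooth = np.convolve(counts.astype(float), np.ones(3) / 3.0, mode="same")
    peaks, _ = find_peaks(smooth, prominence=0.05 * max(smooth.max(), 1.0))
    return int(len(peaks))


def fit_two_gaussian_layers(hist: DistanceHistogram,
                            init_mu: tuple[float, float] = (0.2, 0.4),
                            fit_range: tuple[float, float] = (0.0, 0.5),
                            ) -> TwoGaussianFit:
    """Least-squares two-Gaussian fit to bin-centre counts over fit_range.

    Single-peak or non-convergent data yields a fit flagged ``degenerate``
    (with a warning); :func:`derive_thresholds` then falls back to the fixed
    0.3 / 0.5 nm boundaries.
    """
    lo, hi = fit_range
    window = (hist.centers >= lo) & (hist.centers <= hi)
    x = hist.centers[window]
    y = hist.counts[window].astype(float)

    def _degenerate(msg: str) -> TwoGaussianFit:
        warnings.warn(f"two-Gaussian fit degenerate: {msg}", stacklevel=3)
        return TwoGaussianFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                              fit_range=fit_range, residual_norm=np.nan,
                              degenerate=True, message=msg)

    if x.size < 6 or y.max() <= 0:
        return _degenerate("too few informative bins in fit range")
    if _count_peaks(x, y) < 2:
        return _degenerate("fewer than two local maxima in fit range")

    def _amp_near(mu):
        return max(float(y[np.argmin(np.abs(x - mu))]), 1.0)

    p0 = [_amp_near(init_mu[0]), init_mu[0], 0.04,
          _amp_near(init_mu[1]), init_mu[1], 0.04]
    bounds = ([0.0, lo, 1e-4, 0.0, lo, 1e-4],
              [np.inf, hi, hi - lo, np.inf, hi, hi - lo])
    try:
        popt, _ = curve_fit(_two_gaussians, x, y, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError as exc:
        return _degenerate(f"no convergence: {exc}")
    a1, m1, s1, a2, m2, s2 = popt
    if m1 > m2:       # enforce mu_C < mu_S by ordering components
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    if np.isclose(m1, m2, atol=1e-6):
        return _degenerate("components collapsed onto one mean")
    resid = float(np.linalg.norm(_two_gaussians(x, a1, m1, s1, a2, m2, s2) - y))
    return TwoGaussianFit(mu_C=float(m1), sigma_C=float(s1), amp_C=float(a1),
                          mu_S=float(m2), sigma_S=float(s2), amp_S=float(a2),
                          fit_range=fit_range, residual_norm=resid)


def derive_thresholds(fit: TwoGaussianFit,
                      sn_boundary: float = FALLBACK_SN) -> StateThresholds:
    """C/S boundary = intersection of the two fitted components.

    Equating the component log-densities gives a quadratic in distance; the
    root inside (mu_C, mu_S) is the boundary.  Degenerate fits fall back to
    the fixed 0.3 nm boundary; a missing interior root falls back to the
    midpoint of the means, flagged.
    """
    if fit.degenerate:
        return StateThresholds(FALLBACK_CS, sn_boundary, provenance="fixed",
                               fallback=True,
                               message=f"degenerate fit: {fit.message}")
    mC, sC, aC = fit.mu_C, fit.sigma_C, fit.amp_C
    mS, sS, aS = fit.mu_S, fit.sigma_S, fit.amp_S
    # ln aC - (x-mC)^2/(2 sC^2) = ln aS - (x-mS)^2/(2 sS^2)
    a = 0.5 * (1.0 / sS**2 - 1.0 / sC**2)
    b = mC / sC**2 - mS / sS**2
    c = 0.5 * (mS**2 / sS**2 - mC**2 / sC**2) + np.log(aC / aS)
    if np.isclose(a, 0.0, atol=1e-12):          # equal sigmas: linear case
        roots = [-c / b] if b != 0 else []
    else:
        disc = b * b - 4 * a * c
        roots = [] if disc < 0 else \
            [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
    interior = [r for r in roots if mC < r < mS]
    if not interior:
        return StateThresholds((mC + mS) / 2.0, sn_boundary,
                               provenance="fitted", fallback=True,
                               message="no component intersection between "
                                       "the means; midpoint used")
    return StateThresholds(float(interior[0]), sn_boundary)


# ---------------------------------------------------------------- labelling

def assign_states(d_res: np.ndarray, thr: StateThresholds) -> np.ndarray:
    """Elementwise C/S/N labels: d < cs → C, cs <= d <= sn → S, d > sn → N.

    Boundary values go to the outer state (S at both boundaries).
    """
    d_res = np.asarray(d_res, dtype=float)
    bad = ~np.isfinite(d_res)
    if bad.any():
        idx = tuple(int(v) for v in np.argwhere(bad)[0])
        raise ValueError(f"non-finite distance at (frame, residue) = {idx}")
    if (d_res < 0).any():
        raise ValueError("distances must be non-negative")
    labels = np.full(d_res.shape, "S", dtype="<U1")
    labels[d_res < thr.cs_boundary] = "C"
    labels[d_res > thr.sn_boundary] = "N"
    return labels


def labels_for_series(series_set: Iterable[DistanceSeries],
                      thr: StateThresholds) -> np.ndarray:
    """Stacked label matrix over all frames of the given series."""
    mats = [assign_states(s.d_res, thr) for s in series_set]
    if not mats:
        raise ValueError("no series given")
    return np.concatenate(mats, axis=0)


def microstate_table(labels: np.ndarray, filter_threshold: float = 0.01,
                     peptide_id: str = "",
                     residue_names: Sequence[str] = ()) -> MicrostateTable:
    """Tabulate frame-wise residue-state strings by occurrence fraction."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[0] == 0:
        raise ValueError("labels must be a non-empty (frames, residues) matrix")
    strings = ["".join(row) for row in labels]
    counts = Counter(strings)
    n = len(strings)
    fractions = {s: c / n for s, c in counts.items()}
    return MicrostateTable(peptide_id=peptide_id, microstates=fractions,
                           n_frames=n, filter_threshold=filter_threshold,
                           residue_names=list(residue_names))


def residue_marginals(table: MicrostateTable) -> pd.DataFrame:
    """Per-residue C/S/N marginal occupancies from the unfiltered table."""
    n_res = table.string_length
    out = np.zeros((n_res, 3))
    for s, f in table.microstates.items():
        for i, letter in enumerate(s):
            out[i, STATE_ALPHABET.index(letter)] += f
    names = list(table.residue_names) or [f"res{i+1}" for i in range(n_res)]
    return pd.DataFrame(out, columns=list(STATE_ALPHABET), index=names)


def compare_conditions(table_low: MicrostateTable,
                       table_high: MicrostateTable) -> pd.DataFrame:
    """Union comparison of two conditions, ordered by the low-salt fraction.

    Microstates absent at one condition are reported with fraction 0.0; the
    delta column is high minus low.
    """
    if table_low.string_length != table_high.string_length:
        raise ValueError("tables compare peptides of different lengths")
    union = set(table_low.microstates) | set(table_high.microstates)
    rows = []
    for s in union:
        lo = table_low.microstates.get(s, 0.0)
        hi = table_high.microstates.get(s, 0.0)
        rows.append({"microstate": s, "rate_low": lo, "rate_high": hi,
                     "delta": hi - lo})
    df = pd.DataFrame(rows).sort_values(
        ["rate_low", "rate_high", "microstate"],
        ascending=[False, False, True]).reset_index(drop=True)
    return df


def write_fit_diagnostics(fit: TwoGaussianFit, thr: StateThresholds,
                          path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        **fit.as_dict(),
        "cs_boundary_nm": thr.cs_boundary,
        "sn_boundary_nm": thr.sn_boundary,
        "threshold_provenance": thr.provenance,
        "threshold_fallback": thr.fallback,
        "threshold_message": thr.message,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
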
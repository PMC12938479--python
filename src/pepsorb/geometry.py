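"""Minimum-image distances, slab geometry and backbone RMSD.

Coordinates are nanometres in an orthorhombic periodic box.  Distances from
peptide atoms to the surface are computed against *all* slab atoms under the
minimum-image convention — the slab fills the box laterally, so the nearest
face dominates and no face labelling is needed for an amorphous surface.

Atom scope for surface distances defaults to heavy atoms (hydrogens
excluded), the conventional contact definition; ``atom_scope="all"`` includes
hydrogens.  Backbone means N, Cα, C per residue unless the topology says
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .series import Condition, DistanceSeries

__all__ = [
    "PeriodicBox", "SlabModel", "PeptideTopology", "Frame",
    "min_image_displacement", "min_image_distance", "min_image_distance_matrix",
    "residue_surface_min_distances", "peptide_surface_min_distance",
    "backbone_rmsd", "extract_distance_series",
]

AtomScope = Literal["heavy", "all"]


@dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic periodic box with edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(e) and e > 0 for e in (self.lx, self.ly, self.lz)):
            raise ValueError("box edges must be finite and positive")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)


@dataclass
class SlabModel:
    """Atom positions and Ti/O roles of the surface slab."""

    positions: np.ndarray            # (n, 3) nm
    roles: np.ndarray                # (n,) of {"Ti", "O"}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.roles = np.asarray(self.roles)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("slab positions must be an (n, 3) array")
        if self.positions.shape[0] == 0:
            raise ValueError("slab must contain at least one atom")
        if self.roles.shape[0] != self.positions.shape[0]:
            raise ValueError("one role per slab atom required")
        bad = set(np.unique(self.roles)) - {"Ti", "O"}
        if bad:
            raise ValueError(f"unknown slab atom roles: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_ti(self) -> int:
        return int(np.sum(self.roles == "Ti"))

    @property
    def n_o(self) -> int:
        return int(np.sum(self.roles == "O"))

    @property
    def stoichiometry(self) -> float:
        """O:Ti atom-count ratio (2.0 for stoichiometric TiO2)."""
        if self.n_ti == 0:
            raise ValueError("slab contains no Ti atoms")
        return self.n_o / self.n_ti

    @classmethod
    def build_stoichiometric(cls, n_ti: int, box: PeriodicBox,
                             thickness: float = 2.1, normal_axis: int = 2,
                             seed: int | None = 0) -> "SlabModel":
        """Random disordered TiO2 slab with exact 1:2 Ti:O stoichiometry.

        Atoms are placed uniformly in a layer of the given thickness that
        spans the box along the two lateral axes, mimicking an amorphous
        slab; the arrangement is a geometric stand-in, not a physical glass.
        """
        if n_ti < 1:
            raise ValueError("n_ti must be >= 1")
        if not 0 < thickness <= box.lengths[normal_axis]:
            raise ValueError("slab thickness must fit inside the box")
        rng = np.random.default_rng(seed)
        n = 3 * n_ti
        pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box.lengths
        pos[:, normal_axis] = rng.uniform(0.0, thickness, size=n)
        roles = np.array(["Ti"] * n_ti + ["O"] * (2 * n_ti))
        return cls(positions=pos, roles=roles)


@dataclass
class PeptideTopology:
    """Residue structure of the peptide: ordering, backbone and heavy flags."""

    residue_names: Sequence[str]          # N- to C-terminal order
    atom_residue_index: np.ndarray        # (n_atoms,) int, 0-based
    backbone_flags: np.ndarray            # (n_atoms,) bool
    heavy_flags: np.ndarray               # (n_atoms,) bool
    atom_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.residue_names = list(self.residue_names)
        self.atom_residue_index = np.asarray(self.atom_residue_index, dtype=int)
        self.backbone_flags = np.asarray(self.backbone_flags, dtype=bool)
        self.heavy_flags = np.asarray(self.heavy_flags, dtype=bool)
        n = self.atom_residue_index.shape[0]
        if self.backbone_flags.shape[0] != n or self.heavy_flags.shape[0] != n:
            raise ValueError("per-atom flag arrays must match atom count")
        n_res = len(self.residue_names)
        if n_res == 0:
            raise ValueError("peptide must have at least one residue")
        if self.atom_residue_index.min(initial=0) < 0 or \
                self.atom_residue_index.max(initial=-1) >= n_res:
            raise ValueError("atom_residue_index out of residue range")
        for i in range(n_res):
            members = self.atom_residue_index == i
            if not members.any():
                raise ValueError(f"residue {i} ({self.residue_names[i]}) has no atoms")
            if not (members & self.backbone_flags).any():
                raise ValueError(
                    f"residue {i} ({self.residue_names[i]}) has no backbone atom")

    @property
    def n_atoms(self) -> int:
        return int(self.atom_residue_index.shape[0])

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def scope_mask(self, atom_scope: AtomScope) -> np.ndarray:
        if atom_scope == "heavy":
            return self.heavy_flags.copy()
        if atom_scope == "all":
            return np.ones(self.n_atoms, dtype=bool)
        raise ValueError(f"unknown atom scope {atom_scope!r}")


@dataclass
class Frame:
    """One trajectory frame: time stamp and peptide atom positions (nm)."""

    time: float                 # ps
    positions: np.ndarray       # (n_atoms, 3) nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("frame positions must be an (n, 3) array")
        if self.time < 0 or not np.isfinite(self.time):
            raise ValueError("frame time must be finite and non-negative")


# ------------------------------------------------------------------ distances

def _check_points(*points: np.ndarray) -> list[np.ndarray]:
    out = []
    for p in points:
        p = np.asarray(p, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite coordinates")
        out.append(p)
    return out


def min_image_displacement(p1, p2, box: PeriodicBox) -> np.ndarray:
    """Displacement p2 - p1 wrapped to the nearest periodic image."""
    p1, p2 = _check_points(p1, p2)
    delta = p2 - p1
    lengths = box.lengths
    return delta - lengths * np.round(delta / lengths)


def min_image_distance(p1, p2, box: PeriodicBox) -> float:
    """Smallest Euclidean distance between two points over all images.

    For an orthorhombic box the per-axis nearest-image wrap is exact.
    """
    return float(np.linalg.norm(min_image_displacement(p1, p2, box)))


def min_image_distance_matrix(a: np.ndarray, b: np.ndarray,
                              box: PeriodicBox) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances."""
    a, b = _check_points(a, b)
    delta = a[:, None, :] - b[None, :, :]
    lengths = box.lengths
    delta -= lengths * np.round(delta / lengths)
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))


def residue_surface_min_distances(frame: Frame, slab: SlabModel,
                                  topo: PeptideTopology, box: PeriodicBox,
                                  atom_scope: AtomScope = "heavy") -> np.ndarray:
    """Per-residue minimum distance to any slab atom (nm), N→C order."""
    if frame.positions.shape[0] != topo.n_atoms:
        raise ValueError(
            f"frame has {frame.positions.shape[0]} atoms, topology expects "
            f"{topo.n_atoms}")
    scope = topo.scope_mask(atom_scope)
    out = np.empty(topo.n_residues, dtype=float)
    dmat = min_image_distance_matrix(frame.positions[scope], slab.positions, box)
    atom_min = dmat.min(axis=1)
    res_idx = topo.atom_residue_index[scope]
    for i in range(topo.n_residues):
        members = res_idx == i
        if not members.any():
            raise ValueError(
                f"residue {i} ({topo.residue_names[i]}) has no atoms in "
                f"scope {atom_scope!r}")
        out[i] = atom_min[members].min()
    return out


def peptide_surface_min_distance(frame: Frame, slab: SlabModel,
                                 topo: PeptideTopology, box: PeriodicBox,
                                 atom_scope: AtomScope = "heavy") -> float:
    """Whole-peptide minimum surface distance (nm)."""
    return float(residue_surface_min_distances(
        frame, slab, topo, box, atom_scope).min())


# ------------------------------------------------------------------ RMSD

def _kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centred p onto centred q (Kabsch, SVD)."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def backbone_rmsd(frame: Frame, reference: Frame,
                  topo: PeptideTopology) -> float:
    """Backbone RMSD (nm) after least-squares rigid superposition.

    Raises for fewer than three backbone atoms or a collinear backbone, where
    the rotation is not uniquely determined.
    """
    mask = topo.backbone_flags
    if frame.positions.shape[0] != topo.n_atoms or \
            reference.positions.shape[0] != topo.n_atoms:
        raise ValueError("frame/reference atom count does not match topology")
    p = frame.positions[mask]
    q = reference.positions[mask]
    if p.shape[0] < 3:
        raise ValueError("need at least 3 backbone atoms for superposition")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    sv = np.linalg.svd(pc, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise ValueError("backbone atoms are collinear; superposition degenerate")
    rot = _kabsch_rotation(pc, qc)
    diff = pc @ rot.T - qc
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# ------------------------------------------------------------------ extraction

def extract_distance_series(frames: Iterable[Frame], slab: SlabModel,
                            topo: PeptideTopology, box: PeriodicBox,
                            condition: Condition, stride: int = 1,
                            atom_scope: AtomScope = "heavy",
                            rmsd_reference: Frame | str | None = "first",
                            meta: dict | None = None) -> DistanceSeries:
    """Run the per-frame geometry over a frame stream into a DistanceSeries.

    ``rmsd_reference`` may be a Frame, ``"first"`` (reference = first analysed
    frame) or None to skip RMSD.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    times: list[float] = []
    d_res_rows: list[np.ndarray] = []
    rmsd_vals: list[float] | None = None if rmsd_reference is None else []
    ref = rmsd_reference if isinstance(rmsd_reference, Frame) else None

    for k, frame in enumerate(frames):
        if k % stride:
            continue
        try:
            d = residue_surface_min_distances(frame, slab, topo, box, atom_scope)
        except ValueError as exc:
            raise ValueError(f"frame {k}: {exc}") from exc
        d_res_rows.append(d)
        times.append(frame.time)
        if rmsd_vals is not None:
            if ref is None:
                ref = Frame(frame.time, frame.positions.copy())
            rmsd_vals.append(backbone_rmsd(frame, ref, topo))

    d_res = np.array(d_res_rows) if d_res_rows else \
        np.empty((0, topo.n_residues))
    full_meta = {"stride": stride, "atom_scope": atom_scope}
    full_meta.update(meta or {})
    return DistanceSeries(
        condition=condition,
        times=np.array(times),
        d_min=d_res.min(axis=1) if len(times) else np.empty(0),
        d_res=d_res,
        residue_names=topo.residue_names,
        rmsd=np.array(rmsd_vals) if rmsd_vals is not None else None,
        meta=full_meta,
    )
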
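"""Optional trajectory adapter for standard MD file formats.

Reads a topology-like coordinate file (GRO/PDB) and optionally a trajectory
(XTC/TRR/DCD) through MDAnalysis, splits the system into slab and peptide by
atom selections, converts to nanometres, and streams frames through the
geometry module into a :class:`~pepsorb.series.DistanceSeries`.

Only orthorhombic boxes are supported; triclinic input is rejected.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .geometry import Frame, PeriodicBox, PeptideTopology, SlabModel, \
    extract_distance_series
from .series import Condition, DistanceSeries

__all__ = ["load_trajectory_series"]

_ANGSTROM_TO_NM = 0.1
DEFAULT_BACKBONE_NAMES = ("N", "CA", "C")


def _roles_from_names(names: Sequence[str]) -> np.ndarray:
    roles = []
    for name in names:
        upper = name.upper()
        if upper.startswith("TI"):
            roles.append("Ti")
        elif upper.startswith("O"):
            roles.append("O")
        else:
            raise ValueError(f"cannot classify slab atom {name!r} as Ti or O")
    return np.array(roles)


def _is_hydrogen(atom) -> bool:
    element = getattr(atom, "element", "") or ""
    if element:
        return element.upper() == "H"
    return atom.name.upper().startswith("H")


def load_trajectory_series(topology: str, trajectory: str | None = None, *,
                           slab_selection: str, peptide_selection: str,
                           condition: Condition, stride: int = 1,
                           atom_scope: str = "heavy",
                           backbone_names: Sequence[str] = DEFAULT_BACKBONE_NAMES,
                           rmsd_reference: str | None = "first",
                           ) -> DistanceSeries:
    """Extract a distance series from coordinate/trajectory files.

    ``slab_selection`` / ``peptide_selection`` are MDAnalysis selection
    strings (e.g. ``"resname TIO"`` and ``"protein"``).
    """
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None \
        else mda.Universe(topology, trajectory)
    dims = u.dimensions
    if dims is None or not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ValueError("only orthorhombic boxes are supported")
    box = PeriodicBox(*(dims[:3] * _ANGSTROM_TO_NM))

    slab_atoms = u.select_atoms(slab_selection)
    pep_atoms = u.select_atoms(peptide_selection)
    if len(slab_atoms) == 0 or len(pep_atoms) == 0:
        raise ValueError("empty slab or peptide selection")

    roles = _roles_from_names([a.name for a in slab_atoms])

    residues = pep_atoms.residues
    res_index_of = {r.resindex: i for i, r in enumerate(residues)}
    atom_res = np.array([res_index_of[a.resindex] for a in pep_atoms])
    backbone_set = {n.upper() for n in backbone_names}
    backbone = np.array([a.name.upper() in backbone_set for a in pep_atoms])
    heavy = np.array([not _is_hydrogen(a) for a in pep_atoms])
    topo = PeptideTopology(
        residue_names=[r.resname for r in residues],
        atom_residue_index=atom_res,
        backbone_flags=backbone,
        heavy_flags=heavy,
        atom_names=[a.name for a in pep_atoms],
    )

    def frames():
        for ts in u.trajectory:
            time_ps = float(ts.time) if np.isfinite(ts.time) else 0.0
            yield Frame(max(time_ps, 0.0),
                        pep_atoms.positions * _ANGSTROM_TO_NM)

    # slab coordinates are taken from the first frame; the slab is rigid in
    # this analysis and its atoms are not tracked per frame
    u.trajectory[0]
    slab = SlabModel(positions=slab_atoms.positions * _ANGSTROM_TO_NM,
                     roles=roles)
    ref = "first" if rmsd_reference == "first" else None
    return extract_distance_series(
        frames(), slab, topo, box, condition, stride=stride,
        atom_scope=atom_scope, rmsd_reference=ref,
        meta={"source": topology if trajectory is None
              else f"{topology}+{trajectory}"})
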
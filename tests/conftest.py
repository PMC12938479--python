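import numpy as np
import pytest

from pepsorb.geometry import Frame, PeriodicBox, PeptideTopology, SlabModel
from pepsorb.series import Condition, DistanceSeries


@pytest.fixture
def box() -> PeriodicBox:
    # the reference study's solvated box
    return PeriodicBox(10.11, 4.90, 10.70)


@pytest.fixture
def cube_box() -> PeriodicBox:
    return PeriodicBox(10.0, 10.0, 10.0)


def make_topology(atoms_per_residue: list[int],
                  residue_names: list[str] | None = None,
                  all_backbone: bool = False) -> PeptideTopology:
    """Toy topology: first three atoms of each residue are backbone + heavy,
    any extra atoms are heavy side chain (or everything backbone)."""
    n_res = len(atoms_per_residue)
    names = residue_names or [f"R{i + 1}" for i in range(n_res)]
    res_idx, backbone = [], []
    for i, n_atoms in enumerate(atoms_per_residue):
        assert n_atoms >= 1
        res_idx.extend([i] * n_atoms)
        n_bb = n_atoms if all_backbone else min(3, n_atoms)
        backbone.extend([True] * n_bb + [False] * (n_atoms - n_bb))
    res_idx = np.array(res_idx)
    return PeptideTopology(
        residue_names=names,
        atom_residue_index=res_idx,
        backbone_flags=np.array(backbone),
        heavy_flags=np.ones(len(res_idx), dtype=bool),
    )


@pytest.fixture
def tetra_topology() -> PeptideTopology:
    """4 residues x 3 backbone atoms, all heavy."""
    return make_topology([3, 3, 3, 3], ["K", "R", "S", "R"])


@pytest.fixture
def flat_slab(cube_box) -> SlabModel:
    """Regular grid of slab atoms in the z=0.5 plane (Ti) and z=0.3 (O)."""
    xs = np.linspace(0.5, 9.5, 10)
    ys = np.linspace(0.5, 9.5, 10)
    gx, gy = np.meshgrid(xs, ys)
    ti = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, 0.5)])
    o1 = ti + np.array([0.05, 0.0, -0.2])
    o2 = ti + np.array([-0.05, 0.0, -0.2])
    pos = np.vstack([ti, o1, o2])
    roles = np.array(["Ti"] * len(ti) + ["O"] * (2 * len(ti)))
    return SlabModel(positions=pos, roles=roles)


def random_frame(rng: np.random.Generator, topo: PeptideTopology,
                 box: PeriodicBox, time: float = 0.0) -> Frame:
    return Frame(time, rng.uniform(0, 1, size=(topo.n_atoms, 3)) * box.lengths)


def series_from_dmin(d_min, peptide_id="KRSR", nacl_mM=1.0, replica=1,
                     rmsd=None) -> DistanceSeries:
    """Single-residue series with prescribed whole-peptide distances."""
    d_min = np.asarray(d_min, dtype=float)
    return DistanceSeries(
        condition=Condition(peptide_id, nacl_mM, replica),
        times=np.arange(d_min.size) * 10.0,
        d_min=d_min,
        d_res=d_min[:, None],
        residue_names=["K"],
        rmsd=None if rmsd is None else np.asarray(rmsd, dtype=float),
    )
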
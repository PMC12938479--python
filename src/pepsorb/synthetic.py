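"""Synthetic distance-series studies with known ground truth.

Two generators stand in for atomistic trajectories:

* a per-residue continuous-time Markov chain (CTMC) over the contact (C),
  solvent-separated (S) and non-adsorbed (N) states, with Gaussian layer
  emissions near 0.2 and 0.4 nm and a bulk exponential tail, where the
  desorption rates of charged residues scale up with NaCl concentration
  (electrostatic screening weakens close contact), and
* an overdamped Langevin bead above a surface whose electrostatic attraction
  decays over the Debye screening length, demonstrating the same mechanism
  from an energy function rather than prescribed rates.

The default study design is nine NaCl concentrations from 1 to 200 mM, seven
replicas per condition and 50 ns per replica at a 10 ps frame interval.  All
randomness descends deterministically from one master seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import constants
from scipy.sparse.csgraph import connected_components
from scipy.special import ndtr, ndtri

from .series import Condition, DistanceSeries

__all__ = [
    "STATES", "ResidueStateModel", "SyntheticStudySpec", "GroundTruth",
    "LangevinSurfaceModel", "charged_residue_model", "neutral_residue_model",
    "models_for_sequence", "simulate_residue_ctmc", "stationary_occupancy",
    "generate_study", "debye_length", "simulate_langevin_bead",
    "langevin_salt_scan", "adsorbed_fraction",
]

STATES = ("C", "S", "N")
_IDX = {s: i for i, s in enumerate(STATES)}
# transitions whose rates grow with salt: loss of close contact
DESORPTION_TRANSITIONS = (("C", "S"), ("C", "N"), ("S", "N"))


# ------------------------------------------------------------------ emissions

@dataclass(frozen=True)
class TruncNorm:
    """Gaussian distance layer truncated to its support (nm)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = ndtr((self.lo - self.mean) / self.sd)
        b = ndtr((self.hi - self.mean) / self.sd)
        u = rng.uniform(a, b, size=n)
        return self.mean + self.sd * ndtri(u)


@dataclass(frozen=True)
class ShiftedExp:
    """Bulk distance tail: offset + exponential, truncated at d_max (nm)."""

    offset: float
    scale: float
    d_max: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        fmax = -np.expm1(-(self.d_max - self.offset) / self.scale)
        u = rng.uniform(0.0, fmax, size=n)
        return self.offset - self.scale * np.log1p(-u)


@dataclass(frozen=True)
class ResidueStateModel:
    """CTMC over C/S/N with salt-scaled desorption and layer emissions.

    ``base_rates[i, j]`` is the zero-salt transition rate from state i to j
    in 1/ns; desorption rates (C->S, C->N, S->N) are multiplied by
    ``1 + salt_coupling * c_mM``.
    """

    base_rates: np.ndarray                   # (3, 3), 1/ns, zero diagonal
    salt_coupling: float                     # 1/mM
    emission_C: TruncNorm = TruncNorm(0.20, 0.03, 0.0, 0.30)
    emission_S: TruncNorm = TruncNorm(0.40, 0.05, 0.25, 0.55)
    emission_N: ShiftedExp = ShiftedExp(0.50, 0.30, 4.0)

    def __post_init__(self) -> None:
        rates = np.asarray(self.base_rates, dtype=float)
        if rates.shape != (3, 3):
            raise ValueError("base_rates must be a 3x3 matrix over (C, S, N)")
        if np.any(rates < 0):
            raise ValueError("transition rates must be non-negative")
        object.__setattr__(self, "base_rates", rates)
        if not 0.0 < self.emission_C.mean < self.emission_S.mean < 0.5:
            raise ValueError("emission means must satisfy 0 < mu_C < mu_S < 0.5")

    def rate_matrix(self, c_mM: float) -> np.ndarray:
        """Generator matrix Q at concentration c (diagonal = -exit rate)."""
        if c_mM < 0:
            raise ValueError("concentration must be non-negative")
        q = self.base_rates.copy()
        np.fill_diagonal(q, 0.0)
        factor = 1.0 + self.salt_coupling * c_mM
        for a, b in DESORPTION_TRANSITIONS:
            q[_IDX[a], _IDX[b]] *= factor
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def emission(self, state: str):
        return {"C": self.emission_C, "S": self.emission_S,
                "N": self.emission_N}[state]


def _rates(**kv: float) -> np.ndarray:
    """Build a 3x3 rate matrix from 'CS', 'CN', ... keyword entries."""
    q = np.zeros((3, 3))
    for key, rate in kv.items():
        q[_IDX[key[0]], _IDX[key[1]]] = rate
    return q


def charged_residue_model(salt_coupling: float = 0.012) -> ResidueStateModel:
    """Lys/Arg-like residue: strong surface affinity, salt-sensitive.

    Rates of order 1/ns give sub-nanosecond holding times so 50 ns replicas
    sample many binding/unbinding events.
    """
    return ResidueStateModel(
        base_rates=_rates(NS=1.2, NC=0.4, SC=1.5, SN=1.8, CS=1.2, CN=0.6),
        salt_coupling=salt_coupling,
    )


def neutral_residue_model(salt_coupling: float = 0.0005) -> ResidueStateModel:
    """Polar/neutral residue: weaker binding, essentially salt-blind."""
    return ResidueStateModel(
        base_rates=_rates(NS=0.8, NC=0.15, SC=0.8, SN=2.0, CS=1.5, CN=0.8),
        salt_coupling=salt_coupling,
    )


CHARGED_RESIDUES = frozenset("KR")


def models_for_sequence(residues: Sequence[str]) -> list[ResidueStateModel]:
    """Default per-residue models: K/R charged, everything else neutral."""
    return [charged_residue_model() if r.upper() in CHARGED_RESIDUES
            else neutral_residue_model() for r in residues]


# ------------------------------------------------------------------ CTMC core

def stationary_occupancy(model: ResidueStateModel, c_mM: float) -> np.ndarray:
    """Stationary distribution over (C, S, N) of the salt-scaled chain.

    A reducible chain is flagged with a warning and solved on the recurrent
    structure via the same balance equations.
    """
    q = model.rate_matrix(c_mM)
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    # states with neither in- nor out-rates never carry mass; drop them
    active = (off.sum(axis=0) + off.sum(axis=1)) > 0
    if not active.any():
        warnings.warn("all transition rates are zero; returning uniform "
                      "occupancy", stacklevel=2)
        return np.full(3, 1.0 / 3.0)
    adj = (off[np.ix_(active, active)] > 0).astype(int)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1 or not active.all():
        warnings.warn("rate matrix is reducible; stationary distribution "
                      "computed on the communicating states only",
                      stacklevel=2)
    k = int(active.sum())
    qa = q[np.ix_(active, active)]
    a = np.vstack([qa.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi_active, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.zeros(3)
    pi[active] = np.clip(pi_active, 0.0, None)
    return pi / pi.sum()


def _sample_ctmc_path(q: np.ndarray, duration_ns: float, frame_times: np.ndarray,
                      rng: np.random.Generator, init_state: int) -> np.ndarray:
    """Exact Gillespie sampling, discretised to the frame grid."""
    states = np.empty(frame_times.size, dtype=int)
    t = 0.0
    state = init_state
    k = 0
    while k < frame_times.size:
        exit_rate = -q[state, state]
        t_next = t + (rng.exponential(1.0 / exit_rate)
                      if exit_rate > 0 else np.inf)
        while k < frame_times.size and frame_times[k] < t_next:
            states[k] = state
            k += 1
        if t_next > duration_ns and k >= frame_times.size:
            break
        t = t_next
        probs = q[state].copy()
        probs[state] = 0.0
        total = probs.sum()
        if total <= 0:
            states[k:] = state
            break
        state = rng.choice(3, p=probs / total)
    return states


def simulate_residue_ctmc(model: ResidueStateModel, c_mM: float,
                          duration_ns: float, frame_interval_ps: float,
                          seed=None, init: str | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one residue: (labels per frame, emitted distances per frame).

    Waiting times are exponential in the total exit rate and jumps are drawn
    proportionally to the transition rates (exact CTMC sampling); each frame
    then draws a distance from the current state's emission distribution.
    ``init`` picks the start state; the default draws it from the stationary
    distribution, mimicking unbiased initial placements.
    """
    if duration_ns <= 0 or frame_interval_ps <= 0:
        raise ValueError("duration and frame interval must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    q = model.rate_matrix(c_mM)
    frame_times = np.arange(0.0, duration_ns, frame_interval_ps / 1000.0)
    if init is None:
        pi = stationary_occupancy(model, c_mM)
        init_state = int(rng.choice(3, p=pi))
    else:
        init_state = _IDX[init]
    if -q[init_state, init_state] <= 0 and np.all(q.diagonal() >= 0):
        warnings.warn("all exit rates are zero; trajectory is constant",
                      stacklevel=2)
    states = _sample_ctmc_path(q, duration_ns, frame_times, rng, init_state)
    distances = np.empty(frame_times.size, dtype=float)
    for i, s in enumerate(STATES):
        members = states == i
        if members.any():
            distances[members] = model.emission(s).sample(rng, int(members.sum()))
    labels = np.array(STATES, dtype="<U1")[states]
    return labels, distances


# ------------------------------------------------------------------ the study

DEFAULT_CONCENTRATIONS = (1.0, 25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 175.0, 200.0)

PEPTIDE_SEQUENCES = {"KRSR": ("K", "R", "S", "R"), "RGD": ("R", "G", "D")}


@dataclass
class SyntheticStudySpec:
    """Ground-truth parameters of one synthetic study (one peptide)."""

    peptide_id: str
    residue_names: Sequence[str]
    models: Sequence[ResidueStateModel]
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    replicas: int = 7
    duration_ns: float = 50.0
    frame_interval_ps: float = 10.0
    rmsd_mean: float = 0.15        # nm; backbone RMSD plateau
    rmsd_sd: float = 0.03          # nm; fluctuation around the plateau
    rmsd_tau_ns: float = 1.0       # nm; mean-reversion time of the noise
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.residue_names = list(self.residue_names)
        self.models = list(self.models)
        if len(self.models) != len(self.residue_names):
            raise ValueError("need one state model per residue")
        if self.replicas < 1 or self.duration_ns <= 0:
            raise ValueError("replicas >= 1 and duration > 0 required")

    @classmethod
    def for_peptide(cls, peptide_id: str, **overrides) -> "SyntheticStudySpec":
        residues = PEPTIDE_SEQUENCES[peptide_id.upper()]
        return cls(peptide_id=peptide_id.upper(), residue_names=residues,
                   models=models_for_sequence(residues), **overrides)

    @property
    def n_frames(self) -> int:
        return int(np.ceil(self.duration_ns / (self.frame_interval_ps / 1000.0)))

    def replica_seed(self, cond_index: int, replica: int) -> np.random.SeedSequence:
        """Stable per-replica seed stream derived from the master seed."""
        return np.random.SeedSequence(
            entropy=self.master_seed, spawn_key=(cond_index, replica))


@dataclass
class GroundTruth:
    """Generator truth exported alongside a study for recovery tests."""

    peptide_id: str
    residue_names: list[str]
    salt_couplings: list[float]
    emission_means: tuple[float, float]          # (mu_C, mu_S) nm
    thresholds: tuple[float, float]              # nominal (C/S, S/N) nm
    occupancies: dict[float, np.ndarray]         # c -> (n_res, 3) stationary
    state_sequences: dict[tuple[float, int], np.ndarray] = field(repr=False,
                                                                 default_factory=dict)

    def occupancy(self, c_mM: float, residue: int, state: str) -> float:
        return float(self.occupancies[c_mM][residue, _IDX[state]])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "peptide_id": self.peptide_id,
            "residue_names": self.residue_names,
            "salt_couplings": self.salt_couplings,
            "emission_means_nm": list(self.emission_means),
            "thresholds_nm": list(self.thresholds),
            "stationary_occupancies": {
                str(c): occ.tolist() for c, occ in sorted(self.occupancies.items())
            },
            "states_order": list(STATES),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _ou_rmsd(n: int, dt_ns: float, mean: float, sd: float, tau_ns: float,
             rng: np.random.Generator) -> np.ndarray:
    """Mean-reverting (Ornstein-Uhlenbeck) RMSD noise, clipped at zero."""
    phi = np.exp(-dt_ns / tau_ns)
    innov = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + innov * eps[i - 1]
    return np.clip(x, 0.0, None)


def generate_study(spec: SyntheticStudySpec, out_dir: str | Path | None = None,
                   keep_state_sequences: bool = False,
                   ) -> tuple[list[DistanceSeries], GroundTruth]:
    """Generate every (condition, replica) series of a study.

    Deterministic given ``spec.master_seed``: per-replica generators are
    seeded by spawn keys ``(condition_index, replica)``.  When ``out_dir`` is
    given, the internal CSV + manifest files, a study manifest and
    ``ground_truth.json`` are written there.
    """
    series_list: list[DistanceSeries] = []
    occupancies: dict[float, np.ndarray] = {}
    truth = GroundTruth(
        peptide_id=spec.peptide_id,
        residue_names=list(spec.residue_names),
        salt_couplings=[m.salt_coupling for m in spec.models],
        emission_means=(spec.models[0].emission_C.mean,
                        spec.models[0].emission_S.mean),
        thresholds=(spec.models[0].emission_C.hi, spec.models[0].emission_N.offset),
        occupancies=occupancies,
    )
    dt_ns = spec.frame_interval_ps / 1000.0
    for ci, c in enumerate(spec.concentrations):
        occupancies[float(c)] = np.vstack(
            [stationary_occupancy(m, c) for m in spec.models])
        for rep in range(1, spec.replicas + 1):
            rng = np.random.default_rng(spec.replica_seed(ci, rep))
            d_res = np.empty((spec.n_frames, len(spec.models)))
            labels = np.empty((spec.n_frames, len(spec.models)), dtype="<U1")
            for j, model in enumerate(spec.models):
                lab, dist = simulate_residue_ctmc(
                    model, c, spec.duration_ns, spec.frame_interval_ps, seed=rng)
                labels[:, j] = lab
                d_res[:, j] = dist
            rmsd = _ou_rmsd(spec.n_frames, dt_ns, spec.rmsd_mean, spec.rmsd_sd,
                            spec.rmsd_tau_ns, rng)
            s = DistanceSeries(
                condition=Condition(spec.peptide_id, float(c), rep),
                times=np.arange(spec.n_frames) * spec.frame_interval_ps,
                d_min=d_res.min(axis=1),
                d_res=d_res,
                residue_names=spec.residue_names,
                rmsd=rmsd,
                meta={"source": "synthetic_ctmc",
                      "master_seed": spec.master_seed,
                      "condition_index": ci},
            )
            series_list.append(s)
            if keep_state_sequences:
                truth.state_sequences[(float(c), rep)] = labels
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in series_list:
            c, rep = s.condition.nacl_mM, s.condition.replica
            s.write(out_dir / f"{spec.peptide_id}_c{c:g}mM_r{rep}.csv")
        truth.to_json(out_dir / f"{spec.peptide_id}_ground_truth.json")
        manifest = {
            "schema_version": 1,
            "peptide_id": spec.peptide_id,
            "residue_names": list(spec.residue_names),
            "concentrations_mM": [float(c) for c in spec.concentrations],
            "replicas": spec.replicas,
            "duration_ns": spec.duration_ns,
            "frame_interval_ps": spec.frame_interval_ps,
            "master_seed": spec.master_seed,
        }
        (out_dir / f"{spec.peptide_id}_study_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return series_list, truth


# ------------------------------------------------------------ Debye screening

def debye_length(c_mM: float, temperature: float = 310.0,
                 relative_permittivity: float = 78.4) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte at concentration c.

    kappa^-1 = sqrt(eps0 * eps_r * kB * T / (2 * NA * e^2 * I)) with ionic
    strength I = c (mol/m^3 equals mM for a 1:1 salt).  Scales as c^(-1/2).
    """
    if c_mM <= 0:
        raise ValueError("concentration must be positive")
    ionic_strength = c_mM  # mol/m^3
    num = (constants.epsilon_0 * relative_permittivity
           * constants.k * temperature)
    den = 2.0 * constants.N_A * constants.e ** 2 * ionic_strength
    return float(np.sqrt(num / den) * 1e9)


# ------------------------------------------------------------ Langevin bead

@dataclass(frozen=True)
class LangevinSurfaceModel:
    """Overdamped bead above a charged surface, energies in kT, lengths nm.

    U(z) = -well_depth * exp(-((z - well_center)/well_width)^2)
           - bead_charge * surface_charge_scale * lambda_D(c) * exp(-z / lambda_D(c))

    The short-range well stands for hydrogen-bond/polar contact.  The screened
    term is the Debye-Hueckel attraction of a charged bead to a surface of
    fixed charge density: the surface potential amplitude is proportional to
    the screening length (phi_0 = sigma * lambda_D / epsilon), so added salt
    both shortens the range and lowers the amplitude of the attraction —
    the mechanism that destabilises a +3 bead while leaving a neutral,
    short-range binder untouched.
    """

    bead_charge: float = 3.0            # elementary charges (+3 KRSR-like)
    well_depth: float = 3.0             # kT
    well_width: float = 0.1             # nm
    well_center: float = 0.15           # nm
    surface_charge_scale: float = 0.8   # kT/(nm * e); amplitude = q * this * lambda
    temperature: float = 310.0          # K
    diffusion: float = 1.0              # nm^2/ns
    timestep_ps: float = 0.15
    z_min: float = 0.05                 # nm, reflecting wall (contact)
    z_max: float = 2.0                  # nm, reflecting wall (bulk)

    def lambda_d(self, c_mM: float) -> float:
        return debye_length(c_mM, self.temperature)

    def force(self, z: np.ndarray, lam) -> np.ndarray:
        """-dU/dz in kT/nm."""
        dz = z - self.well_center
        du_well = 2.0 * self.well_depth * dz / self.well_width ** 2 \
            * np.exp(-(dz / self.well_width) ** 2)
        du_elec = (self.bead_charge * self.surface_charge_scale
                   * np.exp(-z / lam))
        return -(du_well + du_elec)

    def check_stability(self, c_mM: float) -> None:
        """Reject timesteps whose drift or diffusion step rivals the well width.

        Criterion: max |F| * D * dt + sqrt(2 D dt) must stay below a quarter
        of the well width, evaluated on a fine z grid.
        """
        dt = self.timestep_ps / 1000.0
        lam = self.lambda_d(c_mM)
        z = np.linspace(self.z_min, self.z_max, 2000)
        fmax = float(np.abs(self.force(z, lam)).max())
        step = fmax * self.diffusion * dt + np.sqrt(2 * self.diffusion * dt)
        if step > 0.25 * self.well_width:
            raise ValueError(
                f"unstable Langevin parameters: per-step displacement scale "
                f"{step:.3f} nm exceeds a quarter well width "
                f"({0.25 * self.well_width:.3f} nm); reduce timestep")


def _reflect(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    z = np.mod(z - lo, 2.0 * span)
    z = np.where(z > span, 2.0 * span - z, z)
    return z + lo


def simulate_langevin_bead(model: LangevinSurfaceModel, c_mM,
                           duration_ns: float, seed=None,
                           record_interval_ps: float = 10.0,
                           n_walkers: int = 1, z0=None) -> np.ndarray:
    """Overdamped Langevin z(t) with reflecting walls; shape (frames, walkers).

    ``c_mM`` may be a scalar or one concentration per walker (walkers evolve
    independently and are used to vectorise seeds/conditions).
    """
    c_arr = np.broadcast_to(np.asarray(c_mM, dtype=float), (n_walkers,)).copy()
    for c in np.unique(c_arr):
        model.check_stability(float(c))
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dt = model.timestep_ps / 1000.0
    n_steps = int(round(duration_ns / dt))
    every = max(int(round(record_interval_ps / model.timestep_ps)), 1)
    lam = np.array([model.lambda_d(float(c)) for c in c_arr])
    z = (np.full(n_walkers, 0.5 * (model.z_min + model.z_max))
         if z0 is None else np.broadcast_to(np.asarray(z0, float),
                                            (n_walkers,)).copy())
    noise_scale = np.sqrt(2.0 * model.diffusion * dt)
    frames = []
    for step in range(n_steps):
        f = model.force(z, lam)
        z = z + model.diffusion * f * dt \
            + noise_scale * rng.standard_normal(n_walkers)
        z = _reflect(z, model.z_min, model.z_max)
        if (step + 1) % every == 0:
            frames.append(z.copy())
    return np.array(frames)


def adsorbed_fraction(z: np.ndarray, cutoff: float = 0.3) -> np.ndarray:
    """Fraction of frames with z below the adsorption cutoff, per walker."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return (z < cutoff).mean(axis=0)


def langevin_salt_scan(model: LangevinSurfaceModel,
                       concentrations: Sequence[float],
                       n_seeds: int = 10, duration_ns: float = 200.0,
                       base_seed: int = 0, cutoff: float = 0.3):
    """Mean adsorbed fraction per concentration, averaged over seeds.

    All (concentration, seed) walkers run as one vectorised ensemble; returns
    a list of (concentration, mean adsorbed fraction) pairs.
    """
    concentrations = [float(c) for c in concentrations]
    c_grid = np.repeat(concentrations, n_seeds)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(987,)))
    z = simulate_langevin_bead(model, c_grid, duration_ns, seed=rng,
                               n_walkers=c_grid.size)
    frac = adsorbed_fraction(z, cutoff).reshape(len(concentrations), n_seeds)
    return [(c, float(frac[i].mean())) for i, c in enumerate(concentrations)]
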
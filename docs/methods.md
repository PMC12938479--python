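# Methods

## Problem and scope

`pepsorb` post-processes molecular-dynamics trajectories of short bioactive
peptides (KRSR, net charge +3; RGD, net-neutral but polar) above an
amorphous TiO₂ slab, quantifying how NaCl concentration modulates
adsorption.  The package does not run any MD engine; it consumes coordinate
frames (or its own synthetic distance series) and produces the four
descriptor families below.  The reference study design throughout is nine
NaCl concentrations (1, 25, 50, 75, 100, 125, 150, 175, 200 mM), seven
independent replicas per condition and 50 ns of production per replica.

## Geometry

All coordinates are nanometres in an orthorhombic periodic box (triclinic
cells are rejected).  Distances use the minimum-image convention, computed
per axis with the nearest-image wrap, which is exact for orthorhombic
boxes.  Peptide–surface distance is the minimum over peptide atoms and all
slab atoms; no slab face is singled out because an amorphous slab has no
face labelling and the nearest face dominates when the slab spans the box
laterally.  Atom scope defaults to heavy atoms (hydrogens excluded), the
conventional contact definition; `atom_scope="all"` is available.

Backbone RMSD uses least-squares rigid superposition (Kabsch, SVD, with the
determinant correction that excludes reflections) over backbone atoms
(N, Cα, C by default).  Fewer than three backbone atoms, or a collinear
backbone, leaves the rotation under-determined and is rejected.  The RMSD
reference defaults to the first analysed frame of each replica; an explicit
reference frame is accepted.

## Replica metrics

* **Surface gate** — frames with whole-peptide minimum distance ≤ 1 nm.
  Mean RMSD and mean minimum distance are computed over gated frames only,
  so conformational statistics are not diluted by bulk diffusion.
* **Adsorption time ratio** — fraction of frames with minimum distance
  < 0.3 nm.  The denominator is all frames of the replica
  (`adsorbed_over_total`, the default); the alternative
  `adsorbed_over_nonadsorbed` convention is implemented and recorded in the
  output.  Boundary conventions are fixed for determinism: gating uses
  `d ≤ 1`, adsorption uses strict `d < 0.3`; both are measure-zero choices.
* An all-excluded gate yields a missing value with a warning, never an
  exception, so study-level tables keep their shape.

## Residue contact states

Per-residue minimum distances pooled over residues, replicas and
concentrations (one fit per peptide) are histogrammed at 0.01 nm bins on
[0, 1] nm.  A two-component Gaussian is least-squares fitted to bin-centre
counts on [0, 0.5] nm, initialised at the two observed layers (0.2 and
0.4 nm).  The contact/solvent-separated (C/S) boundary is the abscissa
where the two fitted components intersect, obtained in closed form from the
quadratic produced by equating component log-densities; the
solvent-separated/non-adsorbed (S/N) boundary is fixed at 0.5 nm, the
conventional edge of the secondary adsorption layer.  Histograms without
two local maxima in the fit window, or non-convergent fits, are flagged
degenerate and fall back to fixed 0.3/0.5 nm boundaries — never silently.
Distances exactly on a boundary are assigned to the outer state (S at both
boundaries).

Frame-wise residue labels concatenated in N→C order form the peptide
**microstate** (e.g. `CNNN` = N-terminal lysine anchored, rest solvated).
Occurrence fractions are tabulated unfiltered (summing to 1) with a
filtered view above an occurrence threshold (1% default; 2% for the
low-vs-high-salt comparison table).  Comparison tables take the union of
microstates ordered by the low-salt fraction, report absent states as 0.00,
and add a delta column.  Displayed tables round to two decimals; persisted
values keep full precision.

## Concentration trends

Each metric is correlated with NaCl concentration using one point per
replica (9 × 7 = 63 points), not per condition mean; the per-replica level
is the only choice under which the study's six reported (r, p) pairs are
mutually consistent with the standard test, and it remains configurable
(`level="condition"`).  Significance uses the exact t reference
distribution, p two-sided with n − 2 degrees of freedom; no
multiple-testing correction (six raw tests).  Slopes come from ordinary
least squares and are displayed in pm/mM for distances and %/mM for the
adsorption ratio (nm/mM × 1000, fraction/mM × 100).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the physics of a specific force field.

**CTMC mode.**  Each residue is an independent continuous-time Markov chain
over {C, S, N}, sampled exactly (exponential waiting times from the total
exit rate, jumps proportional to rates) and discretised to the 10 ps frame
grid; the initial state is drawn from the stationary distribution, mimicking
unbiased initial placements.  Desorption rates (C→S, C→N, S→N) scale as
`rate × (1 + coupling × c_mM)`: screening weakens close contact without
touching approach kinetics.  Charged residues (K/R) get coupling
0.012 mM⁻¹ (desorption ×3.4 at 200 mM); neutral residues 0.0005 mM⁻¹.
Base rates are of order 1 ns⁻¹ (sub-nanosecond holding times), chosen so
50 ns replicas sample many binding/unbinding cycles; occupancies are then
estimated to about a percentage point when pooled over a study.

Emissions per frame: C ~ N(0.20, 0.03²) truncated to (0, 0.3]; S ~
N(0.40, 0.05²) truncated to (0.25, 0.55]; N ~ 0.5 nm + Exp(0.3 nm)
truncated at 4 nm.  The bounded supports make the nominal 0.3/0.5 nm
boundaries almost exact label recovery points (cross-boundary leakage of
the S layer is ~2%), which is deliberately cleaner than real data: passing
recovery tests demonstrates the estimator chain is unbiased at the stated
sample sizes, not that heavily overlapping real layers would be resolved
equally well.  Whole-peptide distance is the per-frame minimum over
residues.  RMSD is synthesised independently of the distance states
(the study design assumes no RMSD–salt coupling) as mean-reverting
Ornstein–Uhlenbeck noise, mean 0.15 nm, sd 0.03 nm, relaxation 1 ns.

Note that in this mode the RGD arginine carries the full charged-residue
coupling, so synthetic RGD retains a reduced but non-zero salt response
(about half the KRSR ratio slope); the peptide-level charged-vs-neutral
contrast is the Langevin demonstrator's job.

All randomness descends from one master seed through
`SeedSequence(master, spawn_key=(condition_index, replica))`, giving
byte-identical studies per seed and statistically independent replicas.
Ground truth (stationary occupancies from the balance equations, couplings,
emission means, nominal thresholds) is exported as JSON.

**Langevin mode.**  An overdamped bead on z ∈ [0.05, 2] nm with reflecting
walls, kT = 1 units:

    U(z) = −A_well exp(−((z − 0.15)/0.1)²) − q σ̃ λ_D(c) exp(−z/λ_D(c))

with A_well = 3 kT (hydrogen-bond/polar contact), q the bead charge and
σ̃ = 0.8 kT nm⁻¹ e⁻¹ the surface-charge scale.  The amplitude ∝ λ_D is the
constant-surface-charge-density Debye–Hückel convention
(φ₀ = σλ_D/ε): added salt both shortens the range and lowers the amplitude
of the attraction.  λ_D uses the standard 1:1-electrolyte expression
(≈ 0.96 nm at 100 mM, 298 K; c^(−1/2) scaling).  Euler–Maruyama
integration with D = 1 nm²/ns and dt = 0.15 ps; a documented stability
check requires the per-step drift-plus-diffusion displacement scale to stay
below a quarter of the well width, evaluated on a fine z grid, and rejects
unstable parameter sets.  The salt scan runs all (concentration, seed)
walkers as one vectorised ensemble: 10 seeds × 400 ns per concentration.
The +3 bead's adsorbed fraction (z < 0.3 nm) falls monotonically over
1→200 mM, while the neutral bead varies only within sampling noise (<10%
relative) — the screening mechanism, demonstrated from an energy function
rather than prescribed rates.

## Numerical and design choices

* Internal series format: tidy CSV (`time_ps, d_min_nm, d_res_<RES><i>_nm…,
  rmsd_nm`) with `%.17g` floats for bit-exact round trips, plus a JSON
  manifest (condition, provenance, seed).
* The two-Gaussian fit orders components by mean (μ_C < μ_S enforced by
  relabelling) and bounds means to the fit window and sigmas away from
  zero.
* The stationary solver drops states with neither in- nor out-rates,
  warns on reducible chains, and solves the balance equations with a
  normalisation row.
* Report bundles contain no timestamps; identical configuration + seed
  reproduce every artifact byte for byte (output paths are excluded from
  the configuration hash).
* Problem sizes in the test suite: oracle checks run at full precision on
  small fixtures; recovery tests run one full 9 × 7 × 50 ns study per
  peptide; the 100-study trend-sign sweep uses 20 ps frames (2500 per
  replica), since trend noise is dominated by state-kinetics sampling, not
  frame count.

## Known limitations

* Residue chains are independent: no cooperative or bridged binding
  kinetics, although such microstates still occur combinatorially.
* Emission layers have bounded supports; real distance histograms overlap
  across the boundaries, so real-data state assignment is noisier than the
  synthetic benchmark.
* The generator is not calibrated to reproduce any particular study's
  absolute occupancies or slopes — couplings are order-of-magnitude
  plausible, and synthetic replica-to-replica noise is far smaller than in
  50 ns atomistic runs, so synthetic correlation coefficients are much
  larger than experimentally reported ones.
* Trajectory input supports orthorhombic boxes only; the slab is treated
  as rigid (coordinates from the first frame).
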
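# pepsorb

Trajectory post-processing for peptide adsorption on inorganic slabs, built
around the question: *how does ionic strength modulate the binding of short
bioactive peptides (KRSR, RGD) to a TiO₂ implant surface?*  It is aimed at
molecular-simulation practitioners who have (or want to emulate)
replica-based MD studies of peptide–surface systems across salt conditions.

The package computes, per replica and condition:

* **minimum-image distances** between peptide residues and every slab atom
  in an orthorhombic periodic box, and **backbone RMSD** after Kabsch
  superposition, gated to frames with the peptide within 1 nm of the
  surface;
* the **adsorption time ratio** — the fraction of frames with the peptide
  within 0.3 nm of the slab;
* **residue contact states**: pooled per-residue distance histograms show
  two layers near 0.2 nm (direct contact, C) and 0.4 nm (solvent-separated,
  S) over a bulk tail (non-adsorbed, N).  A two-Gaussian fit
  `a_C N(μ_C, σ_C²) + a_S N(μ_S, σ_S²)` defines the C/S boundary at the
  component intersection; the S/N boundary is 0.5 nm.  Frame-wise label
  strings (e.g. `CNNN`) are tabulated as **microstates** with occurrence
  filtering and low-vs-high-salt comparison;
* **concentration trends**: Pearson r with the exact two-sided t-test
  (`t = r√(n−2)/√(1−r²)`, df = n−2) and OLS slopes in pm/mM or %/mM, one
  point per replica (9 conditions × 7 replicas = 63).

Because cluster-scale trajectories are not shipped, a first-class
`synthetic` module generates studies with known ground truth: per-residue
continuous-time Markov chains over {C, S, N} whose desorption rates grow
with NaCl concentration for charged residues, plus an overdamped Langevin
bead in a screened electrostatic surface potential
`U(z) = −A e^{−((z−z₀)/w)²} − qσ̃λ_D e^{−z/λ_D}` that demonstrates the
Debye-screening mechanism directly.  See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
from pepsorb.metrics import summarize_replica
from pepsorb.states import (residue_distance_histogram, fit_two_gaussian_layers,
                            derive_thresholds, labels_for_series, microstate_table)
from pepsorb.synthetic import SyntheticStudySpec, generate_study
from pepsorb.trends import trend_report

spec = SyntheticStudySpec.for_peptide("KRSR", master_seed=20260919)
series, truth = generate_study(spec)            # 9 conditions x 7 replicas

fit = fit_two_gaussian_layers(residue_distance_histogram(series))
thr = derive_thresholds(fit)
print(f"layers {fit.mu_C:.3f}/{fit.mu_S:.3f} nm, C|S boundary {thr.cs_boundary:.3f} nm")

res = trend_report([summarize_replica(s) for s in series], "adsorption_time_ratio")
print(f"ratio slope {res.slope_display:.3f} %/mM, r={res.pearson_r:+.3f}, n={res.n_points}")
```

prints

```
layers 0.200/0.400 nm, C|S boundary 0.276 nm
ratio slope -0.176 %/mM, r=-0.919, n=63
```

i.e. the fit recovers the generator's 0.2/0.4 nm emission layers, and the
+3-charged peptide's surface residence drops by ~0.18 percentage points of
simulation time per mM of added NaCl (the negative r says the decline is
systematic across all 63 replicas).

The same flow is available from the shell:

```sh
pepsorb all --out out/ --seed 1 --peptide KRSR --peptide RGD
```

and as a narrated analysis under `analysis/` (`01_simulate_studies.py` …
`05_langevin_screening.py`), which writes its tables to `results/`.

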
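#!/usr/bin/env python
"""Generate the two synthetic adsorption studies (KRSR and RGD).

Each study follows the reference design: nine NaCl concentrations from
1 to 200 mM, seven independent replicas per condition, 50 ns per replica at
a 10 ps frame interval.  Charged residues (K/R) carry a positive desorption
salt coupling; neutral residues are essentially salt-blind.  Series files
and ground truth land in scratch/study/ (regenerable; only summary tables
are kept under results/).
"""

from pathlib import Path

from pepsorb.synthetic import SyntheticStudySpec, generate_study

SEED = 20260919
OUT = Path(__file__).resolve().parent.parent / "scratch" / "study"


def main() -> None:
    for pep in ("KRSR", "RGD"):
        spec = SyntheticStudySpec.for_peptide(pep, master_seed=SEED)
        series, truth = generate_study(spec, out_dir=OUT)
        n_frames = sum(s.n_frames for s in series)
        print(f"{pep}: {len(series)} replicas "
              f"({len(spec.concentrations)} concentrations x {spec.replicas}), "
              f"{n_frames:,} frames total -> {OUT}")
        for c in (min(spec.concentrations), max(spec.concentrations)):
            occ = truth.occupancies[float(c)]
            print(f"  true C occupancy at {c:g} mM: "
                  + ", ".join(f"{r}={occ[i, 0]:.3f}"
                              for i, r in enumerate(spec.residue_names)))


if __name__ == "__main__":
    main()
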
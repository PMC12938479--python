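#!/usr/bin/env python
"""Screened-electrostatics mechanism demonstration.

Overdamped Langevin bead above a charged surface: a +3 bead (KRSR-like)
loses adsorbed fraction monotonically as NaCl shortens the Debye length,
while a neutral bead held only by a short-range well is salt-insensitive.
Writes results/langevin_salt_scan.csv.
"""

import csv
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from pepsorb.synthetic import LangevinSurfaceModel, debye_length, \
    langevin_salt_scan

SEED = 20260919
CONCS = (1.0, 50.0, 100.0, 150.0, 200.0)
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    print("Debye length: "
          + ", ".join(f"{c:g} mM -> {debye_length(c):.2f} nm" for c in CONCS))
    rows = []
    for label, charge in (("charged_+3", 3.0), ("neutral", 0.0)):
        scan = langevin_salt_scan(LangevinSurfaceModel(bead_charge=charge),
                                  CONCS, n_seeds=10, duration_ns=400.0,
                                  base_seed=SEED)
        fracs = [f for _, f in scan]
        rho = spearmanr(list(CONCS), fracs).statistic
        rel = (max(fracs) - min(fracs)) / np.mean(fracs)
        print(f"{label}: adsorbed fraction "
              + ", ".join(f"{f:.3f}" for f in fracs)
              + f"  (spearman {rho:+.2f}, relative variation {100 * rel:.1f}%)")
        for c, f in scan:
            rows.append({"bead": label, "nacl_mM": c, "adsorbed_fraction": f})
    out = ROOT / "langevin_salt_scan.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with out.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    print(f"scan table -> {out}")


if __name__ == "__main__":
    main()
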
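#!/usr/bin/env python
"""Residue contact-state classification and microstate tables.

Pools per-residue distance histograms for each peptide, fits the two
Gaussian layers near 0.2 and 0.4 nm, derives the contact/solvent-separated
boundary from the component intersection (the non-adsorbed boundary is fixed
at 0.5 nm), labels every frame, and tabulates combinatorial microstates at
the lowest and highest salt plus their comparison.  Tables land in results/.
"""

from pathlib import Path

from pepsorb.series import read_study_dir
from pepsorb.states import (
    compare_conditions, derive_thresholds, fit_two_gaussian_layers,
    labels_for_series, microstate_table, residue_distance_histogram,
    write_fit_diagnostics,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    series = read_study_dir(ROOT.parent / "scratch" / "study")
    for pep in ("KRSR", "RGD"):
        pep_series = [s for s in series if s.condition.peptide_id == pep]
        residue_names = pep_series[0].residue_names
        hist = residue_distance_histogram(pep_series)
        fit = fit_two_gaussian_layers(hist)
        thr = derive_thresholds(fit)
        write_fit_diagnostics(fit, thr, ROOT / f"fit_{pep}.json")
        print(f"{pep}: layers at {fit.mu_C:.3f} / {fit.mu_S:.3f} nm, "
              f"C|S boundary {thr.cs_boundary:.3f} nm, "
              f"S|N boundary {thr.sn_boundary:.2f} nm")

        concs = sorted({s.condition.nacl_mM for s in pep_series})
        tables = {}
        for c in (concs[0], concs[-1]):
            cond = [s for s in pep_series if s.condition.nacl_mM == c]
            tables[c] = microstate_table(labels_for_series(cond, thr),
                                         peptide_id=pep,
                                         residue_names=residue_names)
            top = list(tables[c].filtered.items())[:3]
            shown = ", ".join(f"{s}={100 * f:.1f}%" for s, f in top)
            print(f"  {c:g} mM top microstates: {shown}")
        comp = compare_conditions(tables[concs[0]], tables[concs[-1]])
        out = ROOT / f"microstate_comparison_{pep}.csv"
        comp.to_csv(out, index=False, float_format="%.17g")
        all_n = "N" * len(residue_names)
        row = comp.set_index("microstate").loc[all_n]
        print(f"  non-adsorbed ({all_n}) fraction: "
              f"{100 * row.rate_low:.2f}% -> {100 * row.rate_high:.2f}% "
              f"(low -> high salt) -> {out.name}")


if __name__ == "__main__":
    main()
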
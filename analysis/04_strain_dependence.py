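#!/usr/bin/env python
"""Pre-compression stiffening: K_a as a linear function of axial strain.

Refits the S-FKV model at each of the six axial pre-strains and regresses
the springpot coefficient on pre-strain, K_a = k0 (1 + b eps_A).  Writes
results/strain_dependence.csv.
"""

import argparse
from pathlib import Path

from organrheo.fitting import fit_strain_dependence, fit_sweep
from organrheo.io import read_sweep_table, stage_log, write_report
from organrheo.preprocess import detect_inertial_cutoff, truncate_at_cutoff
from organrheo.profiles import ORGANS

STRAINS = (0.5, 2.5, 4.5, 6.5, 8.5, 10.5)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/strain_dependence.csv"))
    args = ap.parse_args()

    rows = []
    for organ in ORGANS:
        pairs = []
        for eps in STRAINS:
            sweep = read_sweep_table(args.data_dir / f"{organ}_freq_sweep_eps{eps:g}.csv", "frequency")
            sweep = truncate_at_cutoff(sweep, detect_inertial_cutoff(sweep))
            pairs.append((eps, fit_sweep(sweep).params.k_alpha / 1e3))  # kPa
        dep = fit_strain_dependence(pairs)
        rows.append({"organ": organ, "k0_kpa": round(dep.k0, 3), "b_per_pct": round(dep.b, 3),
                     "fit_r2": round(dep.fit_r2, 4)})
        stage_log("strain-dependence", **rows[-1])
        print(f"{organ:>7}: k0 = {rows[-1]['k0_kpa']} kPa.s^a, b = {rows[-1]['b_per_pct']} /% "
              f"(r2 = {rows[-1]['fit_r2']})")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_report(rows, args.out, "csv")


if __name__ == "__main__":
    main()
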
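#!/usr/bin/env python
"""Fit the three candidate models and summarise S-FKV parameters per organ.

For each organ's contact-strain frequency sweep, fits S-FKV, FKV and SLS
and reports the ranking; then refits S-FKV across all six pre-strain sweeps
and writes the across-sweep parameter summary.  Outputs:
results/model_comparison.csv and results/sfkv_parameters.csv.
"""

import argparse
from pathlib import Path

from organrheo.fitting import compare_models, fit_sweep, make_parameter_table
from organrheo.io import read_sweep_table, stage_log, write_report
from organrheo.preprocess import detect_inertial_cutoff, truncate_at_cutoff
from organrheo.profiles import ORGANS

STRAINS = (0.5, 2.5, 4.5, 6.5, 8.5, 10.5)


def read_clean(path):
    """Read a frequency sweep and drop the inertial-artifact band."""
    sweep = read_sweep_table(path, "frequency")
    return truncate_at_cutoff(sweep, detect_inertial_cutoff(sweep))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    ranking_rows, fits = [], {}
    for organ in ORGANS:
        sweep = read_clean(args.data_dir / f"{organ}_freq_sweep_eps0.5.csv")
        for rank, fr in enumerate(compare_models(sweep), 1):
            ranking_rows.append({"organ": organ, "rank": rank, "model": fr.model_id,
                                 "r2": round(fr.r2, 4), "residual_norm": round(fr.residual_norm, 4)})
        fits[organ] = [
            fit_sweep(read_clean(args.data_dir / f"{organ}_freq_sweep_eps{eps:g}.csv"))
            for eps in STRAINS
        ]
        stage_log("fit", organ=organ, best=ranking_rows[-3]["model"])

    write_report(ranking_rows, args.out_dir / "model_comparison.csv", "csv")
    table = make_parameter_table(fits)
    write_report(table, args.out_dir / "sfkv_parameters.csv", "csv")

    for organ in ORGANS:
        best = next(r for r in ranking_rows if r["organ"] == organ and r["rank"] == 1)
        print(f"{organ:>7}: best model {best['model']} (r2={best['r2']})")
    print("\nS-FKV parameters across pre-strains (mean ± sd):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
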
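#!/usr/bin/env python
"""Data-quality pass over the simulated sessions.

For each organ: detect the linear viscoelastic limit from the strain sweep,
check the frequency sweeps for inertial artifacts, and convert the 0.1 N
contact force to an axial pre-strain.  Writes results/preprocessing.csv.
"""

import argparse
from pathlib import Path

from organrheo.io import read_sweep_table, stage_log, write_report
from organrheo.preprocess import SampleGeometry, contact_axial_state, detect_inertial_cutoff, detect_lve_limit
from organrheo.profiles import ORGANS, get_profile


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/preprocessing.csv"))
    args = ap.parse_args()

    rows = []
    for organ in ORGANS:
        prof = get_profile(organ)
        strain_sweep = read_sweep_table(args.data_dir / f"{organ}_strain_sweep.csv", "strain")
        freq_sweep = read_sweep_table(args.data_dir / f"{organ}_freq_sweep_eps0.5.csv", "frequency")
        geom = SampleGeometry(diameter=prof.diameter, thickness=prof.thickness, organ=organ,
                              elastic_modulus=prof.elastic_modulus, contact_force=0.1)
        stress, strain = contact_axial_state(geom)
        rows.append({
            "organ": organ,
            "lve_limit_pct": detect_lve_limit(strain_sweep),
            "inertial_cutoff_hz": detect_inertial_cutoff(freq_sweep),
            "axial_stress_pa": stress,
            "contact_axial_strain_pct": round(strain, 1),
        })
        stage_log("preprocess", **rows[-1])

    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_report(rows, args.out, "csv")
    for r in rows:
        print(f"{r['organ']:>7}: LVE limit {r['lve_limit_pct']:.3g} % strain, "
              f"inertial cutoff {r['inertial_cutoff_hz']}, "
              f"contact strain {r['contact_axial_strain_pct']} %")


if __name__ == "__main__":
    main()
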
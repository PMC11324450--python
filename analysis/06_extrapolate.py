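#!/usr/bin/env python
"""Extrapolate the fitted storage modulus to literature elastography bands.

Evaluates each organ's S-FKV storage modulus (Hz convention) at the
frequency bands where published elastography / shear-testing studies report
shear moduli, giving the comparison column of the study's literature table.
Writes results/extrapolation.csv.
"""

import argparse
from pathlib import Path

from organrheo.io import stage_log, write_report
from organrheo.profiles import LITERATURE_BANDS, ORGANS, get_profile
from organrheo.relaxation import extrapolate_storage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/extrapolation.csv"))
    args = ap.parse_args()

    rows = []
    for organ in ORGANS:
        params = get_profile(organ).params
        for label, (f_lo, f_hi) in LITERATURE_BANDS[organ]:
            res = extrapolate_storage(params, [f_lo, f_hi])
            rows.append({"organ": organ, "study": label, "f_min_hz": f_lo, "f_max_hz": f_hi,
                         "storage_min_kpa": res.range_kpa[0], "storage_max_kpa": res.range_kpa[1]})
    stage_log("extrapolate", n_bands=len(rows))

    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_report(rows, args.out, "csv")
    for r in rows:
        band = (f"{r['f_min_hz']:g} Hz" if r["f_min_hz"] == r["f_max_hz"]
                else f"{r['f_min_hz']:g}-{r['f_max_hz']:g} Hz")
        pred = (f"{r['storage_min_kpa']:.2f}" if r["storage_min_kpa"] == r["storage_max_kpa"]
                else f"{r['storage_min_kpa']:.2f}-{r['storage_max_kpa']:.2f}")
        print(f"{r['organ']:>7} {band:>16}: {pred} kPa  ({r['study']})")


if __name__ == "__main__":
    main()
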
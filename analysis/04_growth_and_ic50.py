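#!/usr/bin/env python
"""Doubling time and cisplatin dose-response quantitation.

Reads the growth curves from 01_simulate_inputs.py, estimates the
vehicle doubling time from the log-phase, computes the AUC at each drug
concentration and fits the four-parameter logistic dose-response,
reporting the IC50. Writes results/dose_response.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from cinpipe import io
from cinpipe.growth import (curve_auc, curves_from_frame, doubling_time,
                            fit_dose_response)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    frame = io.read_growth_csv(args.inputs / "growth.csv")
    aucs: dict[float, list[float]] = {}
    dts = []
    for curve in curves_from_frame(frame):
        aucs.setdefault(curve.concentration_uM, []).append(curve_auc(curve))
        if curve.concentration_uM == 0.0:
            dts.append(doubling_time(curve).doubling_time_h)
    print(f"vehicle doubling time: {np.mean(dts):.2f} h "
          f"(replicates: {', '.join(f'{d:.2f}' for d in dts)})")

    mean_auc = {c: float(np.mean(v)) for c, v in aucs.items()}
    vehicle = mean_auc.pop(0.0)
    fit = fit_dose_response(sorted(mean_auc.items()), vehicle_auc=vehicle)
    print(f"cisplatin IC50 = {fit.ic50_uM:.3f} uM "
          f"(hill {fit.hill:.2f}, top {fit.top:.1f}%, bottom {fit.bottom:.1f}%)")

    with open(args.out / "dose_response.tsv", "w") as fh:
        fh.write("concentration_uM\tauc_pct_vehicle\n")
        for c, a in sorted(mean_auc.items()):
            fh.write(f"{c:.6g}\t{100 * a / vehicle:.2f}\n")
        fh.write(f"# doubling_time_h\t{np.mean(dts):.3f}\n")
        fh.write(f"# ic50_uM\t{fit.ic50_uM:.4f}\n")
    print(f"wrote {args.out / 'dose_response.tsv'}")


if __name__ == "__main__":
    main()
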
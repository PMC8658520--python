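#!/usr/bin/env python
"""Summarize the diameter/length trends of peak peri-implant stress.

Pivots the sweep summary into a lengths x diameters table, verifies the
two headline monotonicity properties (peak equivalent stress decreases
with diameter at every length, and does not increase with length at any
diameter), and writes results/peak_stress_by_design.csv plus a trend
figure under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary = pd.read_csv(RESULTS / "sweep" / "summary.csv")
    pivot = summary.pivot(
        index="length_mm", columns="diameter_mm", values="peak_vm_mpa"
    )
    pivot.to_csv(RESULTS / "peak_stress_by_design.csv", float_format="%.4f")

    print("Peak peri-implant equivalent stress (MPa):")
    print(pivot.round(2).to_string())

    dec_in_d = all(
        np.all(np.diff(pivot.loc[l].to_numpy()) < 0) for l in pivot.index
    )
    noninc_in_l = all(
        np.all(np.diff(pivot[d].to_numpy()) <= 0) for d in pivot.columns
    )
    neck = (summary["region"] == "neck").all()
    print(f"strictly decreasing in diameter at every length: {dec_in_d}")
    print(f"non-increasing in length at every diameter:      {noninc_in_l}")
    print(f"peak located at the implant neck in all designs: {neck}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        for d in pivot.columns:
            ax.plot(pivot.index, pivot[d], marker="o", label=f"d = {d:g} mm")
        ax.set_xlabel("implant length (mm)")
        ax.set_ylabel("peak peri-implant von Mises stress (MPa)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(RESULTS / "figure_peak_stress.png", dpi=150)
        print(f"wrote {RESULTS / 'figure_peak_stress.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the trend figure")


if __name__ == "__main__":
    main()
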
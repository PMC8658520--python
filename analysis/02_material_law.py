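#!/usr/bin/env python
"""Tabulate the HU -> density -> Young's-modulus calibration.

Samples the piecewise bone constitutive law over the density range the
phantom produces, records the branch-boundary discontinuities, and writes
results/material_law.csv (density, branch, modulus) for plotting.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from implantfem.material_model import density_to_modulus, density_branch

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rho = np.linspace(0.0, 1.2, 1201)
    df = pd.DataFrame(
        {
            "density_gfcc": rho,
            "branch": density_branch(rho),
            "youngs_modulus_mpa": density_to_modulus(rho),
        }
    )
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "material_law.csv", index=False, float_format="%.6g")

    print("modulus at zero density:", density_to_modulus(0.0), "MPa")
    for edge in (0.27, 0.6):
        below = density_to_modulus(edge - 1e-12)
        above = density_to_modulus(edge + 1e-12)
        at = density_to_modulus(edge)
        print(
            f"branch boundary rho = {edge}: E({edge}-) = {below:.1f}, "
            f"E({edge}) = {at:.1f}, E({edge}+) = {above:.1f} MPa "
            f"(jump {100 * abs(above - below) / max(below, above):.1f}%)"
        )
    print(f"wrote {RESULTS / 'material_law.csv'} ({len(df)} rows)")


if __name__ == "__main__":
    main()
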
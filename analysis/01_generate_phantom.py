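#!/usr/bin/env python
"""Build and segment the synthetic mandibular-segment CT phantom.

Generates the default phantom (0.39 mm voxels, cortical shell, noisy
trabecular interior, one molar-sized tooth), threshold-segments it, and
records the tissue composition and the constitutive-branch coverage of the
bone voxels.  Writes results/phantom_stats.json and a NIfTI copy of the
segmented volume under scratch/ for visual inspection.
"""

import json
from pathlib import Path

import numpy as np

import implantfem as ifm
from implantfem.material_model import hu_to_density, density_branch
from implantfem.pipeline import DEFAULT_BONE_THRESHOLD_HU, DEFAULT_TOOTH_THRESHOLD_HU

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    params = ifm.MandiblePhantomParams()
    volume = ifm.generate_mandible_volume(params)
    segmented = ifm.segment_roi(
        volume, DEFAULT_BONE_THRESHOLD_HU, DEFAULT_TOOTH_THRESHOLD_HU
    )

    bone_ct = segmented.ct_values[segmented.labels == 1]
    rho = hu_to_density(bone_ct)
    branches = density_branch(rho)
    branch_fractions = {
        "low_power": float(np.mean(branches == 1)),
        "linear": float(np.mean(branches == 2)),
        "high_power": float(np.mean(branches == 3)),
    }

    stats = {
        "extents_voxels": list(params.extents),
        "spacing_mm": params.spacing,
        "bone_height_mm": params.bone_height_mm,
        "label_counts": segmented.label_counts(),
        "bone_density_gfcc": {
            "min": float(rho.min()),
            "mean": float(rho.mean()),
            "max": float(rho.max()),
        },
        "constitutive_branch_fractions": branch_fractions,
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "phantom_stats.json").write_text(json.dumps(stats, indent=1))

    SCRATCH.mkdir(exist_ok=True)
    ifm.write_volume(segmented, SCRATCH / "phantom_segmented.nii.gz")

    print(f"phantom: {params.extents} voxels at {params.spacing} mm")
    print(f"label counts: {stats['label_counts']}")
    print(f"bone density range (gf/cc): {rho.min():.3f} .. {rho.max():.3f}")
    print(f"constitutive branch fractions: {branch_fractions}")
    print("all three nonzero branches populated:",
          all(v > 0 for v in branch_fractions.values()))


if __name__ == "__main__":
    main()
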
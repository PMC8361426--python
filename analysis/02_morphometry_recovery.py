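"""Compression-volume morphometry on noiseless and noisy cord phantoms.

Sweeps compression extent (3–15 slices) and depth (20–60% area loss),
runs the slope-rule detector, and compares detected limits and volume
deficit against the analytic ground truth. Then repeats one case across
20 noisy phantoms (0.2 mm surface roughness) to measure the metric's
repeatability. Writes results/morphometry_recovery.csv and a profile plot.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cordbold import synth
from cordbold.morphometry import analyze_mask
from cordbold.viz import plot_area_profile

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for extent in (3, 5, 9, 15):
        for reduction in (0.2, 0.4, 0.6):
            spec = synth.CordPhantomSpec(
                n_slices=60,
                compressions=(
                    synth.CompressionSpec(
                        center_slice=30, extent_slices=extent, max_area_reduction=reduction
                    ),
                ),
            )
            mask, truth = synth.make_cord_phantom(spec)
            profile, regions = analyze_mask(mask)
            det, tru = regions[0], truth[0]
            rows.append(
                {
                    "extent_slices": extent,
                    "area_reduction": reduction,
                    "edge_error_slices": max(abs(det.z_lo - tru.z_lo), abs(det.z_hi - tru.z_hi)),
                    "deficit_true_mm3": tru.volume_deficit,
                    "deficit_measured_mm3": det.volume_deficit,
                    "deficit_error_pct": 100
                    * abs(det.volume_deficit - tru.volume_deficit)
                    / tru.volume_deficit,
                }
            )
    grid = pd.DataFrame(rows)
    grid.to_csv(OUT / "morphometry_recovery.csv", index=False)
    print(grid.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(
        f"\nworst edge error {grid.edge_error_slices.max()} slice(s); "
        f"worst deficit error {grid.deficit_error_pct.max():.2f}%"
    )

    deficits = []
    for s in range(20):
        spec = synth.CordPhantomSpec(
            n_slices=60,
            surface_noise_sd=0.2,
            seed=seed + s,
            compressions=(
                synth.CompressionSpec(center_slice=30, extent_slices=7, max_area_reduction=0.4),
            ),
        )
        mask, _ = synth.make_cord_phantom(spec)
        profile, regions = analyze_mask(mask)
        deficits.append(sum(r.volume_deficit for r in regions))
    cv = np.std(deficits) / np.mean(deficits)
    print(f"noisy-phantom deficit CV over 20 seeds: {cv:.2%}")
    plot_area_profile(profile, regions, OUT / "area_profile_example.png")
    print(f"wrote {OUT / 'morphometry_recovery.csv'}")


if __name__ == "__main__":
    main()
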
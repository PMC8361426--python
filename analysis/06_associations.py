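"""Cohort association analysis: effect-size recovery and the full pipeline.

First checks the cohort generator against its target correlation
(rho = 0.56 between compression volume and percent BOLD at n = 23, the
headline effect size this analysis emulates), then runs the complete
synthetic pipeline — phantoms through GLM to the correlation battery —
and writes its battery plus a compression-vs-activation scatter.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from cordbold import synth
from cordbold.association import correlation_battery
from cordbold.pipeline import DEMO_CONFIG, run_pipeline
from cordbold.viz import plot_association

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(500):
        c = synth.make_cohort(synth.CohortSimSpec(seed=int(rng.integers(2**31))))
        rs.append(np.corrcoef(c["compression_volume"], c["percent_bold"])[0, 1])
    print(f"cohort generator: mean r {np.mean(rs):.3f} over 500 draws (target 0.56, n=23)")

    cohort = synth.make_cohort(synth.CohortSimSpec(seed=seed))
    battery = correlation_battery(
        cohort, [("compression_volume", "percent_bold"), ("compression_volume", "voa"),
                 ("mjoa", "percent_bold"), ("mjoa", "compression_volume")]
    )
    battery.to_csv(OUT / "cohort_battery.csv", index=False)
    print(battery.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    manifest = run_pipeline(replace(DEMO_CONFIG, out_dir=str(OUT / "pipeline"), seed=seed))
    full = pd.read_csv(OUT / "pipeline" / "association" / "battery.csv")
    print("\nfull synthetic pipeline battery (8 subjects, both hands):")
    print(full.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    merged = pd.read_csv(OUT / "pipeline" / "association" / "cohort.csv")
    plot_association(
        merged, "compression_volume", "M1_percent_bold_left", OUT / "compression_vs_m1_bold.png"
    )
    print(f"wrote {OUT / 'cohort_battery.csv'} and pipeline outputs under {OUT / 'pipeline'}")


if __name__ == "__main__":
    main()
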
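#!/usr/bin/env python
"""Wavelength-versus-length regimes of the analyzed cohort.

Fits the λ̂(L) relation separately below and above the 15 μm saturation
length with the two-standard-error slope rule: the proportional regime
should show a significant slope near 1, the saturated regime a slope not
distinguishable from 0.  Writes results/regimes.json and a λ-vs-L figure.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from axobeat import slope_significance

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    df = pd.read_csv(RESULTS / "cohort_summary.csv")
    below = df[df.length_um < 15.0]
    above = df[df.length_um > 15.0]
    prop = slope_significance(below.length_um, below.lambda_um)
    sat = slope_significance(above.length_um, above.lambda_um)

    out = {
        "proportional_regime": {
            "n": int(len(below)),
            "slope": prop.slope,
            "slope_se": prop.slope_se,
            "intercept": prop.intercept,
            "significant": prop.significant,
        },
        "saturated_regime": {
            "n": int(len(above)),
            "slope": sat.slope,
            "slope_se": sat.slope_se,
            "intercept": sat.intercept,
            "significant": sat.significant,
            "mean_lambda_um": float(above.lambda_um.mean()),
        },
    }
    (RESULTS / "regimes.json").write_text(json.dumps(out, indent=1))

    print(f"L < 15 μm: slope {prop.slope:.3f} ± {prop.slope_se:.3f} "
          f"({'significant' if prop.significant else 'not significant'})")
    print(f"L > 15 μm: slope {sat.slope:.3f} ± {sat.slope_se:.3f} "
          f"({'significant' if sat.significant else 'not significant'}); "
          f"λ saturates near {above.lambda_um.mean():.2f} μm")

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, g in df.groupby("group"):
        ax.errorbar(g.length_um, g.lambda_um, yerr=g.sem_um, fmt="o", label=group)
    ax.axline((8, 8), slope=1, ls="--", c="gray", lw=0.8, label="λ = L")
    ax.set_xlabel("length L (μm)")
    ax.set_ylabel("wavelength λ̂ (μm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "wavelength_vs_length.png", dpi=150)
    print(f"wrote {RESULTS / 'regimes.json'} and wavelength_vs_length.png")


if __name__ == "__main__":
    main()
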
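#!/usr/bin/env python
"""Closed-form mechanics estimates for a saturated-wavelength axoneme.

Drag coefficients and flexural rigidity are literature-typical magnitudes
for a demembranated axoneme in aqueous buffer (NOT fitted here): ξ⊥ ≈ 2ξ∥
with ξ∥ ≈ 0.0017 pN·s/μm², κ ≈ 400 pN·μm².  Beat parameters come from the
analyzed cohort where available.  Writes results/mechanics.json.
"""

import json
from pathlib import Path

import pandas as pd

from axobeat import (
    MechanicsInput,
    machin_number,
    propulsive_force_per_length,
    swimming_speed,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

# literature-typical magnitudes, clearly non-measured placeholders
XI_PERP = 0.0034  # pN·s/μm²
XI_PAR = 0.0017  # pN·s/μm²
KAPPA = 400.0  # pN·μm²
AMPLITUDE_UM = 1.5  # transverse amplitude y0


def main() -> None:
    summary = RESULTS / "cohort_summary.csv"
    if summary.exists():
        df = pd.read_csv(summary)
        sat = df[df.length_um >= 15.0]
        lam = float(sat.lambda_um.mean())
        freq = float(df.frequency_hz.mean())
        length = float(sat.length_um.mean())
    else:  # standalone defaults at the saturation scale
        lam, freq, length = 15.0, 65.0, 18.0

    inp = MechanicsInput(
        frequency_hz=freq, lambda_um=lam, xi_perp=XI_PERP, xi_par=XI_PAR,
        kappa_pn_um2=KAPPA, amplitude_um=AMPLITUDE_UM, length_um=length,
    )
    ma = machin_number(inp)
    fl = propulsive_force_per_length(inp)
    v = swimming_speed(fl * length, length, XI_PAR)
    out = {
        "inputs": {"frequency_hz": freq, "lambda_um": lam, "length_um": length,
                   "xi_perp": XI_PERP, "xi_par": XI_PAR, "kappa_pn_um2": KAPPA,
                   "amplitude_um": AMPLITUDE_UM},
        "machin_number": ma,
        "force_per_length_pn_um": fl,
        "swimming_speed_um_s": v,
    }
    (RESULTS / "mechanics.json").write_text(json.dumps(out, indent=1))
    print(f"Ma = {ma:.3f} (bending-dominated if ≪ 1)")
    print(f"F/L = {fl:.3f} pN/μm;  v = {v:.1f} μm/s")


if __name__ == "__main__":
    main()
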
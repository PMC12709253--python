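#!/usr/bin/env python
"""Simulate a cohort of beating axonemes spanning the 8-25 μm length range.

Two mock preparations (different RNG seeds) of seven axonemes each, with the
wavelength following the saturating law λ0 = min(L, 15 μm), static curvature
0.2 rad/μm, rigid-body rotation 1 rad/s, 65 Hz beats, and mild angle noise
(±10% of the amplitude) emulating digitization error.  Centerline CSVs are
large and transient, so they go under scratch/; the manifest of true
parameters goes under results/ for later comparison.
"""

import json
from pathlib import Path

import numpy as np

from axobeat import SyntheticBeatParams, generate_centerlines
from axobeat.io import write_centerlines_csv

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

LENGTHS_UM = np.linspace(8.0, 25.0, 7)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    manifest = []
    for prep, base_seed in [("prep_a", 100), ("prep_b", 200)]:
        for i, L in enumerate(LENGTHS_UM):
            params = SyntheticBeatParams(
                length_um=float(L),
                wavelength_um=float(min(L, 15.0)),
                amplitude_rad=0.5,
                frequency_hz=65.0,
                static_curvature_per_um=0.2,
                rotation_rate_rad_s=1.0,
                noise_level=0.1,
                seed=base_seed + i,
            )
            name = f"{prep}_axoneme_{i:02d}.csv"
            write_centerlines_csv(generate_centerlines(params), OUT / name)
            manifest.append({"file": name, "group": prep, **params.to_dict()})
            print(f"{name}: L={L:.1f} μm, λ0={min(L, 15.0):.1f} μm")
    (RESULTS / "cohort_manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"\nwrote {len(manifest)} centerline files to {OUT}")


if __name__ == "__main__":
    main()
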
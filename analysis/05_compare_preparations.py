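#!/usr/bin/env python
"""Zero-crossing comparison of the two simulated preparations.

Both preparations were drawn from the same saturating λ(L) law, so the test
should not find a significant difference.  Writes results/crossing_test.json.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from axobeat import LengthWavelengthDataset, bonferroni, crossing_test

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    df = pd.read_csv(RESULTS / "cohort_summary.csv")
    a = LengthWavelengthDataset.from_dataframe(df, group="prep_a")
    b = LengthWavelengthDataset.from_dataframe(df, group="prep_b")
    res = crossing_test(a, b)
    res.p_adjusted = float(bonferroni([res.p_value], m=1)[0])
    (RESULTS / "crossing_test.json").write_text(json.dumps(asdict(res), indent=1))
    verdict = "significant" if res.p_adjusted < 0.05 else "not significant"
    print(f"crossings n={res.n_crossings} of N={res.N}; "
          f"t={res.t_stat:.3f} (df={res.df}); p={res.p_value:.4f} -> {verdict}")


if __name__ == "__main__":
    main()
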
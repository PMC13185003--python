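#!/usr/bin/env python
"""Qualitative-structure recovery: critical windows and early shifts.

Two planted-structure studies. First, the distributed-lag model is asked
to localize a late-gestation (weeks 30-39) protective-Hb window from 3
noisy visits per woman. Second, the stratified additive mixed model is
asked to flag a pre-week-20 group Hb shift without flagging the
post-week-20 range. Writes results/window_structure.csv.
"""

from pathlib import Path

import pandas as pd

from hbtraj import validation

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260404

loc = validation.dlnm_window_localization(reps=20, n_subjects=2000, seed=SEED)
det = validation.gamm_shift_detection(reps=10, n_subjects=5000, seed=SEED + 1)

table = pd.DataFrame(
    [
        ("dlnm_peak_in_window_rate", loc["hit_rate"], loc["reps"],
         "peak |log OR| falls in the true weeks-30-39 window"),
        ("gamm_early_detection_rate", det["early_detection_rate"], det["reps"],
         "bands separate before week 16 when a pre-week-20 shift exists"),
        ("gamm_late_false_rate", det["late_false_rate"], det["reps"],
         "bands separate after week 26 (should be rare: no late shift)"),
    ],
    columns=["quantity", "rate", "replicates", "meaning"],
)
out = ROOT / "results" / "window_structure.csv"
out.parent.mkdir(exist_ok=True)
table.to_csv(out, index=False)
print(table.to_string(index=False))
print(f"\n-> {out}")
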
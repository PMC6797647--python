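"""Batch estimation plus the standardized accuracy report.

Generates six synthetic recordings (three resting, three exercising),
estimates each, and summarises agreement with the known reference rates:
Spearman correlation, mean +/- SD absolute difference per condition,
Bland-Altman limits, and AUC separability of the two conditions.
"""

import tempfile
from pathlib import Path

import pandas as pd

from pulsecam import (
    PipelineConfig,
    abs_diff_stats,
    auc_separability,
    bland_altman,
    run_batch,
    spearman_corr,
)
from pulsecam.synth import SynthSpec, write_synth_dataset

tmp = Path(tempfile.mkdtemp())
conditions = [("rest", 62), ("rest", 71), ("rest", 78), ("ex", 118), ("ex", 132), ("ex", 147)]
specs = [
    SynthSpec(hr_bpm=hr, hr_amp=2.0, noise_sd=1.0, seed=i, duration_s=20.0)
    for i, (_, hr) in enumerate(conditions)
]
manifest = write_synth_dataset(tmp, specs)
manifest["condition"] = [c for c, _ in conditions]

records = run_batch(manifest, PipelineConfig(skin_method="wedge"))
records = records.dropna(subset=["hr_rppg"])

rho = spearman_corr(records["hr_rppg"], records["hr_reference"])
bias, lo, hi, _ = bland_altman(records)
table = abs_diff_stats(records, group_by=["condition"])
auc, sep = auc_separability(
    records.loc[records.condition == "rest", "hr_rppg"],
    records.loc[records.condition == "ex", "hr_rppg"],
)

pd.set_option("display.float_format", "{:.2f}".format)
print(f"Spearman rho (rPPG vs reference): {rho:.3f}")
print(f"Bland-Altman: bias {bias:+.2f} BPM, limits [{lo:.2f}, {hi:.2f}]")
print(table.to_string(index=False))
print(f"rest vs exercise: AUC = {auc:.2f}, separability = {sep:.0f}%")
# rho near 1 and a tight Bland-Altman band mean the estimates track the
# reference; AUC 1.0 means the two conditions are fully distinguishable
# from rPPG heart rate alone.
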
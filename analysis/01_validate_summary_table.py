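#!/usr/bin/env python
"""Load the packaged 33-fermentation summary table, check its internal
consistency, and tabulate performance by operating condition.

Finding: the metric columns are mutually consistent at printed precision
for 32 of 33 rows — F10's Yield(P/S) contradicts its own productivity/
uptake ratio and is flagged, not corrected.  Lowering the temperature
from 37 to 30 degC at D = 0.033 1/h raises the mean product yield from
0.55 to 0.66 g/g and the mean specific productivity from 0.20 to 0.22
g/gDCW/h.
"""

from pathlib import Path

import pandas as pd

from fermstab import load_paper_dataset, validate_records

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

records = load_paper_dataset()
print(f"loaded {len(records)} fermentation records")

flagged = validate_records(records)
for ferm_id, issues in flagged.items():
    for issue in issues:
        print(f"flagged: {issue}")

df = pd.DataFrame([{
    "ferm_id": r.ferm_id, "dilution_rate": r.dilution_rate,
    "temperature": r.temperature, "stability_duration": r.stability_duration,
    "yield_ps": r.yield_ps, "specific_productivity": r.specific_productivity,
} for r in records])
means = (df.groupby(["dilution_rate", "temperature"])
           [["stability_duration", "yield_ps", "specific_productivity"]]
           .agg(["count", "mean"]).round(3))
means.to_csv(OUT / "table2_group_means.csv")
print(means)
print(f"\nwrote {OUT / 'table2_group_means.csv'}")
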
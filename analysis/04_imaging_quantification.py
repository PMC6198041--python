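#!/usr/bin/env python
"""Quantify the synthetic imaging cohorts from step 01.

For each cohort (planted 30% CS+ depression, 30% potentiation, null):
per-fly ΔF/F₀ with 2-s pre-odor baselines, 5-s odor-window AUCs,
normalization to the novel odor, and the normality-gated paired CS+ vs CS−
test.  Writes results/imaging_responses.csv and results/imaging_stats.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mbx.imaging import Epoch, FluorescenceTrace, odor_responses, paired_group_test

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"

rows, stats = [], {}
for label in ("depression", "potentiation", "null"):
    df = pd.read_csv(DATA / f"imaging_{label}.csv")
    epochs = [Epoch(**e) for e in
              json.loads((DATA / f"imaging_{label}_epochs.json").read_text())]
    cs_plus, cs_minus = [], []
    for fly_id, grp in df.groupby("fly_id"):
        trace = FluorescenceTrace(grp["F"].to_numpy(), 5.92, epochs,
                                  fly_id=str(fly_id), roi=str(grp["roi"].iloc[0]))
        resp = odor_responses(trace)
        for odor, r in resp.items():
            rows.append({"cohort": label, "fly_id": fly_id, "odor": odor,
                         "auc": r.auc, "normalized_auc": r.normalized_auc})
        cs_plus.append(resp["CS+"].normalized_auc)
        cs_minus.append(resp["CS-"].normalized_auc)
    res = paired_group_test(cs_plus, cs_minus)
    med = float(np.median(np.array(cs_plus) - np.array(cs_minus)))
    stats[label] = {"n": res.n, "test_used": res.test_used,
                    "statistic": res.statistic, "p": res.p,
                    "median_paired_difference": med,
                    "boxplot": res.boxplot}
    print(f"{label}: n={res.n}, {res.test_used}, p={res.p:.3g}, "
          f"median CS+ - CS- = {med:+.3f}")

pd.DataFrame(rows).to_csv(OUT / "imaging_responses.csv", index=False)
(OUT / "imaging_stats.json").write_text(json.dumps(stats, indent=1))
print("wrote imaging_responses.csv and imaging_stats.json")
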
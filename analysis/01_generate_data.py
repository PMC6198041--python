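#!/usr/bin/env python
"""Generate the synthetic study data every later analysis step consumes.

Writes, under results/data/:
  * an EM-style MBON skeleton (SWC) with a planted dendritic root, a
    proximally placed MVP2-input class, a bimodal KC-input class, planted
    axonlets, and the matching synapse-annotation CSV + ground-truth JSON;
  * calcium-imaging cohorts (trace CSV + epoch JSON) for a 30% CS+
    depression group, a 30% potentiation group, and a null group;
  * T-maze count tables for trained (planted PI −0.4) and naive (0) flies.
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from mbx.skeleton import write_swc
from mbx.synth import (
    BehaviorGenSpec,
    ImagingGenSpec,
    SkeletonGenSpec,
    SynapseClassSpec,
    gen_imaging_cohort,
    gen_skeleton,
    gen_tmaze_cohort,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# -- skeleton ---------------------------------------------------------------
classes = (
    SynapseClassSpec("MVP2_input", 80, "post", "dendrite",
                     ("gaussian", 7000.0, 2500.0), "MVP2"),
    SynapseClassSpec("KC_input", 500, "post", "dendrite",
                     ("bimodal", 9000.0, 2500.0, 32000.0, 3000.0, 0.5), "KC"),
    SynapseClassSpec("output", 120, "pre", "axon", ("uniform",), "downstream"),
)
spec = SkeletonGenSpec(name="synthetic_m4", n_nodes=600, seed=SEED,
                       synapse_classes=classes, n_axonlets=3)
skeleton, synapse_table, truth = gen_skeleton(spec)
write_swc(skeleton, OUT / "synthetic_m4.swc")
synapse_table.to_csv(OUT / "synthetic_m4_synapses.csv", index=False)
(OUT / "synthetic_m4_truth.json").write_text(json.dumps({
    "planted_dendritic_root": truth["planted_dendritic_root"],
    "class_of": truth["class_of"],
    "axonlets": [{k: v for k, v in a.items()} for a in truth["axonlets"]],
    "domains": truth["domains"],
}, indent=1, default=str))
print(f"skeleton: {len(skeleton)} nodes, {len(synapse_table)} synapse rows, "
      f"planted root node {truth['planted_dendritic_root']}")

# -- imaging cohorts --------------------------------------------------------
for offset, (label, multiplier) in enumerate(
        (("depression", 0.7), ("potentiation", 1.3), ("null", 1.0))):
    traces, gt = gen_imaging_cohort(ImagingGenSpec(
        csplus_multiplier=multiplier, seed=SEED + 100 * (offset + 1)))
    rows = []
    for trace in traces:
        for i, f in enumerate(trace.samples):
            rows.append({"time_s": i / trace.sampling_rate, "fly_id": trace.fly_id,
                         "roi": trace.roi, "F": f})
    pd.DataFrame(rows).to_csv(OUT / f"imaging_{label}.csv", index=False)
    epochs = [asdict(e) for e in traces[0].epochs]
    (OUT / f"imaging_{label}_epochs.json").write_text(json.dumps(epochs, indent=1))
    print(f"imaging cohort '{label}': {len(traces)} flies, "
          f"planted multiplier {multiplier}")

# -- T-maze counts ----------------------------------------------------------
rows = []
for group, true_pi in (("trained", -0.4), ("naive", 0.0)):
    counts = gen_tmaze_cohort(BehaviorGenSpec(true_pi=true_pi, n_flies=100,
                                              n_groups=12, seed=SEED))
    for rep, c in enumerate(counts):
        rows.append({"group": group, "replicate": rep,
                     "n_csplus_arm": c.n_csplus_arm,
                     "n_csminus_arm": c.n_csminus_arm,
                     "n_nonchoosers": c.n_nonchoosers})
pd.DataFrame(rows).to_csv(OUT / "tmaze_counts.csv", index=False)
print(f"T-maze: {len(rows)} replicates across 2 groups -> tmaze_counts.csv")
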
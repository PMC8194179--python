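#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/: the 20-clone invasion timecourses (hourly,
48 h), one wound-closure series, the qPCR Ct table (LCK plus the
mesenchymal markers), the five RNA-seq count matrices with 20 planted
LCK-consistent genes, and a pair of contact-image batches. Ground truth is
recorded alongside so later steps can score themselves.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from clonotrace import integration, simulate

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

# invasion timecourses ------------------------------------------------------
cohort, truth = simulate.simulate_invasion_cohort(n_clones=20, seed=SEED)
rows = [{"clone_id": tc.clone_id, "time_h": t, "area": a}
        for tc in cohort for t, a in zip(tc.times, tc.areas)]
pd.DataFrame(rows).to_csv(OUT / "invasion.csv", index=False)
with open(OUT / "invasion_truth.json", "w") as fh:
    json.dump(truth.true_t0, fh, indent=2, sort_keys=True)
print(f"invasion: {len(cohort)} clones, onset truth spread "
      f"{min(truth.true_t0.values()):.1f}-{max(truth.true_t0.values()):.1f} h")

# wound closure -------------------------------------------------------------
tc = simulate.simulate_wound(rate=8.0, noise_sd=1.0, seed=SEED)
pd.DataFrame({"sample_id": tc.sample_id, "time_h": tc.times,
              "wound_density_pct": tc.wound_density}
             ).to_csv(OUT / "wound.csv", index=False)
print("wound: planted closure rate 8.0 %/h")

# counts for the five contrasts ---------------------------------------------
matrices, ctruth = simulate.simulate_counts(seed=SEED)
for ds, cm in matrices.items():
    cm.counts.to_csv(OUT / f"counts_{ds}.tsv", sep="\t")
with open(OUT / "counts_truth.json", "w") as fh:
    json.dump(ctruth.planted_genes, fh, indent=2, sort_keys=True)
print(f"counts: 5 contrasts x {matrices['m'].counts.shape}, "
      f"{len(ctruth.planted_genes)} planted LCK-pattern genes")

print(f"inputs written to {OUT}")
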
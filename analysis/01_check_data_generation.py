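#!/usr/bin/env python
"""Verify the data-generating process hits its population targets.

Draws one large complete dataset, checks means, correlations and the proxy
construction, then confirms that every missingness mechanism realizes its
nominal proportion.  Writes results/data_generation_checks.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from missaux import (
    ScenarioConfig,
    generate_complete,
    impose_missing_aux,
    impose_missing_outcome,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = ScenarioConfig(n=200_000, rho_yz=0.7, seed=20240901)
rng = np.random.default_rng(cfg.seed)
d = generate_complete(cfg, rng)

rows = [
    ("mean_y", d.y.mean(), 6.0),
    ("mean_x", d.x.mean(), -3.0),
    ("mean_z", d.z.mean(), 2.0),
    ("sd_y", d.y.std(), 1.0),
    ("corr_xy", np.corrcoef(d.x, d.y)[0, 1], 0.6),
    ("corr_yz", np.corrcoef(d.y, d.z)[0, 1], 0.7),
    ("corr_xz", np.corrcoef(d.x, d.z)[0, 1], 0.0),
    ("mean_w", d.w.mean(), 0.0),
    ("sd_w", d.w.std(), 1.0),
    ("corr_wz", np.corrcoef(d.w, d.z)[0, 1], 0.6 / np.sqrt(1.36)),
]
for mech in (1, 2, 3):
    frac = impose_missing_outcome(d, mech, 0.5).mean()
    rows.append((f"outcome_mech{mech}_missing_frac", frac, 0.5))
for mech in (1, 2, 3):
    frac = impose_missing_aux(d, mech, 0.3, rng=rng).mean()
    rows.append((f"aux_mech{mech}_missing_frac", frac, 0.3))

table = pd.DataFrame(rows, columns=["quantity", "realized", "target"])
table["abs_error"] = (table["realized"] - table["target"]).abs()
table.to_csv(OUT / "data_generation_checks.csv", index=False)

print(table.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
worst = table["abs_error"].max()
print(f"\nAll {len(table)} generator targets realized; worst absolute error {worst:.4f} "
      f"at n={cfg.n}.")
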
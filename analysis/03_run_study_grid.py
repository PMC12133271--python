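#!/usr/bin/env python
"""Run a desk-scale slice of the full factorial design grid.

All nine (outcome mechanism x auxiliary mechanism) panels, two auxiliary
strengths and four missingness proportions, at reduced Monte Carlo size
(n_sim=150, m=20 versus 1000 and 100 at full scale — Monte Carlo SEs are
reported so the loss of precision is explicit).  Writes results/metrics.csv
and results/run_report.json; 04_plot_relative_bias.py consumes the metrics.
"""

import json
import time
from pathlib import Path

from missaux import StudyGrid, run_grid

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

grid = StudyGrid(
    rho_yz=(0.3, 0.7),
    outcome_mech=(1, 2, 3),
    aux_mech=(1, 2, 3),
    pi_z=(0.0, 0.3, 0.6, 0.9),
    n=1000,
    n_sim=150,
    m=20,
    burnin=10,
    seed=20240903,
)

t0 = time.time()
metrics, results, report = run_grid(
    grid, progress_callback=lambda r: print(f"  finished {r.scenario_id}")
)
metrics.to_csv(OUT / "metrics.csv", index=False)
with open(OUT / "run_report.json", "w") as fh:
    json.dump(report, fh, indent=2)

print(f"\n{grid.n_cells} cells, {len(metrics)} metric rows in {time.time() - t0:.0f}s; "
      f"failures: {len(report['failures'])}")
mi = metrics[(metrics.model == "mi_incl") & (metrics.rho_yz == 0.7)]
print("\nMI-with-auxiliary bias at corr(Y,Z)=0.7 by mechanism pair and missing-Z share:")
pivot = mi.pivot_table(index=["outcome_mech", "aux_mech"], columns="pi_z", values="bias")
print(pivot.round(3).to_string())
print(
    "\nReading: where CRA is biased (outcome mechs 1-2) the auxiliary's benefit "
    "erodes as its own missingness grows; where CRA is unbiased (mech 3) an MNAR "
    "auxiliary (aux mech 2) introduces bias, worst near 50% missingness."
)
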
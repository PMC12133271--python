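#!/usr/bin/env python
"""Walk one scenario end to end: the MNAR-auxiliary case that harms MI.

Scenario: outcome missingness driven by the exposure (CRA unbiased),
auxiliary missing not at random (driven by its own value), corr(Y,Z)=0.7,
50% missing in both Y and Z.  Runs a desk-scale batch of replicates and
prints the bias of all three estimators — showing that including the MNAR
auxiliary introduces bias that neither CRA nor MI-without-auxiliary has.
Writes results/single_scenario_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from missaux import FCSConfig, ScenarioConfig, run_scenario, summarize

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = ScenarioConfig(
    n=1000, n_sim=200, outcome_mech=3, aux_mech=2, rho_yz=0.7, pi_z=0.5, seed=20240902
)
fcs = FCSConfig(m=20, burnin=10)

result = run_scenario(cfg, fcs)
rows = summarize(result, true_slope=0.6)
table = pd.DataFrame(
    [
        {
            "model": r.model,
            "bias": r.bias,
            "mcse_bias": r.mcse_bias,
            "empse": r.empse,
            "mean_model_se": r.mean_model_se,
            "mean_fmi": r.mean_fmi,
        }
        for r in rows
    ]
)
table.to_csv(OUT / "single_scenario_metrics.csv", index=False)
print(f"scenario {result.scenario_id}: n={cfg.n}, {cfg.n_sim} replicates, "
      f"m={fcs.m}, burnin={fcs.burnin}\n")
print(table.to_string(index=False, float_format=lambda v: f"{v: .4f}"))

by = {r.model: r for r in rows}
print(
    f"\nCRA and MI-without-auxiliary are unbiased "
    f"(bias {by['cra'].bias:+.4f} and {by['mi_excl'].bias:+.4f}, MC error ~"
    f"{by['cra'].mcse_bias:.4f}); adding the half-missing MNAR auxiliary "
    f"shifts the MI estimate by {by['mi_incl'].bias:+.4f} slope units "
    f"({100 * abs(by['mi_incl'].bias) / 0.6:.0f}% of the true effect 0.6)."
)
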
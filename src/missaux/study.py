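"""Simulation-study orchestration over the full design grid.

One scenario is a cell of the factorial grid (outcome mechanism x auxiliary
mechanism x corr(Y,Z) x auxiliary missingness proportion, plus sensitivity
axes).  Per replicate a fresh dataset is generated, missingness imposed, and
three estimators run:

* ``cra``      — complete records analysis,
* ``mi_excl``  — multiple imputation excluding the auxiliary: Y imputed
  from p(Y|X) alone, Z neither imputed nor used,
* ``mi_incl``  — multiple imputation with the auxiliary: Y from p(Y|X,Z),
  Z from p(Z|Y,X) (or p(Z|Y,X,W) under auxiliary mechanism 3 when the proxy
  is included in the model).

Performance metrics follow standard simulation-study practice: bias with
Monte Carlo SE empSE/sqrt(n_sim), empirical SE with Monte Carlo SE
empSE/sqrt(2(n_sim-1)), the mean model SE, the mean FMI for MI models, and
bias relative to CRA in percent (flagged when the CRA bias is within two
Monte Carlo SEs of zero, where the ratio is unstable).

Seeding: the root seed and the scenario's index in the grid define a
replicate-level seed stream, so every cell is reproducible in isolation and
parallel execution cannot change results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datagen import ScenarioConfig, generate_complete, make_observed
from .engine import FCSConfig, ImputationModelSpec, TermSpec, fcs_impute
from .pooling import cra_fit, mi_estimate

__all__ = [
    "MODELS",
    "StudyGrid",
    "ScenarioResult",
    "MetricRow",
    "run_replicate",
    "run_scenario",
    "summarize",
    "run_grid",
]

MODELS = ("cra", "mi_excl", "mi_incl")

_Y_GIVEN_X = ImputationModelSpec("y", (TermSpec(("x",)),))
_Y_GIVEN_XZ = ImputationModelSpec("y", (TermSpec(("x",)), TermSpec(("z",))))
_Z_GIVEN_YX = ImputationModelSpec("z", (TermSpec(("y",)), TermSpec(("x",))))
_Z_GIVEN_YXW = ImputationModelSpec("z", (TermSpec(("y",)), TermSpec(("x",)), TermSpec(("w",))))


def imputation_specs(aux_mech: int, include_w: bool) -> tuple[ImputationModelSpec, ...]:
    """Models for the MI-with-auxiliary estimator: the proxy W enters the
    model for Z only under auxiliary mechanism 3 (and only if requested)."""
    z_spec = _Z_GIVEN_YXW if (aux_mech == 3 and include_w) else _Z_GIVEN_YX
    return (_Y_GIVEN_XZ, z_spec)


def _replicate_rng(root_seed: int, scenario_index: int, rep_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=(int(root_seed), int(scenario_index), int(rep_index)))


def run_replicate(
    config: ScenarioConfig,
    rep_index: int,
    fcs: FCSConfig,
    *,
    scenario_index: int = 0,
    include_w: bool = True,
    models: tuple[str, ...] = MODELS,
) -> dict[str, tuple[float, float, float]]:
    """One replicate: generate, ampute, estimate.

    Returns ``model -> (slope estimate, SE, fmi)``; the FMI is NaN for CRA.
    The replicate's seed stream is derived from (config.seed,
    scenario_index, rep_index) so replicates are independent and
    individually reproducible.
    """
    ss = _replicate_rng(config.seed, scenario_index, rep_index)
    data_ss, miss_ss, excl_ss, incl_ss = ss.spawn(4)
    complete = generate_complete(config, np.random.default_rng(data_ss))
    observed = make_observed(complete, np.random.default_rng(miss_ss))

    out: dict[str, tuple[float, float, float]] = {}
    if "cra" in models:
        fit = cra_fit(observed)
        out["cra"] = (fit.slope, fit.se, float("nan"))
    if "mi_excl" in models:
        stack = fcs_impute(
            {"y": observed.y, "x": observed.x},
            {"y": observed.m_y},
            (_Y_GIVEN_X,),
            fcs,
            np.random.default_rng(excl_ss),
        )
        pooled = mi_estimate(stack)
        out["mi_excl"] = (pooled.qbar, float(np.sqrt(pooled.t)), pooled.fmi)
    if "mi_incl" in models:
        stack = fcs_impute(
            observed.columns(),
            observed.indicators(),
            imputation_specs(config.aux_mech, include_w),
            fcs,
            np.random.default_rng(incl_ss),
        )
        pooled = mi_estimate(stack)
        out["mi_incl"] = (pooled.qbar, float(np.sqrt(pooled.t)), pooled.fmi)
    return out


@dataclass
class ScenarioResult:
    """Per-replicate estimates for one grid cell; failures are kept, not dropped."""

    scenario_id: str
    config: ScenarioConfig
    estimates: dict[str, np.ndarray]
    ses: dict[str, np.ndarray]
    fmis: dict[str, np.ndarray]
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_sim(self) -> int:
        return next(iter(self.estimates.values())).shape[0]


def scenario_id(config: ScenarioConfig, include_w: bool = True) -> str:
    sid = (
        f"om{config.outcome_mech}_am{config.aux_mech}"
        f"_rhoyz{config.rho_yz:g}_piz{config.pi_z:g}"
    )
    if config.pi_y != 0.5:
        sid += f"_piy{config.pi_y:g}"
    if config.rho_xy != 0.6:
        sid += f"_rhoxy{config.rho_xy:g}"
    if not include_w:
        sid += "_noW"
    return sid


def run_scenario(
    config: ScenarioConfig,
    fcs: FCSConfig,
    *,
    scenario_index: int = 0,
    include_w: bool = True,
    models: tuple[str, ...] = MODELS,
) -> ScenarioResult:
    """Run all n_sim replicates of one cell, recording failures."""
    n_sim = config.n_sim
    est = {mdl: np.full(n_sim, np.nan) for mdl in models}
    se = {mdl: np.full(n_sim, np.nan) for mdl in models}
    fmi = {mdl: np.full(n_sim, np.nan) for mdl in models}
    failures: list[tuple[int, str]] = []
    for rep in range(n_sim):
        try:
            res = run_replicate(
                config,
                rep,
                fcs,
                scenario_index=scenario_index,
                include_w=include_w,
                models=models,
            )
        except Exception as err:  # replicate-level failure: record, keep going
            failures.append((rep, f"{type(err).__name__}: {err}"))
            continue
        for mdl, (q, s, f) in res.items():
            est[mdl][rep] = q
            se[mdl][rep] = s
            fmi[mdl][rep] = f
    return ScenarioResult(
        scenario_id=scenario_id(config, include_w),
        config=config,
        estimates=est,
        ses=se,
        fmis=fmi,
        failures=failures,
    )


@dataclass(frozen=True)
class MetricRow:
    """Simulation performance metrics for one (scenario, model) pair."""

    scenario_id: str
    model: str
    n_reps: int
    bias: float
    empse: float
    mean_model_se: float
    mcse_bias: float
    mcse_empse: float
    mean_fmi: float
    rel_bias_vs_cra_pct: float
    cra_bias_near_zero: bool


def summarize(result: ScenarioResult, true_slope: float) -> list[MetricRow]:
    """Metric rows for every model in a scenario result.

    Relative bias vs CRA is 100*bias_model/bias_CRA, flagged (and still
    reported) when |bias_CRA| < 2*MCSE(bias_CRA): near-zero denominators
    make the ratio unstable.
    """
    rows: list[MetricRow] = []
    stats_by_model: dict[str, tuple[float, float, float, float, float, int]] = {}
    for mdl, q in result.estimates.items():
        ok = np.isfinite(q)
        n_ok = int(ok.sum())
        if n_ok < 2:
            raise ValueError(
                f"scenario {result.scenario_id}, model {mdl}: "
                f"need >= 2 successful replicates, got {n_ok}"
            )
        qq = q[ok]
        bias = float(qq.mean() - true_slope)
        empse = float(qq.std(ddof=1))
        mcse_bias = empse / np.sqrt(n_ok)
        mcse_empse = empse / np.sqrt(2.0 * (n_ok - 1))
        mean_se = float(np.nanmean(result.ses[mdl][ok]))
        fmis = result.fmis[mdl][ok]
        mean_fmi = float(np.nanmean(fmis)) if np.isfinite(fmis).any() else float("nan")
        stats_by_model[mdl] = (bias, empse, mcse_bias, mcse_empse, mean_se, n_ok)
        rows.append((mdl, bias, empse, mcse_bias, mcse_empse, mean_se, mean_fmi, n_ok))

    cra_bias, _, cra_mcse = (np.nan, np.nan, np.nan)
    if "cra" in stats_by_model:
        cra_bias, _, cra_mcse, _, _, _ = stats_by_model["cra"]
    near_zero = (not np.isfinite(cra_bias)) or abs(cra_bias) < 2.0 * cra_mcse

    out = []
    for mdl, bias, empse, mcse_bias, mcse_empse, mean_se, mean_fmi, n_ok in rows:
        rel = 100.0 * bias / cra_bias if np.isfinite(cra_bias) and cra_bias != 0.0 else float("nan")
        out.append(
            MetricRow(
                scenario_id=result.scenario_id,
                model=mdl,
                n_reps=n_ok,
                bias=bias,
                empse=empse,
                mean_model_se=mean_se,
                mcse_bias=mcse_bias,
                mcse_empse=mcse_empse,
                mean_fmi=mean_fmi,
                rel_bias_vs_cra_pct=rel,
                cra_bias_near_zero=bool(near_zero),
            )
        )
    return out


@dataclass
class StudyGrid:
    """Cartesian design grid plus fixed run parameters."""

    rho_yz: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7)
    outcome_mech: tuple[int, ...] = (1, 2, 3)
    aux_mech: tuple[int, ...] = (1, 2, 3)
    pi_z: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(10))
    pi_y: tuple[float, ...] = (0.5,)
    rho_xy: tuple[float, ...] = (0.6,)
    include_w: tuple[bool, ...] = (True,)
    n: int = 1000
    n_sim: int = 1000
    m: int = 100
    burnin: int = 10
    seed: int = 0

    def cells(self):
        """Yield (index, ScenarioConfig, include_w) over the sorted product."""
        axes = itertools.product(
            self.outcome_mech,
            self.aux_mech,
            self.rho_yz,
            self.pi_z,
            self.pi_y,
            self.rho_xy,
            self.include_w,
        )
        for idx, (om, am, ryz, piz, piy, rxy, inc_w) in enumerate(axes):
            cfg = ScenarioConfig(
                n=self.n,
                n_sim=self.n_sim,
                rho_xy=rxy,
                rho_yz=ryz,
                outcome_mech=om,
                aux_mech=am,
                pi_y=piy,
                pi_z=piz,
                seed=self.seed,
            )
            yield idx, cfg, inc_w

    @property
    def n_cells(self) -> int:
        return (
            len(self.outcome_mech)
            * len(self.aux_mech)
            * len(self.rho_yz)
            * len(self.pi_z)
            * len(self.pi_y)
            * len(self.rho_xy)
            * len(self.include_w)
        )

    def fcs_config(self) -> FCSConfig:
        return FCSConfig(m=self.m, burnin=self.burnin)


def _run_cell(grid: StudyGrid, idx: int, cfg: ScenarioConfig, inc_w: bool):
    result = run_scenario(
        cfg, grid.fcs_config(), scenario_index=idx, include_w=inc_w
    )
    rows = summarize(result, true_slope=cfg.rho_xy)
    return idx, result, rows


def run_grid(
    grid: StudyGrid,
    workers: int = 1,
    progress_callback=None,
) -> tuple[pd.DataFrame, list[ScenarioResult], dict]:
    """Execute every cell; returns (metrics table, raw results, run report).

    Seeds are derived per cell from (root seed, cell index), so one worker
    and many workers produce identical output.
    """
    jobs = list(grid.cells())
    if workers > 1:
        outputs = Parallel(n_jobs=workers)(
            delayed(_run_cell)(grid, idx, cfg, inc_w) for idx, cfg, inc_w in jobs
        )
    else:
        outputs = []
        for idx, cfg, inc_w in jobs:
            out = _run_cell(grid, idx, cfg, inc_w)
            if progress_callback is not None:
                progress_callback(out[1])
            outputs.append(out)
    outputs.sort(key=lambda t: t[0])
    results = [r for _, r, _ in outputs]
    rows = [row for _, _, cell_rows in outputs for row in cell_rows]
    metrics = metrics_frame(rows, results)
    report = {
        "seed": grid.seed,
        "n_cells": grid.n_cells,
        "n_sim": grid.n_sim,
        "m": grid.m,
        "burnin": grid.burnin,
        "failures": {
            r.scenario_id: [list(f) for f in r.failures] for r in results if r.failures
        },
    }
    return metrics, results, report


def metrics_frame(rows: list[MetricRow], results: list[ScenarioResult]) -> pd.DataFrame:
    """Tidy metrics table, one MetricRow per line, with the scenario factors."""
    cfg_by_id = {r.scenario_id: r.config for r in results}
    recs = []
    for row in rows:
        cfg = cfg_by_id[row.scenario_id]
        recs.append(
            {
                "scenario_id": row.scenario_id,
                "outcome_mech": cfg.outcome_mech,
                "aux_mech": cfg.aux_mech,
                "rho_yz": cfg.rho_yz,
                "pi_z": cfg.pi_z,
                "pi_y": cfg.pi_y,
                "rho_xy": cfg.rho_xy,
                "model": row.model,
                "n_reps": row.n_reps,
                "bias": row.bias,
                "empse": row.empse,
                "mean_model_se": row.mean_model_se,
                "mcse_bias": row.mcse_bias,
                "mcse_empse": row.mcse_empse,
                "mean_fmi": row.mean_fmi,
                "rel_bias_vs_cra_pct": row.rel_bias_vs_cra_pct,
                "cra_bias_near_zero": row.cra_bias_near_zero,
            }
        )
    frame = pd.DataFrame(recs)
    if not frame.empty:
        frame = frame.sort_values(
            ["outcome_mech", "aux_mech", "rho_yz", "pi_z", "model"]
        ).reset_index(drop=True)
    return frame
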
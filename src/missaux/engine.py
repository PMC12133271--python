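"""Fully-conditional-specification (chained equations) multiple imputation.

Each incomplete variable gets a normal linear imputation model.  Draws are
"proper" in Rubin's sense: per imputed variable and cycle the residual
variance is drawn from its scaled inverse chi-square posterior, the
coefficients from their conditional normal posterior, and the imputed values
add fresh residual noise — never plug-in predictions.  Each of the m
imputations is an independent chain initialized by resampling observed
values, run for a fixed number of burn-in cycles, whose final state is
emitted.

Term specifications allow powered and product terms (e.g. ``z^3`` or
``z^3:edu``); designs are rebuilt from current values at every cycle, so
transformed terms track the latest imputations (passive updating).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TermSpec",
    "ImputationModelSpec",
    "FCSConfig",
    "ImputedStack",
    "SingularDesignError",
    "SampleSizeError",
    "build_design",
    "norm_draw_impute",
    "initial_fill",
    "fcs_cycle",
    "fcs_impute",
]


class SingularDesignError(np.linalg.LinAlgError):
    """Imputation design matrix is rank deficient."""


class SampleSizeError(ValueError):
    """Too few observed rows to fit an imputation model."""


@dataclass(frozen=True)
class TermSpec:
    """Product of (possibly powered) variables, e.g. x, z^3, or z^3 * edu."""

    variables: tuple[str, ...]
    powers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("a term needs at least one variable")
        powers = self.powers or tuple(1 for _ in self.variables)
        if len(powers) != len(self.variables):
            raise ValueError("powers must match variables one-to-one")
        if any(p < 1 for p in powers):
            raise ValueError("powers must be >= 1")
        object.__setattr__(self, "powers", powers)

    @classmethod
    def parse(cls, text: str) -> "TermSpec":
        """Parse 'x', 'z^3' or 'z^3:edu' (':' separates product factors)."""
        names, powers = [], []
        for factor in text.split(":"):
            name, _, pw = factor.partition("^")
            names.append(name.strip())
            powers.append(int(pw) if pw else 1)
        return cls(tuple(names), tuple(powers))

    def label(self) -> str:
        return ":".join(
            f"{v}^{p}" if p != 1 else v for v, p in zip(self.variables, self.powers)
        )

    def evaluate(self, table: dict[str, np.ndarray]) -> np.ndarray:
        missing = [v for v in self.variables if v not in table]
        if missing:
            raise KeyError(f"unknown variable(s) {missing} in term {self.label()}")
        out = None
        for name, power in zip(self.variables, self.powers):
            col = np.asarray(table[name], dtype=float)
            col = col**power if power != 1 else col
            out = col if out is None else out * col
        return out


@dataclass(frozen=True)
class ImputationModelSpec:
    """Conditional model for one incomplete variable (intercept implicit)."""

    target: str
    terms: tuple[TermSpec, ...]

    def __post_init__(self) -> None:
        terms = tuple(
            TermSpec.parse(t) if isinstance(t, str) else t for t in self.terms
        )
        for t in terms:
            if self.target in t.variables:
                raise ValueError(
                    f"target {self.target!r} appears among its own predictors"
                )
        object.__setattr__(self, "terms", terms)


@dataclass(frozen=True)
class FCSConfig:
    """Chained-equations settings.

    The simulation study default is m=100 imputations with 10 burn-in
    cycles; tests and desk-scale runs pass smaller m explicitly.
    """

    m: int = 100
    burnin: int = 10
    visit_order: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.burnin < 1:
            raise ValueError(f"burnin must be >= 1, got {self.burnin}")


def build_design(table: dict[str, np.ndarray], terms: tuple[TermSpec, ...]) -> np.ndarray:
    """Design matrix with a leading intercept column, one column per term."""
    if not terms:
        n = len(next(iter(table.values())))
        return np.ones((n, 1))
    cols = [t.evaluate(table) for t in terms]
    for t, c in zip(terms, cols):
        if np.isnan(c).any():
            raise ValueError(f"missing values among variables of term {t.label()}")
    return np.column_stack([np.ones_like(cols[0])] + cols)


def norm_draw_impute(
    y_obs: np.ndarray,
    design_obs: np.ndarray,
    design_mis: np.ndarray,
    rng: np.random.Generator,
    column_labels: tuple[str, ...] | None = None,
) -> np.ndarray:
    """One proper Bayesian normal-linear imputation draw.

    Fits OLS on the observed rows, draws sigma*^2 = rss / chi2(n_obs - k),
    then beta* ~ N(beta_hat, sigma*^2 (X'X)^-1), and returns
    ``design_mis @ beta* + N(0, sigma*^2)`` — a fresh parameter draw per
    call.  A residual sum of squares of zero collapses to the deterministic
    fit (degenerate posterior).
    """
    n_obs, k = design_obs.shape
    if n_obs < k + 2:
        raise SampleSizeError(
            f"need at least {k + 2} observed rows for a {k}-column design, got {n_obs}"
        )
    gram = design_obs.T @ design_obs
    try:
        chol = np.linalg.cholesky(gram)
    except np.linalg.LinAlgError:
        labels = column_labels or tuple(f"col{j}" for j in range(k))
        # name the dependent columns via rank-revealing QR diagnostics
        diag = np.abs(np.diag(np.linalg.qr(design_obs, mode="r")))
        bad = [labels[j] for j in range(k) if diag[j] <= 1e-10 * max(diag.max(), 1.0)]
        raise SingularDesignError(
            f"imputation design is rank deficient (collinear columns: {bad or labels})"
        ) from None
    xty = design_obs.T @ y_obs
    beta_hat = np.linalg.solve(gram, xty)
    resid = y_obs - design_obs @ beta_hat
    rss = float(resid @ resid)
    df = n_obs - k
    sigma2_star = rss / rng.chisquare(df)
    n_mis = design_mis.shape[0]
    if n_mis == 0:
        return np.empty(0)
    # beta* = beta_hat + sqrt(sigma*^2) L^-T u,  with gram = L L^T
    u = rng.standard_normal(k)
    beta_star = beta_hat + np.sqrt(sigma2_star) * np.linalg.solve(chol.T, u)
    noise = rng.standard_normal(n_mis) * np.sqrt(sigma2_star)
    return design_mis @ beta_star + noise


def initial_fill(
    columns: dict[str, np.ndarray],
    indicators: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Start a chain by resampling each incomplete variable's observed values."""
    table = {name: np.array(col, dtype=float, copy=True) for name, col in columns.items()}
    for name, ind in indicators.items():
        mis = np.asarray(ind) == 1
        if not mis.any():
            continue
        obs_values = table[name][~mis]
        if obs_values.size == 0:
            raise ValueError(f"variable {name!r} has no observed values to resample")
        table[name][mis] = rng.choice(obs_values, size=int(mis.sum()), replace=True)
    return table


def fcs_cycle(
    table: dict[str, np.ndarray],
    specs: tuple[ImputationModelSpec, ...],
    indicators: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One sweep over the incomplete variables, in spec order, in place.

    For each target the design is rebuilt from the current table, the model
    refit on the originally observed rows of the target, and the originally
    missing rows redrawn.
    """
    for spec in specs:
        ind = np.asarray(indicators.get(spec.target))
        if ind is None or not (ind == 1).any():
            continue
        mis = ind == 1
        design = build_design(table, spec.terms)
        labels = ("intercept",) + tuple(t.label() for t in spec.terms)
        try:
            table[spec.target][mis] = norm_draw_impute(
                table[spec.target][~mis], design[~mis], design[mis], rng, labels
            )
        except (SingularDesignError, SampleSizeError) as err:
            raise type(err)(f"imputing {spec.target!r}: {err}") from None
    return table


@dataclass
class ImputedStack:
    """m completed copies of an observed dataset plus provenance."""

    tables: list[dict[str, np.ndarray]]
    indicators: dict[str, np.ndarray]
    config: FCSConfig
    specs: tuple[ImputationModelSpec, ...]

    @property
    def m(self) -> int:
        return len(self.tables)

    def to_long_frame(self) -> pd.DataFrame:
        """Stack the m completed tables with an imputation-index column."""
        frames = []
        for i, table in enumerate(self.tables, start=1):
            f = pd.DataFrame(table)
            f.insert(0, "imputation", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _order_specs(
    specs: tuple[ImputationModelSpec, ...], visit_order: tuple[str, ...] | None
) -> tuple[ImputationModelSpec, ...]:
    if visit_order is None:
        return tuple(specs)
    by_target = {s.target: s for s in specs}
    unknown = [t for t in visit_order if t not in by_target]
    if unknown:
        raise ValueError(f"visit_order names variables without a model: {unknown}")
    return tuple(by_target[t] for t in visit_order)


def fcs_impute(
    columns: dict[str, np.ndarray],
    indicators: dict[str, np.ndarray],
    specs: tuple[ImputationModelSpec, ...],
    cfg: FCSConfig,
    rng: np.random.Generator | None = None,
) -> ImputedStack:
    """Run m independent chains and return their final completed tables.

    ``columns`` maps variable names to vectors with NaN in missing cells;
    ``indicators`` maps incomplete variable names to 0/1 missingness
    vectors.  Chains draw from independent substreams spawned from ``rng``
    (or from ``cfg.seed`` if no generator is given), so the stack is
    reproducible and chains could be run in any order.
    """
    active = {n: np.asarray(ind) for n, ind in indicators.items() if (np.asarray(ind) == 1).any()}
    uncovered = [n for n in active if n not in {s.target for s in specs}]
    if uncovered:
        raise ValueError(f"incomplete variable(s) without an imputation model: {uncovered}")
    ordered = _order_specs(specs, cfg.visit_order)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    child_seeds = rng.bit_generator.seed_seq.spawn(cfg.m) if hasattr(
        rng.bit_generator, "seed_seq"
    ) else None
    tables: list[dict[str, np.ndarray]] = []
    for chain in range(cfg.m):
        chain_rng = (
            np.random.Generator(np.random.PCG64(child_seeds[chain]))
            if child_seeds is not None
            else np.random.default_rng(rng.integers(2**63))
        )
        table = initial_fill(columns, indicators, chain_rng)
        for cycle in range(cfg.burnin):
            try:
                fcs_cycle(table, ordered, indicators, chain_rng)
            except (SingularDesignError, SampleSizeError) as err:
                raise type(err)(f"chain {chain + 1}, cycle {cycle + 1}: {err}") from None
        tables.append(table)
    return ImputedStack(tables=tables, indicators=dict(indicators), config=cfg, specs=ordered)
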
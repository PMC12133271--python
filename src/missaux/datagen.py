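"""Synthetic data generation and missingness amputation.

Generates complete trivariate-normal datasets (outcome Y, exposure X,
auxiliary Z) with a derived, fully observed proxy W for Z, and imposes
deterministic CDF-cutoff missingness in the outcome and auxiliary under
three mechanisms each:

outcome mechanisms
    1. missingness in Y driven jointly by X and Z (each marginal CDF below
       ``sqrt(pi_y)``; with X independent of Z the two cutoffs multiply to
       an overall proportion of ``pi_y``),
    2. missingness in Y driven by Y itself (MNAR outcome),
    3. missingness in Y driven by X only (covariate-dependent, so complete
       records analysis is unbiased).

auxiliary mechanisms
    1. independent Bernoulli(``pi_z``) missingness (MCAR),
    2. missingness in Z driven by Z itself (MNAR auxiliary),
    3. missingness in Z driven by the proxy W (MAR given W).

CDF cutoffs are evaluated either against the population standard-normal CDF
of the standardized value (``cdf_mode="population"``, the default, a
deterministic threshold on latent values) or against fractional ranks
``(rank - 0.5)/n`` (``cdf_mode="empirical"``, which pins exact missing
counts).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScenarioConfig",
    "CompleteDataset",
    "ObservedDataset",
    "ConfigurationError",
    "build_covariance",
    "generate_complete",
    "impose_missing_outcome",
    "impose_missing_aux",
    "make_observed",
]

_CDF_MODES = ("population", "empirical")


class ConfigurationError(ValueError):
    """Invalid scenario configuration (bad correlation structure, proportions...)."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design grid.

    Defaults reproduce the base study conditions: n=1000 rows per dataset,
    1000 replicates, means (6, -3, 2), unit variances, corr(X,Y)=0.6,
    corr(X,Z)=0, 50% outcome missingness.  ``rho_yz`` and ``pi_z`` are the
    main grid axes ({0.1,0.3,0.5,0.7} and 0-0.9 by 0.1 respectively).
    """

    n: int = 1000
    n_sim: int = 1000
    mean_y: float = 6.0
    mean_x: float = -3.0
    mean_z: float = 2.0
    rho_xy: float = 0.6
    rho_yz: float = 0.5
    rho_xz: float = 0.0
    w_loading: float = 0.6
    outcome_mech: int = 1
    aux_mech: int = 1
    pi_y: float = 0.5
    pi_z: float = 0.5
    cdf_mode: str = "population"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ConfigurationError(f"n must be >= 10, got {self.n}")
        if self.n_sim < 1:
            raise ConfigurationError(f"n_sim must be >= 1, got {self.n_sim}")
        for name in ("rho_xy", "rho_yz", "rho_xz"):
            r = getattr(self, name)
            if not -1.0 < r < 1.0:
                raise ConfigurationError(f"{name} must lie in (-1, 1), got {r}")
        for name in ("pi_y", "pi_z"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {p}")
        if self.outcome_mech not in (1, 2, 3):
            raise ConfigurationError(f"outcome_mech must be 1, 2 or 3, got {self.outcome_mech}")
        if self.aux_mech not in (1, 2, 3):
            raise ConfigurationError(f"aux_mech must be 1, 2 or 3, got {self.aux_mech}")
        if self.cdf_mode not in _CDF_MODES:
            raise ConfigurationError(f"cdf_mode must be one of {_CDF_MODES}, got {self.cdf_mode!r}")
        build_covariance(self)  # positive-definiteness check at construction

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_y, self.mean_x, self.mean_z])

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def build_covariance(config: ScenarioConfig) -> np.ndarray:
    """Covariance matrix of (Y, X, Z).

    With unit variances this equals the correlation matrix.  Raises
    :class:`ConfigurationError` if the implied matrix is not positive
    definite, naming the offending correlations.
    """
    cov = np.array(
        [
            [1.0, config.rho_xy, config.rho_yz],
            [config.rho_xy, 1.0, config.rho_xz],
            [config.rho_yz, config.rho_xz, 1.0],
        ]
    )
    # smallest eigenvalue of a symmetric 3x3; cheap and exact enough
    if np.linalg.eigvalsh(cov)[0] <= 1e-12:
        raise ConfigurationError(
            "correlations rho_xy={0.rho_xy}, rho_yz={0.rho_yz}, rho_xz={0.rho_xz} "
            "do not form a positive definite correlation matrix".format(config)
        )
    return cov


@dataclass
class CompleteDataset:
    """Fully observed (y, x, z, w) sample plus the scenario that produced it."""

    y: np.ndarray
    x: np.ndarray
    z: np.ndarray
    w: np.ndarray
    scenario: ScenarioConfig

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y": self.y, "x": self.x, "z": self.z, "w": self.w})


def generate_complete(
    config: ScenarioConfig,
    rng: np.random.Generator,
    *,
    w_standardize: str = "population",
) -> CompleteDataset:
    """Draw one complete dataset of size ``config.n``.

    (Y, X, Z) are multivariate normal with the configured means and unit
    variances.  The proxy is ``w = (loading * (z - mean_z) + e) / sqrt(loading**2 + 1)``
    with ``e`` an independent standard-normal draw, so that W has population
    mean 0, variance 1 and corr(W, Z) = loading / sqrt(loading**2 + 1).
    ``w_standardize="sample"`` rescales by the sample moments instead.
    """
    cov = build_covariance(config)
    chol = np.linalg.cholesky(cov)
    draws = rng.standard_normal((config.n, 3)) @ chol.T + config.means
    y, x, z = draws[:, 0], draws[:, 1], draws[:, 2]
    e = rng.standard_normal(config.n)
    w_raw = config.w_loading * (z - config.mean_z) + e
    if w_standardize == "population":
        w = w_raw / np.sqrt(config.w_loading**2 + 1.0)
    elif w_standardize == "sample":
        w = (w_raw - w_raw.mean()) / w_raw.std(ddof=1)
    else:
        raise ValueError(f"unknown w_standardize {w_standardize!r}")
    return CompleteDataset(y=y, x=x, z=z, w=w, scenario=config)


def _cdf_values(values: np.ndarray, mean: float, cdf_mode: str) -> np.ndarray:
    """CDF position of each value: population standard-normal CDF of the
    (known-moment) standardized value, or fractional ranks (rank-0.5)/n."""
    if cdf_mode == "population":
        return stats.norm.cdf(values - mean)  # unit population SD throughout
    if cdf_mode == "empirical":
        return (stats.rankdata(values, method="ordinal") - 0.5) / values.shape[0]
    raise ConfigurationError(f"cdf_mode must be one of {_CDF_MODES}, got {cdf_mode!r}")


def impose_missing_outcome(
    data: CompleteDataset,
    mech: int,
    pi_y: float,
    cdf_mode: str = "population",
) -> np.ndarray:
    """Binary indicator (1 = missing) for the outcome.

    Mechanism 1 marks Y missing where both CDF(X) and CDF(Z) fall below
    ``sqrt(pi_y)``; with X independent of Z the expected overall proportion
    is ``pi_y``.  Mechanism 2 thresholds CDF(Y) at ``pi_y`` (MNAR), and
    mechanism 3 thresholds CDF(X) (missingness from the exposure only).
    """
    cfg = data.scenario
    if mech == 1:
        cut = np.sqrt(pi_y)
        m = (_cdf_values(data.x, cfg.mean_x, cdf_mode) < cut) & (
            _cdf_values(data.z, cfg.mean_z, cdf_mode) < cut
        )
    elif mech == 2:
        m = _cdf_values(data.y, cfg.mean_y, cdf_mode) < pi_y
    elif mech == 3:
        m = _cdf_values(data.x, cfg.mean_x, cdf_mode) < pi_y
    else:
        raise ConfigurationError(f"outcome mechanism must be 1, 2 or 3, got {mech}")
    return m.astype(np.int8)


def impose_missing_aux(
    data: CompleteDataset,
    mech: int,
    pi_z: float,
    cdf_mode: str = "population",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary indicator (1 = missing) for the auxiliary.

    Mechanism 1 draws independent uniforms (MCAR, requires ``rng``);
    mechanism 2 thresholds CDF(Z) at ``pi_z`` (MNAR); mechanism 3 thresholds
    CDF(W) (MAR given the proxy).  W is already standardized, so its
    population CDF is the standard-normal CDF of w itself.
    """
    if mech == 1:
        if rng is None:
            raise ValueError("auxiliary mechanism 1 needs a random generator")
        m = rng.uniform(size=data.n) < pi_z
    elif mech == 2:
        m = _cdf_values(data.z, data.scenario.mean_z, cdf_mode) < pi_z
    elif mech == 3:
        m = _cdf_values(data.w, 0.0, cdf_mode) < pi_z
    else:
        raise ConfigurationError(f"auxiliary mechanism must be 1, 2 or 3, got {mech}")
    return m.astype(np.int8)


@dataclass
class ObservedDataset:
    """Complete data after amputation: y and z carry NaN where missing.

    ``m_y`` and ``m_z`` are 0/1 indicator vectors (1 = missing); x and w are
    always fully observed.
    """

    y: np.ndarray
    x: np.ndarray
    z: np.ndarray
    w: np.ndarray
    m_y: np.ndarray
    m_z: np.ndarray
    scenario: ScenarioConfig | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.y) == (self.m_y == 1)).all():
            raise ValueError("y NaN pattern disagrees with m_y")
        if not (np.isnan(self.z) == (self.m_z == 1)).all():
            raise ValueError("z NaN pattern disagrees with m_z")
        if np.isnan(self.x).any() or np.isnan(self.w).any():
            raise ValueError("x and w must be fully observed")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def columns(self) -> dict[str, np.ndarray]:
        return {"y": self.y, "x": self.x, "z": self.z, "w": self.w}

    def indicators(self) -> dict[str, np.ndarray]:
        return {"y": self.m_y, "z": self.m_z}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y": self.y,
                "x": self.x,
                "z": self.z,
                "w": self.w,
                "m_y": self.m_y.astype(int),
                "m_z": self.m_z.astype(int),
            }
        )

    def to_csv(self, path_or_buf) -> None:
        """Delimited-text round trip; missing cells are written empty."""
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservedDataset":
        return cls(
            y=frame["y"].to_numpy(float),
            x=frame["x"].to_numpy(float),
            z=frame["z"].to_numpy(float),
            w=frame["w"].to_numpy(float),
            m_y=frame["m_y"].to_numpy(np.int8),
            m_z=frame["m_z"].to_numpy(np.int8),
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "ObservedDataset":
        return cls.from_frame(pd.read_csv(path_or_buf))


def make_observed(
    data: CompleteDataset,
    rng: np.random.Generator,
    *,
    config: ScenarioConfig | None = None,
) -> ObservedDataset:
    """Apply both missingness mechanisms of the scenario to a complete dataset.

    Outcome and auxiliary missingness are imposed independently, each
    computed from the complete data, so the order of imposition is
    immaterial.
    """
    cfg = config if config is not None else data.scenario
    m_y = impose_missing_outcome(data, cfg.outcome_mech, cfg.pi_y, cfg.cdf_mode)
    m_z = impose_missing_aux(data, cfg.aux_mech, cfg.pi_z, cfg.cdf_mode, rng)
    y = data.y.copy()
    z = data.z.copy()
    y[m_y == 1] = np.nan
    z[m_z == 1] = np.nan
    return ObservedDataset(y=y, x=data.x.copy(), z=z, w=data.w.copy(), m_y=m_y, m_z=m_z, scenario=cfg)
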
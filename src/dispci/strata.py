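"""Stratified event-count data and directly age-standardized rates.

The raw data are a J x K grid of cells: J socioeconomic groups (ordered
from most to least disadvantaged, ascending) crossed with K age groups.
Each cell holds an event count ``D_jk`` (assumed Poisson with mean
``n_jk * lambda_jk``) and person-years at risk ``n_jk``.  A fixed
standard-population weight ``w_k`` attaches to each age group.

The directly standardized ("age-adjusted") rate of group j is

    Y_j = sum_k w_k * D_jk / n_jk,

an unbiased estimator of mu_j = sum_k w_k * lambda_jk, with unbiased
variance estimate sigma^2_j = sum_k w_k^2 * D_jk / n_jk^2.  Group
population shares p_j = n_j / sum(n) are treated as known constants, and
the relative (midpoint) rank of group j is z_j = sum_{s<=j} p_s - p_j/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrataTable",
    "AdjustedRates",
    "TrueRateConfig",
    "adjusted_rates",
    "true_rates",
    "population_shares",
    "relative_ranks",
]

_WEIGHT_TOL = 1e-12


def population_shares(group_person_years: np.ndarray) -> np.ndarray:
    """Population shares p_j = n_j / sum_s n_s from per-group person-years."""
    n = np.asarray(group_person_years, dtype=float)
    return n / n.sum()


def relative_ranks(p: np.ndarray) -> np.ndarray:
    """Midpoint relative ranks z_j = sum_{s<=j} p_s - p_j / 2.

    The ranks are strictly increasing and bracket the cumulative shares:
    sum_{s<j} p_s < z_j < sum_{s<=j} p_s.
    """
    p = np.asarray(p, dtype=float)
    return np.cumsum(p) - p / 2.0


@dataclass(frozen=True)
class StrataTable:
    """Observed J x K grid of event counts, person-years and age weights.

    Groups are rows in ascending socioeconomic order; age bands are columns.
    """

    events: np.ndarray
    person_years: np.ndarray
    weights: np.ndarray
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float)
        py = np.asarray(self.person_years, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if ev.ndim != 2 or py.shape != ev.shape:
            raise ValueError("events and person_years must be matching 2-D (J, K) arrays")
        if ev.shape[0] < 2:
            raise ValueError("at least J=2 socioeconomic groups are required")
        if w.shape != (ev.shape[1],):
            raise ValueError("weights must have one entry per age group")
        if np.any(py <= 0):
            raise ValueError("all person-years must be strictly positive")
        if np.any(ev < 0) or np.any(ev != np.floor(ev)):
            raise ValueError("event counts must be non-negative integers")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"age weights must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "person_years", py)
        object.__setattr__(self, "weights", w)
        labels = tuple(self.group_labels) or tuple(f"group{j + 1}" for j in range(ev.shape[0]))
        if len(labels) != ev.shape[0]:
            raise ValueError("group_labels length must equal J")
        object.__setattr__(self, "group_labels", labels)

    @property
    def J(self) -> int:
        return self.events.shape[0]

    @property
    def K(self) -> int:
        return self.events.shape[1]


@dataclass(frozen=True)
class AdjustedRates:
    """Per-group age-adjusted rate estimates and attached constants.

    Attributes
    ----------
    Y : estimated age-adjusted rates, one per group.
    var_hat : unbiased variance estimates sigma^2_j.
    p : population shares (fixed, from person-years).
    z : midpoint relative ranks in ascending socioeconomic order.
    n_total : per-group person-years n_j.
    """

    Y: np.ndarray
    var_hat: np.ndarray
    p: np.ndarray
    z: np.ndarray
    n_total: np.ndarray

    @property
    def mean_rate(self) -> float:
        """Population mean rate Y-bar = sum_j p_j Y_j."""
        return float(self.p @ self.Y)


def adjusted_rates(table: StrataTable) -> AdjustedRates:
    """Age-adjusted rates, variances, shares and ranks from observed strata.

    Y_j = sum_k w_k D_jk / n_jk and var_hat_j = sum_k w_k^2 D_jk / n_jk^2;
    shares come from total person-years and ranks from the input group order.
    """
    w = table.weights
    rates = table.events / table.person_years
    Y = rates @ w
    var_hat = (table.events / table.person_years**2) @ (w**2)
    n_total = table.person_years.sum(axis=1)
    p = population_shares(n_total)
    z = relative_ranks(p)
    return AdjustedRates(Y=Y, var_hat=var_hat, p=p, z=z, n_total=n_total)


@dataclass(frozen=True)
class TrueRateConfig:
    """True cell rates lambda_jk with person-years and weights.

    Defines the estimands: mu_j = sum_k w_k lambda_jk, its sampling
    variance sigma^2_j = sum_k w_k^2 lambda_jk / n_jk, and the fixed
    shares/ranks, against which interval coverage is scored.
    """

    lam: np.ndarray
    person_years: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        py = np.asarray(self.person_years, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if lam.ndim != 2 or py.shape != lam.shape:
            raise ValueError("lam and person_years must be matching 2-D (J, K) arrays")
        if np.any(lam <= 0):
            raise ValueError("all true rates must be strictly positive")
        if np.any(py <= 0):
            raise ValueError("all person-years must be strictly positive")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("age weights must sum to 1")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "person_years", py)
        object.__setattr__(self, "weights", w)

    @property
    def mu(self) -> np.ndarray:
        return self.lam @ self.weights

    @property
    def true_var(self) -> np.ndarray:
        return (self.lam / self.person_years) @ (self.weights**2)

    @property
    def p(self) -> np.ndarray:
        return population_shares(self.person_years.sum(axis=1))

    @property
    def z(self) -> np.ndarray:
        return relative_ranks(self.p)

    @property
    def mu_bar(self) -> float:
        return float(self.p @ self.mu)


def true_rates(config: TrueRateConfig):
    """Evaluate the truth: (mu, true_var, p, z, mu_bar)."""
    return config.mu, config.true_var, config.p, config.z, config.mu_bar
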
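"""Scenario construction and the empirical-coverage simulation study.

Nine canonical scenarios cross three person-year magnitudes with three
true-rate magnitudes over a 3 (socioeconomic groups) x 4 (age bands)
grid, spanning expected counts per cell from below 1 (extremely sparse)
to several thousand.  For each scenario the study draws R independent
Poisson datasets, constructs nominal-level intervals for every requested
measure with every requested method, and reports the empirical coverage
of the true measure value as a percentage, together with the binomial
Monte-Carlo standard error 100 * sqrt(c(1-c)/R).

All methods are evaluated on the same R datasets (one data stream, one
independent draw stream per method), so method comparisons are paired
and a full run is reproducible from (scenario, R, B, seed) alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .classical import measure_gradient, wald_interval
from .fiducial import FI_METHODS, _fi_intervals_counts
from .measures import MEASURE_IDS, MeasureSpec, evaluate_measure
from .mcs import _mcs_intervals_counts
from .strata import StrataTable, TrueRateConfig
from scipy import stats

__all__ = [
    "METHOD_IDS",
    "ScenarioSpec",
    "CoverageReport",
    "load_scenario_config",
    "build_scenario",
    "simulate_dataset",
    "coverage_experiment",
    "mc_se",
]

logger = logging.getLogger(__name__)

#: Interval methods, in reporting order.
METHOD_IDS = ("classical", "mcs_n", "mcs_g", "fi1", "fi2", "fi3")

_MAGNITUDE_BINS = ((1, "<1"), (10, "1-9"), (100, "10-99"),
                   (1000, "100-999"), (10000, "1000-9999"))


def load_scenario_config(path=None) -> dict:
    """Load the scenario fixture (packaged YAML by default)."""
    if path is None:
        text = resources.files("dispci").joinpath("data/scenarios.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: true cell rates, person-years, weights."""

    id: int
    person_years: np.ndarray
    lam: np.ndarray
    weights: np.ndarray
    group_labels: tuple[str, ...] = ()

    @property
    def true_config(self) -> TrueRateConfig:
        return TrueRateConfig(lam=self.lam, person_years=self.person_years,
                              weights=self.weights)

    @property
    def expected_counts(self) -> np.ndarray:
        return self.person_years * self.lam

    def moments(self) -> dict:
        """12-cell means/SDs of person-years, rates and expected counts,
        plus the magnitude class of the mean expected count."""
        e = self.expected_counts
        mag = next(label for bound, label in _MAGNITUDE_BINS if e.mean() < bound)
        sd = lambda x: float(np.std(x, ddof=1))
        return {
            "person_years": (float(self.person_years.mean()), sd(self.person_years)),
            "rate": (float(self.lam.mean()), sd(self.lam)),
            "expected_count": (float(e.mean()), sd(e)),
            "magnitude": mag,
        }


def build_scenario(scenario_id: int, config_path=None) -> ScenarioSpec:
    """Instantiate one of the nine canonical scenarios from the fixture."""
    cfg = load_scenario_config(config_path)
    scen = cfg["scenarios"].get(int(scenario_id))
    if scen is None:
        raise ValueError(f"unknown scenario id {scenario_id!r}")
    w = np.asarray(cfg["weights"], dtype=float)
    return ScenarioSpec(
        id=int(scenario_id),
        person_years=np.asarray(cfg["base_person_years"], float) * scen["py_scale"],
        lam=np.asarray(cfg["base_rates"], float) * scen["rate_scale"],
        weights=w / w.sum(),
        group_labels=tuple(cfg.get("group_labels", ())),
    )


def simulate_dataset(spec: ScenarioSpec, rng: np.random.Generator) -> StrataTable:
    """One dataset: independent Poisson counts with mean n_jk * lambda_jk."""
    counts = rng.poisson(spec.expected_counts)
    return StrataTable(events=counts, person_years=spec.person_years,
                       weights=spec.weights, group_labels=spec.group_labels)


def mc_se(coverage_percent: float, R: int) -> float:
    """Binomial Monte-Carlo standard error, in percentage points."""
    c = np.asarray(coverage_percent, dtype=float) / 100.0
    return 100.0 * np.sqrt(c * (1.0 - c) / R)


@dataclass(frozen=True)
class CoverageReport:
    """Empirical coverage (%) per measure x method, with provenance."""

    coverage: pd.DataFrame          # rows measures, columns methods, percent
    invalid: pd.DataFrame           # count of undefined intervals, scored non-covering
    scenario_id: int
    R: int
    B: int
    seed: int
    level: float

    def mc_se_table(self) -> pd.DataFrame:
        return self.coverage.apply(lambda col: mc_se(col, self.R))

    def to_long(self) -> pd.DataFrame:
        long = (self.coverage.rename_axis(index="measure", columns="method")
                .stack().rename("coverage").reset_index())
        long["mc_se"] = mc_se(long["coverage"].to_numpy(), self.R)
        long["invalid"] = self.invalid.rename_axis(index="measure", columns="method") \
            .stack().reset_index(drop=True)
        for key, val in (("scenario", self.scenario_id), ("R", self.R),
                         ("B", self.B), ("seed", self.seed), ("level", self.level)):
            long[key] = val
        return long


def _measure_specs(measures, aversion, pair) -> list[MeasureSpec]:
    return [MeasureSpec(id=m, aversion=aversion, pair=pair)
            if not isinstance(m, MeasureSpec) else m for m in measures]


def _classical_bounds(counts, person_years, weights, p, z, specs, level):
    """Wald bounds for many datasets: {measure_id: (R, 2)}."""
    rates = counts / person_years
    Y = rates @ weights
    V = (counts / person_years**2) @ (weights**2)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    out = {}
    for s in specs:
        point = evaluate_measure(s, Y, p, z, check=False)
        grad = measure_gradient(s, Y, p, z)
        with np.errstate(invalid="ignore"):
            half = zcrit * np.sqrt((grad**2 * V).sum(axis=-1))
        out[s.id] = np.stack([point - half, point + half], axis=-1)
    return out


def coverage_experiment(scenario, measures: Sequence = MEASURE_IDS,
                        methods: Sequence[str] = METHOD_IDS,
                        R: int = 5000, B: int = 5000, level: float = 0.95,
                        seed: int = 0, aversion: float = 3.0,
                        pair=None, chunk: Optional[int] = None,
                        failure_policy: str = "noncover") -> CoverageReport:
    """Empirical coverage of nominal ``level`` intervals under a scenario.

    Parameters
    ----------
    scenario : a :class:`ScenarioSpec` or a scenario id (1..9).
    measures : measure ids or :class:`MeasureSpec` objects.
    methods : subset of :data:`METHOD_IDS`.
    R : number of simulated datasets (all methods share them).
    B : simulation draws per dataset for the MCS and fiducial methods.
    failure_policy : "noncover" scores an undefined interval (division by
        zero or log of zero in a degenerate dataset) as not covering and
        logs a summary; "raise" propagates an error instead.

    Coverage of the true measure value F(mu) — with RD/RR truth taken at
    the true extremes, IDisp truth at the true minimum-rate reference and
    PD/PR truth at the configured fixed pair — is reported in percent.
    """
    if R < 100:
        raise ValueError("at least R=100 replicates are required")
    if failure_policy not in ("noncover", "raise"):
        raise ValueError(f"unknown failure_policy {failure_policy!r}")
    spec = scenario if isinstance(scenario, ScenarioSpec) else build_scenario(scenario)
    specs = _measure_specs(measures, aversion, pair)
    methods = [m.lower() for m in methods]
    unknown = set(methods) - set(METHOD_IDS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    tc = spec.true_config
    mu, p, z = tc.mu, tc.p, tc.z
    truth = {s.id: float(evaluate_measure(s, mu, p, z)) for s in specs}

    # one master seed: substream 0 generates the shared datasets, then one
    # fixed substream per method so subsets of methods reproduce exactly
    children = np.random.SeedSequence(seed).spawn(1 + len(METHOD_IDS))
    data_rng = np.random.Generator(np.random.PCG64(children[0]))
    counts = data_rng.poisson(spec.expected_counts, size=(R,) + spec.lam.shape)
    counts = counts.astype(float)

    cov = pd.DataFrame(index=[s.id for s in specs], columns=list(methods), dtype=float)
    inv = pd.DataFrame(0, index=[s.id for s in specs], columns=list(methods))
    for method in methods:
        rng = np.random.Generator(np.random.PCG64(children[1 + METHOD_IDS.index(method)]))
        if method == "classical":
            bounds = _classical_bounds(counts, spec.person_years, spec.weights,
                                       p, z, specs, level)
        elif method in ("mcs_n", "mcs_g"):
            dist = "gamma" if method == "mcs_g" else "truncnormal"
            bounds = _mcs_intervals_counts(counts, spec.person_years, spec.weights,
                                           p, z, specs, dist, B, level, rng, chunk)
        elif method in FI_METHODS:
            bounds = _fi_intervals_counts(counts, spec.person_years, spec.weights,
                                          p, z, specs, method, B, level, rng, chunk)
        for s in specs:
            lo, hi = bounds[s.id][:, 0], bounds[s.id][:, 1]
            ok = np.isfinite(lo) & np.isfinite(hi)
            n_bad = int(R - ok.sum())
            if n_bad and failure_policy == "raise":
                raise FloatingPointError(
                    f"{n_bad} undefined {method} intervals for {s.id}")
            if n_bad:
                logger.warning("scenario %s: %d/%d %s intervals for %s undefined; "
                               "scored as non-covering", spec.id, n_bad, R, method, s.id)
            covered = ok & (lo <= truth[s.id]) & (truth[s.id] <= hi)
            cov.loc[s.id, method] = 100.0 * covered.mean()
            inv.loc[s.id, method] = n_bad
    return CoverageReport(coverage=cov, invalid=inv, scenario_id=spec.id,
                          R=R, B=B, seed=seed, level=level)
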
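"""Fiducial quantities for Poisson rates and fiducial intervals.

For an observed count m with exposure n, the chi-squared tail identities

    Pr(D >= m | lambda) = Pr(chi2_{2m} / (2n) < lambda),
    Pr(D <= m | lambda) = Pr(chi2_{2m+2} / (2n) > lambda),

link the Poisson likelihood to chi-squared pivots.  They yield the exact
Garwood interval, Cox's approximate fiducial quantity chi2_{2m+1}/(2n),
and Dempster's 50-50 mixture of chi2_{2m}/(2n) and chi2_{2m+2}/(2n).

For a disparity measure h(lambda_11, ..., lambda_JK), an approximate
fiducial quantity is obtained by substituting a fiducial draw for every
cell rate.  Three interval constructions are provided:

* FI1 — each cell rate drawn from chi2_{2m+1}/(2n) (Cox);
* FI2 — each cell rate drawn from chi2_{2m}/(2n) or chi2_{2m+2}/(2n)
  with probability 1/2, independently per replicate and cell (Dempster);
* FI3 — per replicate, one evaluation with all cells drawn from
  chi2_{2m}/(2n) and one with all cells from chi2_{2m+2}/(2n); the 2B
  values are pooled before taking percentiles.

When m = 0 the lower pivot chi2_{2m} degenerates to a point mass at
zero; wherever that degenerate draw would be used (the lower branch of
FI2 and the all-lower evaluation of FI3), the cell instead receives the
fixed substitute rate 1 / (n * (n + 1)), which keeps every simulated
measure value finite.  The proper fiducial quantities (chi2_{2m+1} for
FI1 and the upper pivot chi2_{2m+2}) are well defined at m = 0 and are
drawn as such.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .classical import IntervalEstimate
from .measures import _as_spec, evaluate_measure
from .strata import StrataTable, relative_ranks

__all__ = [
    "FI_METHODS",
    "garwood_interval",
    "cox_interval",
    "zero_adjust",
    "draw_cell_fq",
    "fiducial_interval",
]

FI_METHODS = ("fi1", "fi2", "fi3")


def garwood_interval(m: int, n: float, level: float = 0.95):
    """Exact Poisson-rate interval from chi-squared quantiles.

    ``[chi2_{2m; a/2} / (2n), chi2_{2m+2; 1-a/2} / (2n)]`` with a = 1 - level;
    the lower bound is 0 when m = 0 (the chi-squared with 0 df is a point
    mass at 0).
    """
    alpha = 1.0 - level
    lower = 0.0 if m == 0 else stats.chi2.ppf(alpha / 2.0, 2 * m) / (2.0 * n)
    upper = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * m + 2) / (2.0 * n)
    return lower, upper


def cox_interval(m: int, n: float, level: float = 0.95):
    """Approximate fiducial interval with both endpoints from chi2_{2m+1}."""
    alpha = 1.0 - level
    df = 2 * m + 1
    return (stats.chi2.ppf(alpha / 2.0, df) / (2.0 * n),
            stats.chi2.ppf(1.0 - alpha / 2.0, df) / (2.0 * n))


def zero_adjust(m: int, n: float) -> float:
    """Substitute rate 1 / (n * (n + 1)) for a cell with zero events.

    The substitute is a fixed (degenerate) value, not a distribution; it
    replaces the degenerate chi2_0 fiducial draw (a point mass at zero)
    wherever a zero-count cell would otherwise contribute an exact zero.
    """
    if m != 0:
        raise ValueError("zero_adjust applies only to cells with zero events")
    return 1.0 / (n * (n + 1.0))


def draw_cell_fq(m: int, n: float, method: str, B: int, rng: np.random.Generator):
    """Fiducial draws for one cell's rate.

    Returns shape (B,) for FI1/FI2 and (2, B) for FI3 (paired lower/upper
    draws per replicate).  At m = 0 the degenerate lower pivot chi2_0 is
    replaced by the constant :func:`zero_adjust` value (FI2 lower branch
    and FI3 lower row); chi2_1 (FI1) and chi2_2 (upper pivot) are proper
    distributions and are drawn as such.
    """
    method = method.lower()
    if method not in FI_METHODS:
        raise ValueError(f"unknown fiducial method {method!r}")
    if method == "fi1":
        return rng.chisquare(2 * m + 1, size=B) / (2.0 * n)
    if method == "fi2":
        pick_lower = rng.random(B) < 0.5
        if m == 0:
            upper = rng.chisquare(2, size=B) / (2.0 * n)
            return np.where(pick_lower, zero_adjust(0, n), upper)
        df = np.where(pick_lower, 2 * m, 2 * m + 2)
        return rng.chisquare(df) / (2.0 * n)
    if m == 0:
        lower = np.full(B, zero_adjust(0, n))
    else:
        lower = rng.chisquare(2 * m, size=B) / (2.0 * n)
    upper = rng.chisquare(2 * m + 2, size=B) / (2.0 * n)
    return np.stack([lower, upper])


def _fi_rate_draws(counts, person_years, method, B, rng):
    """Simulated cell-rate arrays for a block of datasets.

    counts: (..., J, K) observed cell counts.  Returns (..., B, J, K) for
    FI1/FI2 and (..., 2B, J, K) for FI3 (all-lower block then all-upper).
    """
    m = np.asarray(counts, dtype=float)
    n = np.asarray(person_years, dtype=float)
    lead = m.shape[:-2]
    J, K = m.shape[-2:]
    sub = 1.0 / (n * (n + 1.0))  # replacement for the degenerate chi2_0 draw
    zeroB = (m == 0)[..., None, :, :]   # broadcast over the draw axis
    mB = m[..., None, :, :]

    if method == "fi1":
        df = np.broadcast_to(2 * mB + 1, lead + (B, J, K))
        return rng.chisquare(df) / (2.0 * n)
    if method == "fi2":
        pick_lower = rng.random(lead + (B, J, K)) < 0.5
        df = np.where(pick_lower, np.maximum(2 * mB, 1.0), 2 * mB + 2)
        lam = rng.chisquare(df) / (2.0 * n)
        return np.where(pick_lower & zeroB, sub, lam)
    # fi3: paired lower/upper evaluations, pooled along the draw axis
    df_lo = np.broadcast_to(np.where(zeroB, 1.0, 2 * mB), lead + (B, J, K))
    lam_lo = rng.chisquare(df_lo) / (2.0 * n)
    lam_lo = np.where(zeroB, sub, lam_lo)
    df_hi = np.broadcast_to(2 * mB + 2, lead + (B, J, K))
    lam_hi = rng.chisquare(df_hi) / (2.0 * n)
    return np.concatenate([lam_lo, lam_hi], axis=-3)


def _fi_intervals_counts(counts, person_years, weights, p, z, specs, method,
                         B, level, rng, chunk=None):
    """Percentile fiducial intervals for many datasets at once.

    counts: (R, J, K).  Returns {measure_id: (R, 2) array of bounds}.
    """
    method = method.lower()
    if method not in FI_METHODS:
        raise ValueError(f"unknown fiducial method {method!r}")
    counts = np.asarray(counts, dtype=float)
    R, J, K = counts.shape
    specs = [_as_spec(s) for s in specs]
    qs = [(1.0 - level) / 2.0, (1.0 + level) / 2.0]
    out = {s.id: np.empty((R, 2)) for s in specs}
    if chunk is None:
        chunk = max(1, int(2_000_000 // max(B * J * K, 1)))
    for start in range(0, R, chunk):
        sl = slice(start, min(start + chunk, R))
        lam = _fi_rate_draws(counts[sl], person_years, method, B, rng)
        Y = lam @ weights                       # (c, draws, J)
        for s in specs:
            vals = evaluate_measure(s, Y, p, z, check=False)
            lo, hi = np.quantile(vals, qs, axis=-1)
            out[s.id][sl, 0] = lo
            out[s.id][sl, 1] = hi
    return out


def fiducial_interval(table: StrataTable, measure, method: str = "fi1",
                      B: int = 5000, level: float = 0.95,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> IntervalEstimate:
    """Percentile fiducial interval for one measure on one dataset.

    Per replicate every cell rate is drawn from its fiducial quantity
    (zero cells substituted), the group rates Y_j = sum_k w_k lambda_jk
    are formed, and the measure is evaluated; the interval is the
    percentile interval of the B (FI1/FI2) or pooled 2B (FI3) values.
    """
    if B < 100:
        raise ValueError("at least B=100 fiducial replicates are required")
    if rng is None:
        rng = np.random.default_rng(seed)
    spec = _as_spec(measure)
    from .strata import adjusted_rates  # local import to avoid cycle at module load

    adj = adjusted_rates(table)
    bounds = _fi_intervals_counts(
        table.events[None], table.person_years, table.weights,
        adj.p, adj.z, [spec], method, B, level, rng)[spec.id][0]
    point = float(evaluate_measure(spec, adj.Y, adj.p, adj.z, check=False))
    return IntervalEstimate(measure=spec.id, method=method.lower(),
                            lower=float(bounds[0]), upper=float(bounds[1]),
                            level=level, point=point)
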
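"""Delta-method variances and Wald intervals for the disparity measures.

The estimator theta-hat = F(Y) is linearized around the rate vector: a
first-order Taylor expansion with independent groups gives

    Var(theta-hat) ~= sum_j (dF/dy_j |_{y=Y})^2 * sigma^2_j,

with the gradient derived analytically per measure and the shares p_j,
ranks z_j and age weights held fixed.  The Wald interval is then
point +/- z_{1-alpha/2} * sqrt(variance), on the natural scale, with no
truncation at zero and no log transformation.

Non-differentiable points are resolved deterministically rather than
raised: RD/RR attribute all variance to the groups attaining the
observed maximum and minimum (ties broken by lowest group index), and
IDisp uses sign(Y_j - Y_ref) for non-reference groups with exact ties
contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .measures import MeasureSpec, _as_spec, _sii_slope, evaluate_measure
from .strata import AdjustedRates, StrataTable, adjusted_rates

__all__ = [
    "IntervalEstimate",
    "delta_variance",
    "measure_gradient",
    "wald_interval",
    "classical_interval",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """One interval for one measure: the unit of method comparison."""

    measure: str
    method: str
    lower: float
    upper: float
    level: float = 0.95
    point: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("confidence level must lie in (0, 1)")
        if np.isfinite(self.lower) and np.isfinite(self.upper) and self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    def contains(self, value: float) -> bool:
        return bool(self.lower <= value <= self.upper)


def _onehot_add(grad: np.ndarray, idx: np.ndarray, values: np.ndarray) -> None:
    """Add ``values`` into grad at per-row group indices ``idx`` (last axis)."""
    np.put_along_axis(
        grad,
        idx[..., None],
        np.take_along_axis(grad, idx[..., None], axis=-1) + values[..., None],
        axis=-1,
    )


def measure_gradient(measure, rates, p, z=None) -> np.ndarray:
    """Analytic gradient dF/dy evaluated at ``rates``; vectorized like
    :func:`dispci.measures.evaluate_measure` (groups on the last axis)."""
    spec = _as_spec(measure)
    r = np.asarray(rates, dtype=float)
    p = np.asarray(p, dtype=float)
    if z is not None:
        z = np.asarray(z, dtype=float)
    J = r.shape[-1]
    grad = np.zeros_like(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        _GRADIENTS[spec.id](spec, r, p, z, J, grad)
    return grad


def _grad_rd(spec, r, p, z, J, grad):
    _onehot_add(grad, np.argmax(r, axis=-1), np.ones(r.shape[:-1]))
    _onehot_add(grad, np.argmin(r, axis=-1), -np.ones(r.shape[:-1]))


def _grad_pd(spec, r, p, z, J, grad):
    a, b = spec.resolve_pair(J)
    grad[..., a] += 1.0
    grad[..., b] -= 1.0


def _grad_bgv(spec, r, p, z, J, grad):
    grad += 2.0 * p * (r - (r @ p)[..., None])


def _grad_aci(spec, r, p, z, J, grad):
    grad += p * (2.0 * z - 1.0)


def _grad_eaci(spec, r, p, z, J, grad):
    nu = spec.aversion
    q = (1.0 - z) ** (nu - 1.0)
    grad += nu * p * ((p @ q) - q)


def _sii_coef(p, z):
    zbar = p @ z
    denom = p @ (z * z) - zbar**2
    return p * (z - zbar) / denom


def _grad_sii(spec, r, p, z, J, grad):
    grad += _sii_coef(p, z)


def _grad_rr(spec, r, p, z, J, grad):
    rmax = r.max(axis=-1)
    rmin = r.min(axis=-1)
    _onehot_add(grad, np.argmax(r, axis=-1), 1.0 / rmin)
    _onehot_add(grad, np.argmin(r, axis=-1), -rmax / rmin**2)


def _grad_pr(spec, r, p, z, J, grad):
    a, b = spec.resolve_pair(J)
    grad[..., a] += 1.0 / r[..., b]
    grad[..., b] -= r[..., a] / r[..., b] ** 2


def _grad_idisp(spec, r, p, z, J, grad):
    c = 100.0 / (J - 1)
    if spec.idisp_variant == "population-mean":
        # F = (100/J) * sum_j |y_j - ybar| / ybar; tie terms contribute 0
        ybar = (r @ p)[..., None]
        sgn = np.sign(r - ybar)
        total = np.abs(r - ybar).sum(axis=-1, keepdims=True)
        sgn_sum = sgn.sum(axis=-1, keepdims=True)
        grad += (100.0 / J) * ((sgn - p * sgn_sum) / ybar - total * p / ybar**2)
        return
    if spec.reference_rule == "fixed-index":
        ref_idx = np.full(r.shape[:-1], spec.reference_index - 1, dtype=np.intp)
    else:
        ref_idx = np.argmin(r, axis=-1)
    yref = np.take_along_axis(r, ref_idx[..., None], axis=-1)
    sgn = np.sign(r - yref)
    grad += c * sgn / yref
    # reference column: - c * sum_{j != ref} (sign_j * yref + |y_j - yref|) / yref^2
    ref_term = -c * (sgn * yref + np.abs(r - yref)).sum(axis=-1) / yref[..., 0] ** 2
    np.put_along_axis(grad, ref_idx[..., None], ref_term[..., None], axis=-1)


def _grad_mld(spec, r, p, z, J, grad):
    grad += p / (r @ p)[..., None] - p / r


def _grad_rci(spec, r, p, z, J, grad):
    ybar = r @ p
    nsum = r @ (p * z)
    grad += (2.0 * p / ybar[..., None]) * (z - (nsum / ybar)[..., None])


def _grad_erci(spec, r, p, z, J, grad):
    nu = spec.aversion
    q = (1.0 - z) ** (nu - 1.0)
    ybar = r @ p
    msum = r @ (p * q)
    grad += (nu * p / ybar[..., None]) * ((msum / ybar)[..., None] - q)


def _grad_theil(spec, r, p, z, J, grad):
    ybar = (r @ p)[..., None]
    t = evaluate_measure("T", r, p, check=False)[..., None]
    grad += (p / ybar) * (np.log(r / ybar) - t)


def _grad_rii(spec, r, p, z, J, grad):
    ybar = (r @ p)[..., None]
    slope = _sii_slope(r, p, z)[..., None]
    grad += _sii_coef(p, z) / ybar - slope * p / ybar**2


def _grad_kmi(spec, r, p, z, J, grad):
    zbar = p @ z
    c = _sii_coef(p, z)
    slope = _sii_slope(r, p, z)[..., None]
    ybar = (r @ p)[..., None]
    b0, s2 = ybar - slope * zbar, ybar + slope * (1.0 - zbar)
    db0, ds2 = p - zbar * c, p + (1.0 - zbar) * c
    grad += (db0 * s2 - b0 * ds2) / s2**2


_GRADIENTS = {
    "RD": _grad_rd, "PD": _grad_pd, "BGV": _grad_bgv, "ACI": _grad_aci,
    "eACI": _grad_eaci, "SII": _grad_sii, "RR": _grad_rr, "PR": _grad_pr,
    "IDisp": _grad_idisp, "MLD": _grad_mld, "RCI": _grad_rci,
    "eRCI": _grad_erci, "T": _grad_theil, "RII": _grad_rii, "KMI": _grad_kmi,
}


def delta_variance(measure, adjusted: AdjustedRates) -> float:
    """First-order (Delta-method) variance of the plug-in estimator."""
    spec = _as_spec(measure)
    grad = measure_gradient(spec, adjusted.Y, adjusted.p, adjusted.z)
    return float((grad**2) @ adjusted.var_hat)


def wald_interval(point: float, variance: float, level: float = 0.95,
                  measure: str = "", method: str = "classical") -> IntervalEstimate:
    """point +/- z_{1-alpha/2} * sqrt(variance), untruncated."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    half = zcrit * np.sqrt(variance)
    return IntervalEstimate(measure=measure, method=method,
                            lower=point - half, upper=point + half,
                            level=level, point=point)


def classical_interval(table: StrataTable, measure, level: float = 0.95) -> IntervalEstimate:
    """Wald interval from the Delta-method variance for one measure."""
    spec = _as_spec(measure)
    adj = adjusted_rates(table)
    point = float(evaluate_measure(spec, adj.Y, adj.p, adj.z))
    return wald_interval(point, delta_variance(spec, adj), level, measure=spec.id)
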
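"""The fifteen health-disparity measures.

Every measure is a function F of the vector of (true or estimated)
age-adjusted rates, with the population shares p_j, relative ranks z_j
and age weights treated as known constants.  Evaluating F on the true
rates mu gives the estimand theta = F(mu); evaluating the same formula
on the estimated rates Y gives the plug-in estimator theta-hat = F(Y).

Absolute measures: RD (range difference), BGV (between-group variance),
ACI / eACI (absolute concentration index and its extended form with
aversion parameter nu), SII (slope index of inequality).  Relative
measures: RR, IDisp, MLD, T (Theil), RCI / eRCI, RII, KMI.  Pairwise:
PD, PR, comparing two pre-specified groups.

All evaluators are vectorized: ``rates`` may carry arbitrary leading
axes with groups on the last axis, so a (R, B, J) block of simulated
rate vectors is evaluated in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "MEASURE_IDS",
    "MeasureSpec",
    "MeasureValue",
    "evaluate_measure",
    "range_measures",
    "bgv",
    "concentration_measures",
    "regression_measures",
    "idisp",
    "entropy_measures",
]

#: Canonical measure identifiers, in reporting order.
MEASURE_IDS = (
    "RD", "PD", "BGV", "ACI", "eACI", "SII", "RR", "PR",
    "IDisp", "MLD", "RCI", "eRCI", "T", "RII", "KMI",
)

_RANK_MEASURES = frozenset({"ACI", "eACI", "RCI", "eRCI", "SII", "RII", "KMI"})


@dataclass(frozen=True)
class MeasureSpec:
    """Configuration of one disparity measure.

    Parameters
    ----------
    id : one of :data:`MEASURE_IDS`.
    aversion : aversion parameter nu for eACI/eRCI; nu=2 recovers ACI/RCI.
    pair : 1-based (a, b) group indices for PD/PR, rate_a - rate_b and
        rate_a / rate_b.  Default (J, 1): last (highest-rank) group minus
        first, so PD > 0 when rates rise with socioeconomic rank.
    reference_rule : "min-rate" (default) re-selects the group with the
        smallest rate as the IDisp reference; "fixed-index" pins it.
    reference_index : 1-based group index when reference_rule="fixed-index".
    idisp_variant : "reference-group" (default) or "population-mean",
        the older IDisp form using the population mean rate as reference.
    """

    id: str
    aversion: float = 3.0
    pair: Optional[Tuple[int, int]] = None
    reference_rule: str = "min-rate"
    reference_index: Optional[int] = None
    idisp_variant: str = "reference-group"

    def __post_init__(self) -> None:
        if self.id not in MEASURE_IDS:
            raise ValueError(f"unknown measure id {self.id!r}")
        if self.aversion <= 0:
            raise ValueError("aversion parameter must be positive")
        if self.pair is not None:
            a, b = self.pair
            if a == b:
                raise ValueError("pair indices must be distinct")
        if self.reference_rule not in ("min-rate", "fixed-index"):
            raise ValueError(f"unknown reference_rule {self.reference_rule!r}")
        if self.idisp_variant not in ("reference-group", "population-mean"):
            raise ValueError(f"unknown idisp_variant {self.idisp_variant!r}")

    def resolve_pair(self, J: int) -> Tuple[int, int]:
        """0-based (a, b) indices, defaulting to (J, 1) in 1-based terms."""
        if self.pair is None:
            return J - 1, 0
        a, b = self.pair
        if not (1 <= a <= J and 1 <= b <= J):
            raise ValueError(f"pair {self.pair} out of range for J={J}")
        return a - 1, b - 1


@dataclass(frozen=True)
class MeasureValue:
    id: str
    value: float
    on_true_rates: bool = False


def _as_spec(measure) -> MeasureSpec:
    return measure if isinstance(measure, MeasureSpec) else MeasureSpec(id=measure)


def evaluate_measure(measure, rates, p, z=None, *, check: bool = True) -> np.ndarray:
    """Evaluate one disparity measure on rate vectors.

    Parameters
    ----------
    measure : a :class:`MeasureSpec` or a bare measure id string.
    rates : array with groups on the last axis; leading axes broadcast.
    p : population shares, shape (J,), summing to 1.
    z : relative ranks, shape (J,); required for rank-dependent measures
        (concentration and regression families).
    check : raise informative domain errors (zero denominators, log of
        non-positive rates).  With ``check=False`` the evaluation is
        silent and returns inf/nan where undefined, for bulk simulation.

    Returns
    -------
    ndarray with the leading axes of ``rates`` (0-d for a single vector).
    """
    spec = _as_spec(measure)
    r = np.asarray(rates, dtype=float)
    p = np.asarray(p, dtype=float)
    J = r.shape[-1]
    if p.shape != (J,):
        raise ValueError("shares p must have one entry per group")
    if spec.id in _RANK_MEASURES:
        if z is None:
            raise ValueError(f"measure {spec.id} requires relative ranks z")
        z = np.asarray(z, dtype=float)

    if check:
        _domain_check(spec, r, p, J)

    with np.errstate(divide="ignore", invalid="ignore"):
        out = _EVALUATORS[spec.id](spec, r, p, z, J)
    return out


def _domain_check(spec: MeasureSpec, r: np.ndarray, p: np.ndarray, J: int) -> None:
    if spec.id == "RR" and np.any(r.min(axis=-1) == 0):
        raise ZeroDivisionError("RR: minimum rate is zero")
    if spec.id == "PR":
        _, b = spec.resolve_pair(J)
        if np.any(r[..., b] == 0):
            raise ZeroDivisionError("PR: denominator-group rate is zero")
    if spec.id in ("MLD", "T") and np.any(r <= 0):
        bad = np.argwhere(r <= 0)
        j = int(bad[0][-1])
        raise ValueError(f"{spec.id}: rate of group {j + 1} is non-positive (log domain)")
    if spec.id in ("RCI", "eRCI", "RII") and np.any(r @ p == 0):
        raise ZeroDivisionError(f"{spec.id}: population mean rate is zero")
    if spec.id == "IDisp":
        if spec.idisp_variant == "population-mean":
            if np.any(r @ p == 0):
                raise ZeroDivisionError("IDisp: population mean rate is zero")
        elif np.any(_idisp_reference(spec, r, J) == 0):
            raise ZeroDivisionError("IDisp: reference-group rate is zero")


def _idisp_reference(spec: MeasureSpec, r: np.ndarray, J: int) -> np.ndarray:
    if spec.reference_rule == "fixed-index":
        if spec.reference_index is None:
            raise ValueError("reference_index required with reference_rule='fixed-index'")
        return r[..., spec.reference_index - 1]
    return r.min(axis=-1)


# ---------------------------------------------------------------------------
# evaluators; all receive (spec, rates, p, z, J) and reduce the last axis

def _rd(spec, r, p, z, J):
    return r.max(axis=-1) - r.min(axis=-1)


def _pd(spec, r, p, z, J):
    a, b = spec.resolve_pair(J)
    return r[..., a] - r[..., b]


def _bgv(spec, r, p, z, J):
    ybar = r @ p
    return ((r - ybar[..., None]) ** 2) @ p


def _aci(spec, r, p, z, J):
    return r @ (p * (2.0 * z - 1.0))


def _eaci(spec, r, p, z, J):
    nu = spec.aversion
    q = (1.0 - z) ** (nu - 1.0)
    return nu * ((r @ p) * (p @ q) - r @ (p * q))


def _sii_slope(r, p, z):
    zbar = p @ z
    denom = p @ (z * z) - zbar**2
    return (r @ (p * z) - zbar * (r @ p)) / denom


def _sii(spec, r, p, z, J):
    return _sii_slope(r, p, z)


def _rr(spec, r, p, z, J):
    return r.max(axis=-1) / r.min(axis=-1)


def _pr(spec, r, p, z, J):
    a, b = spec.resolve_pair(J)
    return r[..., a] / r[..., b]


def _idisp(spec, r, p, z, J):
    if spec.idisp_variant == "population-mean":
        ybar = r @ p
        return 100.0 / J * np.abs(r - ybar[..., None]).sum(axis=-1) / ybar
    ref = _idisp_reference(spec, r, J)
    total = np.abs(r - ref[..., None]).sum(axis=-1)
    return 100.0 / (J - 1) * total / ref


def _mld(spec, r, p, z, J):
    return np.log(r @ p) - np.log(r) @ p


def _rci(spec, r, p, z, J):
    return 2.0 * (r @ (p * z)) / (r @ p) - 1.0


def _erci(spec, r, p, z, J):
    nu = spec.aversion
    q = (1.0 - z) ** (nu - 1.0)
    return nu * (p @ q) - nu * (r @ (p * q)) / (r @ p)


def _theil(spec, r, p, z, J):
    g = r / (r @ p)[..., None]
    return (g * np.log(g)) @ p


def _rii(spec, r, p, z, J):
    return _sii_slope(r, p, z) / (r @ p)


def _kmi(spec, r, p, z, J):
    slope = _sii_slope(r, p, z)
    b0 = r @ p - slope * (p @ z)
    return b0 / (b0 + slope)


_EVALUATORS = {
    "RD": _rd, "PD": _pd, "BGV": _bgv, "ACI": _aci, "eACI": _eaci,
    "SII": _sii, "RR": _rr, "PR": _pr, "IDisp": _idisp, "MLD": _mld,
    "RCI": _rci, "eRCI": _erci, "T": _theil, "RII": _rii, "KMI": _kmi,
}


# ---------------------------------------------------------------------------
# grouped convenience surface

def _value(spec, rates, p, z, on_true_rates):
    v = evaluate_measure(spec, rates, p, z)
    return MeasureValue(id=spec.id, value=float(v), on_true_rates=on_true_rates)


def range_measures(rates, spec=None, *, on_true_rates=False):
    """RD, RR and, if a pair is configured, PD and PR."""
    base = spec or MeasureSpec(id="RD")
    p = np.full(len(rates), 1.0 / len(rates))  # unused by range measures
    out = {}
    for mid in ("RD", "RR", "PD", "PR"):
        s = MeasureSpec(id=mid, pair=base.pair)
        out[mid] = _value(s, rates, p, None, on_true_rates)
    return out


def bgv(rates, p, *, on_true_rates=False) -> MeasureValue:
    """Between-group variance sum_j p_j (rate_j - mean)^2."""
    return _value(MeasureSpec(id="BGV"), rates, p, None, on_true_rates)


def concentration_measures(rates, p, z, spec=None, *, on_true_rates=False):
    """RCI, ACI and their extended (aversion-weighted) versions."""
    nu = (spec.aversion if spec else 3.0)
    out = {}
    for mid in ("RCI", "ACI", "eRCI", "eACI"):
        out[mid] = _value(MeasureSpec(id=mid, aversion=nu), rates, p, z, on_true_rates)
    return out


def regression_measures(rates, p, z, *, on_true_rates=False):
    """SII, RII and KMI from the share-weighted rank regression."""
    z = np.asarray(z, dtype=float)
    if np.ptp(z) == 0:
        raise ValueError("degenerate ranks: all z equal, regression design is singular")
    out = {}
    for mid in ("SII", "RII", "KMI"):
        out[mid] = _value(MeasureSpec(id=mid), rates, p, z, on_true_rates)
    return out


def idisp(rates, spec=None, *, p=None, on_true_rates=False) -> MeasureValue:
    """Index of disparity; reference group re-selected per the spec rule."""
    s = spec or MeasureSpec(id="IDisp")
    if s.id != "IDisp":
        raise ValueError("idisp() requires an IDisp spec")
    rates = np.asarray(rates, dtype=float)
    if p is None:
        p = np.full(rates.shape[-1], 1.0 / rates.shape[-1])
    return _value(s, rates, p, None, on_true_rates)


def entropy_measures(rates, p, *, on_true_rates=False):
    """Mean log deviation and Theil's index (natural logs)."""
    out = {}
    for mid in ("MLD", "T"):
        out[mid] = _value(MeasureSpec(id=mid), rates, p, None, on_true_rates)
    return out
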
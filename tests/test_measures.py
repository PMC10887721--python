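"""The fifteen disparity measures: oracles, identities, invariances."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from dispci import MEASURE_IDS, MeasureSpec, evaluate_measure
from dispci.measures import (bgv, concentration_measures, entropy_measures,
                             idisp, range_measures, regression_measures)

from conftest import random_config

TWO = dict(rates=np.array([1.0, 3.0]), p=np.array([0.5, 0.5]),
           z=np.array([0.25, 0.75]))

#: relative-measure ids unchanged under rate rescaling; the rest scale.
SCALE_INVARIANT = {"RR", "PR", "RCI", "eRCI", "RII", "KMI", "IDisp", "MLD", "T"}


def _eval(mid, rates, p, z, **kw):
    return float(evaluate_measure(MeasureSpec(id=mid, **kw), rates, p, z))


class TestConstantRates:
    """Every measure has a known value when all groups share one rate."""

    EXPECTED = dict(RD=0, PD=0, BGV=0, ACI=0, eACI=0, SII=0, RR=1, PR=1,
                    IDisp=0, MLD=0, RCI=0, eRCI=0, T=0, RII=0, KMI=1)

    @pytest.mark.parametrize("mid", MEASURE_IDS)
    def test_constant_vector(self, mid):
        rates = np.full(4, 0.7)
        p = np.array([0.1, 0.2, 0.3, 0.4])
        z = np.cumsum(p) - p / 2
        npt.assert_allclose(_eval(mid, rates, p, z), self.EXPECTED[mid], atol=1e-12)


class TestHandOracles:
    def test_range_and_pair(self):
        assert _eval("RD", **TWO) == 2.0
        assert _eval("RR", **TWO) == 3.0
        assert _eval("PD", **TWO, pair=(1, 2)) == -2.0
        npt.assert_allclose(_eval("PR", **TWO, pair=(1, 2)), 1.0 / 3.0)
        # default pair: last minus first
        assert _eval("PD", **TWO) == 2.0

    def test_bgv_hand_value(self):
        # mean 2, deviations +-1, shares 1/2 -> 1
        assert _eval("BGV", **TWO) == 1.0

    def test_bgv_translation_invariance(self, rng):
        rates, p, z = random_config(rng)
        npt.assert_allclose(_eval("BGV", rates + 1.7, p, z),
                            _eval("BGV", rates, p, z), rtol=1e-9, atol=1e-12)

    def test_concentration_hand_values(self):
        # Sum p z mu = .5(.25*1 + .75*3) = 1.25; mean 2 -> RCI = 2*1.25/2-1 = .25
        npt.assert_allclose(_eval("RCI", **TWO), 0.25)
        npt.assert_allclose(_eval("ACI", **TWO), 0.5)

    def test_regression_hand_values(self):
        # weighted LS on z=(.25,.75): slope 4, intercept 0
        npt.assert_allclose(_eval("SII", **TWO), 4.0)
        npt.assert_allclose(_eval("RII", **TWO), 2.0)
        npt.assert_allclose(_eval("KMI", **TWO), 0.0, atol=1e-12)

    def test_idisp_min_reference(self):
        rates = np.array([1.0, 2.0, 4.0])
        p = np.full(3, 1 / 3)
        val = _eval("IDisp", rates, p, None)
        npt.assert_allclose(val, 100 / 2 * ((2 - 1) + (4 - 1)) / 1.0)  # 200

    def test_idisp_population_mean_variant(self):
        val = float(evaluate_measure(
            MeasureSpec(id="IDisp", idisp_variant="population-mean"),
            TWO["rates"], TWO["p"]))
        npt.assert_allclose(val, 50.0)  # (1/2)(.5+.5)*100 at mean 2

    def test_entropy_hand_values(self):
        # oracle: direct evaluation of the defining formulas
        mld_oracle = np.log(2.0) - 0.5 * (np.log(1.0) + np.log(3.0))
        g = TWO["rates"] / 2.0
        t_oracle = float((0.5 * g * np.log(g)).sum())
        npt.assert_allclose(_eval("MLD", **TWO), mld_oracle)
        npt.assert_allclose(_eval("T", **TWO), t_oracle)

    def test_entropy_nonnegative(self, rng):
        # Jensen: MLD >= 0 and T >= 0 for positive rates
        for _ in range(200):
            rates, p, z = random_config(rng)
            assert _eval("MLD", rates, p, z) >= -1e-12
            assert _eval("T", rates, p, z) >= -1e-12


class TestIdentities:
    def test_absolute_equals_mean_times_relative(self, rng):
        for _ in range(50):
            rates, p, z = random_config(rng)
            ybar = rates @ p
            npt.assert_allclose(_eval("ACI", rates, p, z),
                                ybar * _eval("RCI", rates, p, z), rtol=1e-10)
            npt.assert_allclose(_eval("eACI", rates, p, z),
                                ybar * _eval("eRCI", rates, p, z), rtol=1e-10)
            npt.assert_allclose(_eval("RII", rates, p, z),
                                _eval("SII", rates, p, z) / ybar, rtol=1e-10)

    def test_aversion_two_recovers_plain_indices(self, rng):
        for _ in range(100):
            rates, p, z = random_config(rng)
            npt.assert_allclose(_eval("eRCI", rates, p, z, aversion=2.0),
                                _eval("RCI", rates, p, z), rtol=1e-9, atol=1e-12)
            npt.assert_allclose(_eval("eACI", rates, p, z, aversion=2.0),
                                _eval("ACI", rates, p, z), rtol=1e-9, atol=1e-12)

    def test_kmi_consistent_with_intercept_recovery(self, rng):
        for _ in range(20):
            rates, p, z = random_config(rng)
            sii = _eval("SII", rates, p, z)
            b0 = rates @ p - sii * (p @ z)
            npt.assert_allclose(_eval("KMI", rates, p, z), b0 / (b0 + sii), rtol=1e-10)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10.0),
       mid=st.sampled_from(MEASURE_IDS))
def test_scale_behavior(seed, c, mid):
    """Rescaling all rates by c leaves relative measures unchanged and
    scales absolute ones by c (BGV by c^2)."""
    rates, p, z = random_config(np.random.default_rng(seed))
    base = _eval(mid, rates, p, z)
    scaled = _eval(mid, c * rates, p, z)
    if mid in SCALE_INVARIANT:
        npt.assert_allclose(scaled, base, rtol=1e-8, atol=1e-10)
    elif mid == "BGV":
        npt.assert_allclose(scaled, c**2 * base, rtol=1e-8)
    else:
        npt.assert_allclose(scaled, c * base, rtol=1e-8, atol=1e-12)


class TestDomainErrors:
    def test_rr_zero_minimum(self):
        with pytest.raises(ZeroDivisionError, match="RR"):
            evaluate_measure("RR", [0.0, 1.0], [0.5, 0.5])

    def test_log_domain_names_group(self):
        with pytest.raises(ValueError, match="MLD.*group 1"):
            evaluate_measure("MLD", [0.0, 1.0], [0.5, 0.5])

    def test_degenerate_ranks_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            regression_measures([1.0, 2.0], [0.5, 0.5], [0.5, 0.5])

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError):
            MeasureSpec(id="GINI")


class TestGroupedSurface:
    def test_grouped_helpers_agree_with_engine(self, rng):
        rates, p, z = random_config(rng, J=3)
        assert range_measures(rates)["RD"].value == _eval("RD", rates, p, z)
        assert bgv(rates, p).value == _eval("BGV", rates, p, z)
        cm = concentration_measures(rates, p, z)
        npt.assert_allclose(cm["eRCI"].value, _eval("eRCI", rates, p, z))
        rm = regression_measures(rates, p, z)
        npt.assert_allclose(rm["SII"].value, _eval("SII", rates, p, z))
        em = entropy_measures(rates, p)
        npt.assert_allclose(em["T"].value, _eval("T", rates, p, z))
        npt.assert_allclose(idisp(rates).value, _eval("IDisp", rates, p, z))

    def test_vectorized_matches_scalar(self, rng):
        block = rng.uniform(0.2, 3.0, (7, 5, 3))
        p = rng.dirichlet(np.ones(3))
        z = np.cumsum(p) - p / 2
        for mid in MEASURE_IDS:
            vec = evaluate_measure(mid, block, p, z)
            assert vec.shape == (7, 5)
            one = _eval(mid, block[2, 4], p, z)
            npt.assert_allclose(vec[2, 4], one, rtol=1e-12)
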
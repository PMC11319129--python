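"""Ecoenzymatic vector analysis, root N:P classification and SMA fits."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizostoich import (
    EnzymeProfile,
    RootChemistry,
    angle_threshold_from_np,
    classify_microbial_limitation,
    classify_root_limitation,
    enzyme_cnp_ratio,
    enzyme_np_ratio,
    microbial_n_limitation,
    root_np,
    root_vector_angle,
    sma_fit,
    vector_angle,
    vector_length,
)
from rhizostoich.errors import ConfigError, DomainError

activity = st.floats(min_value=1.5, max_value=2000.0,
                     allow_nan=False, allow_infinity=False)


def profiles():
    return st.builds(EnzymeProfile, bg=activity, nag=activity,
                     lap=activity, acp=activity)


class TestEnzymeRatios:
    def test_np_ratio_boundary_is_one(self):
        assert enzyme_np_ratio(EnzymeProfile(bg=30, nag=30, lap=20, acp=50)) == 1.0

    def test_np_ratio_value(self):
        e = EnzymeProfile(bg=30, nag=60, lap=40, acp=50)
        assert enzyme_np_ratio(e) == pytest.approx(math.log(100) / math.log(50))
        assert enzyme_np_ratio(e) == pytest.approx(1.1772, abs=5e-5)

    def test_np_ratio_log_domain(self):
        with pytest.raises(DomainError, match="ACP"):
            enzyme_np_ratio(EnzymeProfile(bg=30, nag=30, lap=20, acp=1.0))

    def test_cnp_symmetry(self):
        v = math.e ** 10
        e = EnzymeProfile(bg=v, nag=v / 2, lap=v / 2, acp=v)
        assert enzyme_cnp_ratio(e) == pytest.approx((1.0, 1.0, 1.0))

    def test_cnp_value(self):
        e = EnzymeProfile(bg=50, nag=60, lap=40, acp=80)
        c, n, p = enzyme_cnp_ratio(e)
        assert c == 1.0
        assert n == pytest.approx(math.log(100) / math.log(50))
        assert p == pytest.approx(math.log(80) / math.log(50))
        assert (n, p) == pytest.approx((1.1772, 1.1201), abs=1e-4)

    def test_cnp_log_domain(self):
        with pytest.raises(DomainError, match="BG"):
            enzyme_cnp_ratio(EnzymeProfile(bg=0.9, nag=30, lap=20, acp=50))


class TestVectorGeometry:
    def test_length_unit_ratios(self):
        v = math.e
        e = EnzymeProfile(bg=v, nag=v / 2, lap=v / 2, acp=v)
        assert vector_length(e) == pytest.approx(math.sqrt(2.0))

    def test_length_value(self):
        e = EnzymeProfile(bg=80, nag=60, lap=40, acp=50)
        x = math.log(80) / math.log(50)
        y = math.log(80) / math.log(100)
        assert vector_length(e) == pytest.approx(math.hypot(x, y))
        assert vector_length(e) == pytest.approx(1.46974, abs=5e-5)

    def test_length_monotone_in_bg(self):
        e1 = EnzymeProfile(bg=40, nag=60, lap=40, acp=50)
        e2 = EnzymeProfile(bg=80, nag=60, lap=40, acp=50)
        assert vector_length(e2) > vector_length(e1)

    def test_angle_boundary(self):
        e = EnzymeProfile(bg=30, nag=30, lap=20, acp=50)
        assert vector_angle(e) == pytest.approx(45.0, abs=1e-12)

    def test_angle_value_and_call(self):
        e = EnzymeProfile(bg=80, nag=60, lap=40, acp=50)
        a = vector_angle(e)
        assert a == pytest.approx(math.degrees(math.atan(math.log(50) / math.log(100))))
        assert a == pytest.approx(40.35, abs=5e-3)
        assert classify_microbial_limitation(a) == "N-limited"

    def test_angle_asymptote(self):
        e = EnzymeProfile(bg=30, nag=30, lap=20, acp=1e280)
        assert vector_angle(e) > 89.0

    def test_n_limitation_values(self):
        assert microbial_n_limitation(
            EnzymeProfile(bg=30, nag=30, lap=20, acp=50)
        ) == pytest.approx(45.0)
        assert microbial_n_limitation(
            EnzymeProfile(bg=80, nag=60, lap=40, acp=50)
        ) == pytest.approx(49.65, abs=5e-3)

    @given(profiles())
    @settings(max_examples=300)
    def test_complementarity(self, e):
        """N-limitation angle and vector angle always sum to 90 degrees."""
        assert vector_angle(e) + microbial_n_limitation(e) == pytest.approx(
            90.0, abs=1e-9
        )

    @given(profiles())
    @settings(max_examples=300)
    def test_npsee_angle_coherence(self, e):
        """Enzymatic N:P above 1 exactly when the angle is below 45 deg."""
        ratio = enzyme_np_ratio(e)
        angle = vector_angle(e)
        if abs(ratio - 1.0) > 1e-12:
            assert (ratio > 1.0) == (angle < 45.0)

    def test_not_scale_invariant(self):
        """Rescaling all activities by a common factor changes the metrics;
        this is inherent to ln-ratio stoichiometry, not a defect."""
        e1 = EnzymeProfile(bg=80, nag=60, lap=40, acp=50)
        e2 = EnzymeProfile(bg=160, nag=120, lap=80, acp=100)
        assert vector_angle(e1) != pytest.approx(vector_angle(e2), abs=1e-6)
        assert vector_length(e1) != pytest.approx(vector_length(e2), abs=1e-6)


class TestRootClassification:
    def test_np_ratio(self):
        assert root_np(RootChemistry(tc=400, tn=14, tp=1)) == 14.0
        assert root_np(RootChemistry(tc=400, tn=3, tp=3)) == 1.0

    def test_angle_at_conventional_thresholds(self):
        """The printed cut-offs 4.09 and 3.58 deg sit on N:P = 14 and 16."""
        a14 = root_vector_angle(RootChemistry(tc=400, tn=14, tp=1))
        a16 = root_vector_angle(RootChemistry(tc=400, tn=16, tp=1))
        assert round(a14, 2) == 4.09
        assert round(a16, 2) == 3.58

    def test_angle_symmetry(self):
        assert root_vector_angle(RootChemistry(tc=400, tn=5, tp=5)) == pytest.approx(45.0)

    @pytest.mark.parametrize(
        "angle, call",
        [(5.0, "N-limited"), (3.8, "unlimited"), (3.0, "P-limited"),
         (4.09, "unlimited"), (3.58, "unlimited")],
    )
    def test_classification_rule(self, angle, call):
        assert classify_root_limitation(angle) == call

    def test_bad_thresholds(self):
        with pytest.raises(ConfigError):
            classify_root_limitation(4.0, thresholds=(5.0, 3.0))

    @pytest.mark.parametrize(
        "angle, call", [(40.35, "N-limited"), (60.0, "P-limited"), (45.0, "balanced")]
    )
    def test_microbial_rule(self, angle, call):
        assert classify_microbial_limitation(angle) == call

    @given(tn=st.floats(0.5, 40.0), tp=st.floats(0.05, 4.0))
    @settings(max_examples=500)
    def test_angle_rule_matches_ratio_rule(self, tn, tp):
        """With exact thresholds the angle rule and the N:P < 14 rule make
        the same N-limitation call everywhere off the boundary."""
        r = RootChemistry(tc=400.0, tn=tn, tp=tp)
        ratio = root_np(r)
        if abs(ratio - 14.0) < 1e-9 or abs(ratio - 16.0) < 1e-9:
            return
        thresholds = (angle_threshold_from_np(16.0), angle_threshold_from_np(14.0))
        by_angle = classify_root_limitation(root_vector_angle(r), thresholds)
        assert (by_angle == "N-limited") == (ratio < 14.0)
        assert (by_angle == "P-limited") == (ratio > 16.0)


class TestSMA:
    def test_exact_positive_line(self):
        fit = sma_fit([1, 2, 3], [2, 4, 6])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r == pytest.approx(1.0)

    def test_exact_negative_line(self):
        fit = sma_fit([1, 2, 3], [6, 4, 2])
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(8.0)
        assert fit.r == pytest.approx(-1.0)

    def test_slope_is_sd_ratio_under_independence(self):
        """|slope| = sd(y)/sd(x) regardless of correlation strength."""
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 2.0, 1000)
        y = rng.normal(0.0, 5.0, 1000)
        fit = sma_fit(x, y)
        assert abs(fit.slope) == pytest.approx(y.std(ddof=1) / x.std(ddof=1))
        assert abs(fit.slope) == pytest.approx(2.5, rel=0.15)

    @given(st.integers(0, 1000))
    @settings(max_examples=30)
    def test_slope_squared_variance_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = 0.3 * x + rng.normal(size=20)
        fit = sma_fit(x, y)
        assert fit.slope ** 2 * x.var(ddof=1) == pytest.approx(
            y.var(ddof=1), rel=1e-12
        )
        assert math.copysign(1, fit.slope) == math.copysign(1, fit.r)

    def test_degenerate(self):
        with pytest.raises(DomainError):
            sma_fit([1, 1, 1], [2, 3, 4])
        with pytest.raises(DomainError):
            sma_fit([1, 2], [2, 3])
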
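import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seepcomm.core_data_io import FluidSample, ValidationError, load_ktl_fluid_fixture
from seepcomm.endmember_mixing import (
    MixingModel, default_ktl_model, forward_mix, invert_f_chloride,
    invert_f_joint, max_saline_fraction, mixing_curve,
)
from seepcomm.synthetic_data import gen_fluids

# module-level model for hypothesis property tests (deterministic construction)
MODEL = default_ktl_model()


class TestForwardMix:
    def test_end_member_identities(self, ktl_model):
        assert forward_mix(0.0, ktl_model) == pytest.approx((15.0, 0.2, 0.72))
        assert forward_mix(1.0, ktl_model) == pytest.approx((546.0, 92.0, 0.709))

    def test_ten_percent_blend(self, ktl_model):
        Cl, Sr, ratio = forward_mix(0.1, ktl_model)
        assert Cl == pytest.approx(68.1)
        assert Sr == pytest.approx(9.38)
        assert ratio == pytest.approx(0.70921, abs=5e-6)

    def test_f_outside_unit_interval_rejected(self, ktl_model):
        for f in (-0.01, 1.01):
            with pytest.raises(ValidationError):
                forward_mix(f, ktl_model)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_sr_mass_conservation_exact(self, f):
        """Sr_mix * R_mix equals the Sr-weighted sum of end-member ratios."""
        s, w = MODEL.saline, MODEL.fresh
        _, Sr, ratio = forward_mix(f, MODEL)
        lhs = Sr * ratio
        rhs = f * s.Sr_uM * s.ratio_87_86 + (1 - f) * w.Sr_uM * w.ratio_87_86
        assert lhs == pytest.approx(rhs, rel=1e-14)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_ratio_bounded_by_end_members(self, f):
        _, _, ratio = forward_mix(f, MODEL)
        assert 0.709 - 1e-12 <= ratio <= 0.72 + 1e-12


class TestMixingCurve:
    def test_eleven_point_grid(self, ktl_model):
        curve = mixing_curve(ktl_model, 11)
        assert curve.shape == (11, 4)
        np.testing.assert_allclose(curve[:, 0], np.arange(0.0, 1.05, 0.1))
        assert np.all(np.diff(curve[:, 3]) < 0)  # ratio strictly decreasing (R_s < R_f)

    def test_curve_matches_dense_brute_force(self, ktl_model):
        """The (Cl, ratio) curve agrees with direct evaluation at 10⁴ points."""
        fs = np.linspace(0.0, 1.0, 10_000)
        curve = mixing_curve(ktl_model, 10_000)
        s, w = ktl_model.saline, ktl_model.fresh
        Cl = fs * s.Cl_mM + (1 - fs) * w.Cl_mM
        Sr = fs * s.Sr_uM + (1 - fs) * w.Sr_uM
        ratio = (fs * s.Sr_uM * s.ratio_87_86 + (1 - fs) * w.Sr_uM * w.ratio_87_86) / Sr
        np.testing.assert_allclose(curve[:, 1], Cl, rtol=1e-12)
        np.testing.assert_allclose(curve[:, 3], ratio, rtol=1e-12)
        # hyperbolic shape: ratio vs Cl is convex upward toward the freshwater end
        d2 = np.diff(np.diff(curve[:, 3]) / np.diff(curve[:, 1]))
        assert np.all(d2 > 0)

    def test_too_few_points_rejected(self, ktl_model):
        with pytest.raises(ValidationError):
            mixing_curve(ktl_model, 1)


class TestInvertChloride:
    @pytest.mark.parametrize("Cl,expected", [
        (83.1, (83.1 - 15) / 531),   # highest-Cl field sample
        (15.0, 0.0),
        (62.0, (62.0 - 15) / 531),
    ])
    def test_closed_form(self, ktl_model, Cl, expected):
        assert invert_f_chloride(Cl, ktl_model) == pytest.approx(expected)

    def test_slightly_below_fresh_clamps_with_warning(self, ktl_model):
        with pytest.warns(UserWarning, match="clamped"):
            assert invert_f_chloride(14.0, ktl_model) == 0.0

    def test_far_out_of_range_rejected(self, ktl_model):
        with pytest.raises(ValidationError, match="end-member"):
            invert_f_chloride(600.0, ktl_model)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_to_1e12(self, f):
        Cl, _, _ = forward_mix(f, MODEL)
        assert invert_f_chloride(Cl, MODEL) == pytest.approx(f, abs=1e-12)


class TestInvertJoint:
    def test_noise_free_self_consistency(self, ktl_model):
        Cl, Sr, ratio = forward_mix(0.15, ktl_model)
        res = invert_f_joint(FluidSample("syn", Cl, Sr, ratio), ktl_model)
        assert res.f_saline == pytest.approx(0.15, abs=1e-6)
        assert res.misfit == pytest.approx(0.0, abs=1e-10)

    def test_field_sample_has_positive_misfit(self, ktl_model):
        """The two-end-member model cannot fit all three tracers of KTL02."""
        ktl02 = FluidSample("KTL02", Cl_mM=83.1, Sr_uM=27.8, ratio_87_86=0.71142)
        res = invert_f_joint(ktl02, ktl_model)
        assert res.misfit > 1e-3

    def test_chloride_only_weights_match_closed_form(self, ktl_model):
        sample = FluidSample("s", Cl_mM=83.1, Sr_uM=27.8, ratio_87_86=0.71142)
        with pytest.raises(ValidationError):
            invert_f_joint(FluidSample("s", Cl_mM=83.1), ktl_model)
        res = invert_f_joint(sample, ktl_model, weights=(1.0, 1.0, 0.0))
        # with Sr still active this differs from Cl-only; zero all but Cl
        res = invert_f_joint(sample, ktl_model, weights=(1.0, 0.0, 1e-30))
        assert res.f_saline == pytest.approx(
            invert_f_chloride(83.1, ktl_model), abs=1e-6)

    def test_noisy_recovery_median_within_002(self, ktl_model):
        """2% tracer noise at f = 0.12: median |Δf| < 0.02 over 500 draws."""
        samples, fs = gen_fluids(ktl_model, f_values=[0.12] * 500,
                                 tracer_noise_frac=0.02, seed=11)
        errs = [abs(invert_f_joint(s, ktl_model).f_saline - f)
                for s, f in zip(samples, fs)]
        assert np.median(errs) < 0.02


class TestMaxSalineFraction:
    def test_field_samples_stay_below_20pct(self, ktl_model):
        samples = load_ktl_fluid_fixture()
        f_max, results = max_saline_fraction(samples, ktl_model, method="chloride")
        assert f_max < 0.20
        assert len(results) == 4

    def test_single_freshwater_sample(self, ktl_model):
        f_max, _ = max_saline_fraction([FluidSample("f", Cl_mM=15.0)], ktl_model)
        assert f_max == 0.0

    def test_max_of_known_fractions(self, ktl_model):
        samples, _ = gen_fluids(ktl_model, f_values=[0.05, 0.1, 0.19],
                                tracer_noise_frac=0.0, seed=0)
        f_max, _ = max_saline_fraction(samples, ktl_model, method="chloride")
        assert f_max == pytest.approx(0.19, abs=1e-12)

    def test_empty_sample_list_rejected(self, ktl_model):
        with pytest.raises(ValidationError):
            max_saline_fraction([], ktl_model)
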
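"""Response pipeline: fraction→current→concentration composition and ΔI/I₀."""

import numpy as np
import pytest

from rfetsense.binding import BindingModel, bound_fraction
from rfetsense.curves import ResponseCurve
from rfetsense.errors import (DomainError, ExtrapolationError, InversionError,
                              ValidationError)
from rfetsense.response import (DEFAULT_CONCENTRATIONS, calibration_curve,
                                current_vs_fraction,
                                default_interface_condition,
                                invert_response_for_kd, relative_response)


def analytic_fraction_curve(slope=-0.5, i0=1.0, n=21):
    """Fake device map I(f) = i0·(1 + slope·f) on a dense fraction grid."""
    f = np.linspace(0.0, 1.0, n)
    return ResponseCurve(x=f, current=i0 * (1.0 + slope * f), x_kind="fraction")


class TestCalibrationCurve:
    model = BindingModel(kd=1.47e-9)

    def test_zero_concentration_is_exact_endpoint(self):
        cf = analytic_fraction_curve()
        cc = calibration_curve(cf, self.model, DEFAULT_CONCENTRATIONS)
        assert cc.current[0] == cf.current[0]

    def test_kd_maps_to_half_occupancy_current(self):
        cf = analytic_fraction_curve()
        cc = calibration_curve(cf, self.model, np.array([self.model.kd]))
        assert cc.current[0] == pytest.approx(1.0 - 0.5 * 0.5, rel=1e-9)

    def test_saturation_approaches_full_occupancy(self):
        cf = analytic_fraction_curve()
        cc = calibration_curve(cf, self.model, np.array([1e6 * self.model.kd]))
        assert cc.current[0] == pytest.approx(cf.current[-1], rel=1e-5)

    def test_monotone_composition(self):
        cf = analytic_fraction_curve(slope=0.8)
        cc = calibration_curve(cf, self.model, DEFAULT_CONCENTRATIONS)
        assert np.all(np.diff(cc.current) >= 0)

    def test_sparse_fraction_curve_rejected(self):
        cf = analytic_fraction_curve(n=5)
        with pytest.raises(ValidationError):
            calibration_curve(cf, self.model, DEFAULT_CONCENTRATIONS)

    def test_uncovered_fraction_range_rejected(self):
        f = np.linspace(0.0, 0.4, 11)
        cf = ResponseCurve(x=f, current=1.0 - f, x_kind="fraction")
        with pytest.raises(ExtrapolationError):
            calibration_curve(cf, self.model, np.array([1e-6]))


class TestRelativeResponse:
    def test_flat_curve_has_zero_response(self):
        c = DEFAULT_CONCENTRATIONS
        curve = ResponseCurve(x=c, current=np.full(c.size, 2e-9),
                              x_kind="concentration")
        assert relative_response(curve).max_relative_response == 0.0

    def test_langmuir_suppression_closed_form(self):
        # I(c) = I0·(1 − 0.5·f(c)): 50% max suppression, half response at KD
        model = BindingModel(kd=2e-9)
        c = np.concatenate([[0.0], np.logspace(-12, -6, 200)])
        f = np.concatenate([[0.0], bound_fraction(c[1:], model)])
        curve = ResponseCurve(x=c, current=1e-9 * (1.0 - 0.5 * f),
                              x_kind="concentration")
        s = relative_response(curve)
        assert s.response_sign == "suppression"
        # grid tops out at 500×KD where f = 0.998, so max ΔI/I0 = 0.499
        assert s.max_relative_response == pytest.approx(0.5, rel=5e-3)
        assert s.half_response_concentration == pytest.approx(model.kd,
                                                              rel=0.02)

    def test_doubled_current_is_full_enhancement(self):
        curve = ResponseCurve(x=np.array([0.0, 1e-9]),
                              current=np.array([1e-10, 2e-10]),
                              x_kind="concentration")
        s = relative_response(curve)
        assert s.response_sign == "enhancement"
        assert s.max_relative_response == pytest.approx(1.0)

    def test_negative_branch_handled_on_magnitude(self):
        curve = ResponseCurve(x=np.array([0.0, 1e-9, 1e-8]),
                              current=np.array([-2e-9, -1.5e-9, -1e-9]),
                              x_kind="concentration")
        assert relative_response(curve).response_sign == "suppression"

    def test_missing_baseline_rejected(self):
        curve = ResponseCurve(x=np.array([1e-10, 1e-9]),
                              current=np.array([1e-9, 2e-9]),
                              x_kind="concentration")
        with pytest.raises(ValidationError):
            relative_response(curve)

    def test_zero_baseline_rejected(self):
        curve = ResponseCurve(x=np.array([0.0, 1e-9]),
                              current=np.array([0.0, 1e-9]),
                              x_kind="concentration")
        with pytest.raises(DomainError):
            relative_response(curve)


class TestKdRecovery:
    @pytest.mark.parametrize("kd", [1.47e-9, 0.31e-9])
    def test_round_trip_on_analytic_pipeline(self, kd):
        model = BindingModel(kd=kd)
        cf = analytic_fraction_curve(slope=-0.6)
        cc = calibration_curve(cf, model, DEFAULT_CONCENTRATIONS)
        rec = invert_response_for_kd(cc, cf)
        assert rec == pytest.approx(kd, rel=0.05)

    def test_constant_device_map_cannot_invert(self):
        cf = ResponseCurve(x=np.linspace(0, 1, 11), current=np.full(11, 1.0),
                           x_kind="fraction")
        cc = ResponseCurve(x=np.array([0.0, 1e-9]),
                           current=np.array([1.0, 1.0]),
                           x_kind="concentration")
        with pytest.raises(InversionError):
            invert_response_for_kd(cc, cf)


class TestDeviceComposition:
    def test_fraction_validation_precedes_solving(self, coarse_device):
        from rfetsense.device import program_polarity
        from rfetsense.probes import make_fixture
        fx = make_fixture("aptamer_cea")
        cond = default_interface_condition("aptamer_cea")
        with pytest.raises(ValidationError):
            current_vs_fraction(coarse_device, program_polarity("p"), fx, cond,
                                [0.5, 0.2])
        with pytest.raises(ValidationError):
            current_vs_fraction(coarse_device, program_polarity("p"), fx, cond,
                                [0.0, 1.2])

    def test_default_conditions_pair_screening_with_chemistry(self):
        apt = default_interface_condition("aptamer_cea")
        assert apt.mode == "wet" and apt.ionic_strength == pytest.approx(1.5e-3)
        assert default_interface_condition("protease_inhibitor").mode == "dry"

    def test_single_fraction_degenerate_sweep(self, coarse_device):
        from rfetsense.device import program_polarity
        from rfetsense.probes import make_fixture
        fx = make_fixture("protease_inhibitor")
        cond = default_interface_condition("protease_inhibitor")
        curve = current_vs_fraction(coarse_device, program_polarity("n"), fx,
                                    cond, [0.0])
        assert len(curve) == 1
        assert curve.current[0] > 0  # n-programmed electron current
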
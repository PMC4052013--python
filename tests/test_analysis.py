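import numpy as np
import pytest

import monofilm as mf
from monofilm.errors import DomainError, InsufficientDataError, RangeError


def linear_record(lift=70.0, slope=1.0, pis=None):
    """Record with A(pi) = lift − slope·pi (exactly linear)."""
    pis = np.linspace(0.0, 18.0, 10) if pis is None else pis
    return mf.IsothermRecord.from_points(lift - slope * pis, pis)


class TestSmoothing:
    @pytest.mark.parametrize("window,polyorder", [(5, 1), (11, 3)])
    def test_linear_segment_reproduced_exactly(self, window, polyorder):
        rec = linear_record(pis=np.linspace(0.0, 18.0, 40))
        out = mf.smooth_isotherm(rec, window, polyorder)
        np.testing.assert_allclose(out.pressure, rec.pressure, atol=1e-9)

    def test_quadratic_reproduced_exactly(self):
        area = np.linspace(100.0, 40.0, 60)
        pressure = 0.01 * (100.0 - area) ** 2 + 0.5
        rec = mf.IsothermRecord.from_points(area, pressure)
        out = mf.smooth_isotherm(rec, 11, 2)
        np.testing.assert_allclose(out.pressure, rec.pressure, atol=1e-9)

    def test_noise_rms_strictly_reduced(self):
        eos = mf.EOSSpec(model="volmer", a0=20.0, noise_sigma=0.1, seed=7)
        grid = mf.pressure_spaced_area_grid(eos, 1.0, 30.0, 300)
        noisy = mf.generate_pure_isotherm(eos, grid)
        clean = eos.pressure_of_area(noisy.area)
        smoothed = mf.smooth_isotherm(noisy, 11, 3)
        rms_before = np.sqrt(np.mean((noisy.pressure - clean) ** 2))
        rms_after = np.sqrt(np.mean((smoothed.pressure - clean) ** 2))
        assert rms_after < rms_before

    @pytest.mark.parametrize("window,polyorder", [(4, 2), (1, 0), (999, 3), (5, 5)])
    def test_invalid_parameters_rejected(self, window, polyorder):
        rec = linear_record(pis=np.linspace(0.0, 18.0, 40))
        with pytest.raises(DomainError):
            mf.smooth_isotherm(rec, window, polyorder)


class TestCompressionModulus:
    def test_ideal_gas_identity(self):
        """2-D ideal gas: C_s⁻¹(π) = π exactly; pipeline within 0.5%."""
        eos = mf.EOSSpec(model="ideal_gas")
        grid = mf.pressure_spaced_area_grid(eos, 1.0, 30.0, 400)
        curve = mf.compression_modulus(mf.generate_pure_isotherm(eos, grid))
        np.testing.assert_allclose(curve.cs_inverse, curve.pressure, rtol=5e-3)

    def test_volmer_closed_form_value(self, volmer_record):
        """Volmer film: C_s⁻¹ = π·A/(A − A0); at A = 120 Å² this is ≈ 5.139 mN/m."""
        curve = mf.compression_modulus(volmer_record)
        pi_at_120 = mf.THERMAL_CONSTANT_37C / 100.0  # ≈ 4.282 mN/m
        expected = 120.0 * mf.THERMAL_CONSTANT_37C / 100.0**2
        assert curve.at(pi_at_120) == pytest.approx(expected, rel=1e-2)

    def test_linear_condensed_segment_gives_2A(self):
        """A(π) = 60 − 0.5·π ⇒ C_s⁻¹ = 2·A; at π = 10 that is 110 mN/m."""
        rec = linear_record(lift=60.0, slope=0.5, pis=np.linspace(0.0, 30.0, 100))
        curve = mf.compression_modulus(rec)
        assert curve.at(10.0) == pytest.approx(110.0, rel=1e-2)

    @pytest.mark.parametrize("model,kwargs", [
        ("ideal_gas", {}),
        ("volmer", {"a0": 20.0}),
        ("two_segment", {}),
    ])
    def test_matches_fine_grid_oracle(self, model, kwargs):
        """Pipeline modulus equals fine-grid finite differences of the analytic curve."""
        eos = mf.EOSSpec(model=model, **kwargs)
        grid = mf.pressure_spaced_area_grid(eos, 1.0, 30.0, 400)
        curve = mf.compression_modulus(mf.generate_pure_isotherm(eos, grid))
        fine_pi = np.linspace(0.9, 30.1, 10_000)
        fine_a = eos.area_of_pressure(fine_pi)
        fine_cs = -fine_a * np.gradient(fine_pi, fine_a, edge_order=2)
        oracle = np.interp(curve.pressure, fine_pi, fine_cs)
        mask = np.ones(len(curve), dtype=bool)
        if model == "two_segment":  # derivative jump at the segment break
            mask = np.abs(curve.pressure - eos.break_pressure) > 0.3
        np.testing.assert_allclose(curve.cs_inverse[mask], oracle[mask], rtol=1e-2)

    def test_smoothing_neutral_on_polynomial_segments(self):
        rec = linear_record(lift=60.0, slope=0.5, pis=np.linspace(0.0, 30.0, 100))
        raw = mf.compression_modulus(rec)
        smoothed = mf.compression_modulus(rec, smoothing=(11, 3))
        np.testing.assert_allclose(smoothed.cs_inverse, raw.cs_inverse, rtol=1e-6)

    def test_insufficient_points_below_collapse(self):
        rec = linear_record(pis=np.linspace(0.0, 18.0, 10))
        info = mf.CollapseInfo(pi_coll=5.0, method="manual", point_index=3)
        with pytest.raises(InsufficientDataError):
            mf.compression_modulus(rec, collapse=info)


class TestMaxModulusAndPhase:
    def test_monotone_curve_takes_last_sample(self):
        curve = mf.CompressionModulusCurve(np.linspace(1, 20, 10), np.linspace(10, 100, 10))
        assert mf.max_compression_modulus(curve) == (100.0, 20.0)

    def test_interior_peak_found(self):
        pis = np.linspace(1, 20, 11)
        cs = 100.0 - (pis - 12.0) ** 2
        curve = mf.CompressionModulusCurve(pis, cs)
        cs_max, pi_at = mf.max_compression_modulus(curve)
        assert pi_at == pytest.approx(12.3, abs=0.5)

    def test_tie_broken_toward_lower_pressure(self):
        curve = mf.CompressionModulusCurve(np.array([5.0, 10.0, 15.0]), np.array([80.0, 90.0, 90.0]))
        assert mf.max_compression_modulus(curve) == (90.0, 10.0)

    def test_empty_curve_rejected(self):
        curve = mf.CompressionModulusCurve(np.array([]), np.array([]))
        with pytest.raises(DomainError):
            mf.max_compression_modulus(curve)

    @pytest.mark.parametrize("cs_max,label", [
        (5.0, "gaseous"),
        (30.0, "liquid-expanded"),
        (160.0, "liquid-condensed"),  # the condensed model-membrane regime
        (250.0, "liquid-condensed"),
        (300.0, "solid"),
    ])
    def test_phase_bands(self, cs_max, label):
        assert mf.classify_phase(cs_max).label == label

    def test_negative_modulus_rejected(self):
        with pytest.raises(DomainError):
            mf.classify_phase(-1.0)

    def test_custom_band_edges(self):
        assert mf.classify_phase(30.0, bands=(5.0, 20.0, 100.0)).label == "liquid-condensed"


class TestCollapseDetection:
    def test_hard_plateau_at_40(self):
        eos = mf.EOSSpec(model="two_segment", collapse=mf.CollapseSpec(40.0))
        grid = mf.pressure_spaced_area_grid(eos, 0.5, 46.0, 300, spacing="linear")
        det = mf.detect_collapse(mf.generate_pure_isotherm(eos, grid))
        assert det is not None
        assert det.pi_coll == pytest.approx(40.0, abs=0.5)

    def test_slope_drop_kink_at_35(self):
        # |dπ/dA| falls from 2.0 to 0.1 (95% drop) at the 35 mN/m breakpoint
        eos = mf.EOSSpec(model="two_segment", lift_off_area=98.0, slope1=0.5, slope2=10.0, break_pressure=35.0)
        grid = mf.pressure_spaced_area_grid(eos, 1.0, 40.0, 300, spacing="linear")
        det = mf.detect_collapse(mf.generate_pure_isotherm(eos, grid))
        assert det is not None
        assert det.pi_coll == pytest.approx(35.0, abs=0.5)

    def test_steepening_isotherm_has_no_collapse(self, volmer_record):
        assert mf.detect_collapse(volmer_record) is None

    def test_detected_pressure_tracks_generator_plateau(self):
        """Raising the plateau pressure raises detected π_coll monotonically."""
        detected = []
        for pc in (30.0, 34.0, 38.0, 42.0, 46.0):
            eos = mf.EOSSpec(model="two_segment", collapse=mf.CollapseSpec(pc))
            grid = mf.pressure_spaced_area_grid(eos, 0.5, pc + 6.0, 300, spacing="linear")
            det = mf.detect_collapse(mf.generate_pure_isotherm(eos, grid))
            detected.append(det.pi_coll)
        assert np.all(np.diff(detected) > 0)


class TestAreaAtPressure:
    def test_grid_pressure_returns_grid_area(self, membrane_record):
        i = 120
        pi = float(membrane_record.pressure[i])
        assert mf.area_at_pressure(membrane_record, pi) == pytest.approx(float(membrane_record.area[i]))

    def test_hand_linear_interpolation(self):
        # A = 70 − π sampled every 2 mN/m: between (60, 10) and (58, 12), π = 11 → 59 Å²
        rec = linear_record(lift=70.0, slope=1.0, pis=np.arange(0.0, 20.0, 2.0))
        assert mf.area_at_pressure(rec, 11.0) == pytest.approx(59.0, abs=1e-9)

    def test_target_above_range_rejected(self, membrane_record):
        with pytest.raises(RangeError):
            mf.area_at_pressure(membrane_record, 90.0)

    def test_interpolation_stops_at_collapse(self):
        eos = mf.EOSSpec(model="two_segment", collapse=mf.CollapseSpec(40.0))
        grid = mf.pressure_spaced_area_grid(eos, 0.5, 46.0, 300, spacing="linear")
        rec = mf.generate_pure_isotherm(eos, grid)
        with pytest.raises(RangeError):
            mf.area_at_pressure(rec, 43.0)


class TestFluidization:
    def test_identical_curves_give_zero(self, membrane_record):
        curve = mf.compression_modulus(membrane_record)
        deltas = mf.fluidization_delta(curve, [(0.3, curve), (0.5, curve)])
        assert all(d == 0.0 for _, d in deltas)

    def test_expanded_blend_fluidizes_condensed_membrane(self, attractive_series):
        spec, series = attractive_series
        d = dict(series)
        ref = mf.compression_modulus(d[0.0])
        mixed = [(x3, mf.compression_modulus(rec)) for x3, rec in series if 0.0 < x3 < 1.0]
        for x3, delta in mf.fluidization_delta(ref, mixed, pi_eval=15.0):
            assert delta > 0.0

    def test_pure_drug_endpoint_identity(self, attractive_series):
        spec, series = attractive_series
        d = dict(series)
        ref = mf.compression_modulus(d[0.0])
        drug_curve = mf.compression_modulus(d[1.0])
        [(_, delta)] = mf.fluidization_delta(ref, [(1.0, drug_curve)], pi_eval=15.0)
        assert delta == pytest.approx(ref.at(15.0) - drug_curve.at(15.0))

    def test_out_of_range_evaluation_names_curve(self, membrane_record):
        curve = mf.compression_modulus(membrane_record)
        short = mf.CompressionModulusCurve(np.array([1.0, 2.0, 3.0]), np.array([5.0, 6.0, 7.0]),
                                           source_label="short")
        with pytest.raises(RangeError, match="short"):
            mf.fluidization_delta(curve, [(0.5, short)], pi_eval=15.0)
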
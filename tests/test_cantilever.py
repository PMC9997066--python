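"""Stepped-cantilever modal analysis, Mel grid, stress and voltage models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmakit.cantilever import (
    CantileverGeometry,
    MaterialLayer,
    ValidationError,
    compose_segment_properties,
    composite_section,
    estimate_root_stress,
    mel_forward,
    mel_inverse,
    mel_spaced_frequencies,
    piezo_open_circuit_voltage,
    solve_stepped_modes,
    uniform_cantilever_frequency,
)
from rmakit.presets import design_frequencies

from conftest import E_SI, RHO_SI, fem_modes, uniform_geometry


class TestGeometryValidation:
    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValidationError):
            CantileverGeometry(l=-1e-3, c=1e-3, l_n=0.5e-3, c_n=0.1e-3, h=5e-6)
        with pytest.raises(ValidationError):
            CantileverGeometry(l=1e-3, c=1e-3, l_n=2e-3, c_n=0.1e-3, h=5e-6)
        with pytest.raises(ValidationError):
            # support beams wider than the plate
            CantileverGeometry(l=1e-3, c=0.1e-3, l_n=0.5e-3, c_n=0.1e-3, h=5e-6)

    def test_warns_outside_thin_beam_regime(self):
        with pytest.warns(UserWarning, match="thin-beam"):
            CantileverGeometry(l=1e-3, c=0.5e-3, l_n=0.5e-3, c_n=0.1e-3, h=60e-6)


class TestSegmentProperties:
    def test_single_layer_reduces_to_textbook_rigidity(self, si_layer):
        # E c h^3 / 12 for the wide segment of width 2.3 mm
        geom = CantileverGeometry(l=3.6e-3, c=2.3e-3, l_n=0.9e-3, c_n=0.13e-3, h=5e-6)
        props = compose_segment_properties(geom, [si_layer])
        assert props.EI2 == pytest.approx(E_SI * 2.3e-3 * (5e-6) ** 3 / 12, rel=1e-12)
        assert props.m2 == pytest.approx(RHO_SI * 2.3e-3 * 5e-6, rel=1e-12)
        # narrow segment sums over the two beams
        assert props.EI1 == pytest.approx(E_SI * 2 * 0.13e-3 * (5e-6) ** 3 / 12, rel=1e-12)

    def test_equal_width_segments_degenerate_to_uniform(self, si_layer):
        props = compose_segment_properties(uniform_geometry(), [si_layer])
        assert props.m1 == pytest.approx(props.m2)
        assert props.EI1 == pytest.approx(props.EI2)

    def test_zero_thickness_layer_is_identity(self, si_layer):
        geom = uniform_geometry()
        ghost = MaterialLayer("ghost", 0.0, 1e9, 1000.0)
        a = compose_segment_properties(geom, [si_layer])
        b = compose_segment_properties(geom, [si_layer, ghost])
        assert a == b

    def test_empty_layer_list_rejected(self):
        with pytest.raises(ValidationError):
            compose_segment_properties(uniform_geometry(), [])

    def test_composite_section_symmetric_stack(self):
        # two identical half-layers equal one full layer
        half = MaterialLayer("half", 2.5e-6, E_SI, RHO_SI)
        full = MaterialLayer("full", 5e-6, E_SI, RHO_SI)
        ei2, m2 = composite_section([half, half])
        ei1, m1 = composite_section([full])
        assert ei2 == pytest.approx(ei1, rel=1e-12)
        assert m2 == pytest.approx(m1, rel=1e-12)


class TestSteppedSolver:
    def test_uniform_limit_matches_closed_form(self, si_layer):
        """Equal segments must reproduce the clamped-free closed form."""
        geom = uniform_geometry()
        props = compose_segment_properties(geom, [si_layer])
        modes = solve_stepped_modes(props, geom, n_modes=3)
        for k, mode in enumerate(modes, start=1):
            f_exact = uniform_cantilever_frequency(geom.l, props.EI1, props.m1, k)
            assert mode.frequency == pytest.approx(f_exact, rel=1e-6)

    def test_eigenvalue_consistency(self, ref_geometries, ref_layers):
        """beta1^4 EI1/m1 = beta2^4 EI2/m2 = omega^2 for every mode."""
        geom = ref_geometries[0]
        props = compose_segment_properties(geom, ref_layers)
        for mode in solve_stepped_modes(props, geom, n_modes=3):
            w1 = mode.beta1**4 * props.EI1 / props.m1
            w2 = mode.beta2**4 * props.EI2 / props.m2
            assert w1 == pytest.approx(mode.omega**2, rel=1e-9)
            assert w2 == pytest.approx(mode.omega**2, rel=1e-9)

    def test_matches_independent_fem_oracle(self, ref_geometries, si_layers):
        """Transcendental roots agree with a Hermite-element eigensolver."""
        for geom in (ref_geometries[0], ref_geometries[7]):
            props = compose_segment_properties(geom, si_layers)
            modes = solve_stepped_modes(props, geom, n_modes=2)
            fem = fem_modes(geom, props.EI1, props.m1, props.EI2, props.m2)
            for mode, f_fem in zip(modes, fem):
                assert mode.frequency == pytest.approx(f_fem, rel=2e-3)

    def test_thickness_scaling(self, ref_geometries):
        """f scales linearly with h for a homogeneous plate (EI ~ h^3, m ~ h)."""
        geom = ref_geometries[0]
        f_by_h = []
        for h in (5e-6, 10e-6):
            g = CantileverGeometry(geom.l, geom.c, geom.l_n, geom.c_n, h)
            props = compose_segment_properties(g, [MaterialLayer("Si", h, E_SI, RHO_SI)])
            f_by_h.append(solve_stepped_modes(props, g, n_modes=2))
        for m5, m10 in zip(*f_by_h):
            assert m10.frequency == pytest.approx(2 * m5.frequency, rel=1e-6)

    def test_fundamental_monotonic_in_geometry(self, si_layers):
        """Longer plate -> lower f1; wider support beams -> higher f1."""
        def fund(l, c_n):
            g = CantileverGeometry(l=l, c=2.3e-3, l_n=0.9e-3, c_n=c_n, h=5e-6)
            props = compose_segment_properties(g, si_layers)
            return solve_stepped_modes(props, g, n_modes=1)[0].frequency

        lengths = [2.8e-3, 3.2e-3, 3.6e-3]
        f_of_l = [fund(l, 0.13e-3) for l in lengths]
        assert f_of_l[0] > f_of_l[1] > f_of_l[2]
        widths = [0.10e-3, 0.13e-3, 0.16e-3]
        f_of_w = [fund(3.6e-3, w) for w in widths]
        assert f_of_w[0] < f_of_w[1] < f_of_w[2]

    def test_frequency_ratio_material_independent(self, ref_geometries):
        """f(#8)/f(#1) is set by geometry alone and sits near the design ratio."""
        ratios = []
        for e_mod, rho in ((169e9, 2329.0), (130e9, 2329.0), (200e9, 4000.0)):
            layer = [MaterialLayer("x", 5e-6, e_mod, rho)]
            funds = []
            for geom in (ref_geometries[0], ref_geometries[7]):
                props = compose_segment_properties(geom, layer)
                funds.append(solve_stepped_modes(props, geom, n_modes=1)[0].frequency)
            ratios.append(funds[1] / funds[0])
        assert np.ptp(ratios) < 1e-6 * ratios[0]
        design_ratio = 717.0 / 253.0
        assert abs(ratios[0] / design_ratio - 1) < 0.12

    def test_scan_range_exhausted_error(self, si_layers):
        geom = uniform_geometry()
        props = compose_segment_properties(geom, si_layers)
        with pytest.raises(RuntimeError, match="scan range exhausted"):
            solve_stepped_modes(props, geom, n_modes=3, f_max=100.0)


class TestUniformClosedForm:
    def test_si_microbeam_value(self):
        # 1 mm x 0.1 mm x 5 um Si beam
        ei = E_SI * 1e-4 * (5e-6) ** 3 / 12
        m = RHO_SI * 1e-4 * 5e-6
        assert uniform_cantilever_frequency(1e-3, ei, m, 1) == pytest.approx(6881, rel=1e-3)

    def test_mode_ratio_is_geometry_free(self):
        f1 = uniform_cantilever_frequency(1e-3, 1e-10, 1e-6, 1)
        f2 = uniform_cantilever_frequency(1e-3, 1e-10, 1e-6, 2)
        assert f2 / f1 == pytest.approx((4.69409113 / 1.87510407) ** 2, rel=1e-9)

    def test_length_scaling(self):
        f_l = uniform_cantilever_frequency(1e-3, 1e-10, 1e-6, 1)
        f_4l = uniform_cantilever_frequency(4e-3, 1e-10, 1e-6, 1)
        assert f_l / f_4l == pytest.approx(16.0, rel=1e-12)

    def test_mode_index_range(self):
        with pytest.raises(ValidationError):
            uniform_cantilever_frequency(1e-3, 1e-10, 1e-6, 6)


class TestMelScale:
    def test_anchor_values(self):
        assert mel_forward(0.0) == 0.0
        assert mel_forward(700.0) == pytest.approx(2595 * np.log10(2), rel=1e-12)

    @given(st.floats(min_value=0.0, max_value=20000.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, f):
        assert mel_inverse(mel_forward(f)) == pytest.approx(f, rel=1e-9, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            mel_forward(-1.0)
        with pytest.raises(ValidationError):
            mel_inverse(-1.0)

    def test_grid_reproduces_design_frequencies(self):
        grid = mel_spaced_frequencies(253.0, 717.0, 8)
        # rounded grid within 1 Hz of every quoted design frequency
        assert np.all(np.abs(grid.hz_rounded - design_frequencies()) <= 1)
        assert grid.hz[0] == 253.0 and grid.hz[-1] == 717.0

    def test_grid_uniform_in_mel_and_convex_in_hz(self):
        grid = mel_spaced_frequencies(200.0, 800.0, 10)
        mels = mel_forward(grid.hz)
        gaps_mel = np.diff(mels)
        assert np.allclose(gaps_mel, gaps_mel[0], rtol=1e-9)
        gaps_hz = np.diff(grid.hz)
        assert np.all(np.diff(gaps_hz) > 0)  # denser at low frequencies

    def test_needs_two_points(self):
        with pytest.raises(ValidationError):
            mel_spaced_frequencies(200.0, 800.0, 1)


class TestPiezoVoltage:
    def test_worked_example_and_linearity(self):
        zno = MaterialLayer("ZnO", 0.5e-6, 140e9, 5606.0, d31=5.43e-12,
                            relative_permittivity=10.9)
        v = piezo_open_circuit_voltage(1e6, zno)
        assert v == pytest.approx(0.0281, rel=1e-2)
        assert piezo_open_circuit_voltage(0.0, zno) == 0.0
        assert piezo_open_circuit_voltage(2e6, zno) == pytest.approx(2 * v, rel=1e-12)

    def test_missing_constants_rejected(self):
        plain = MaterialLayer("Si", 5e-6, E_SI, RHO_SI)
        with pytest.raises(ValidationError):
            piezo_open_circuit_voltage(1e6, plain)


class TestRootStress:
    def test_zero_pressure_and_linearity(self, ref_geometries):
        geom = ref_geometries[0]
        assert estimate_root_stress(geom, 0.0) == 0.0
        s1 = estimate_root_stress(geom, 1.0)
        assert estimate_root_stress(geom, 2.5) == pytest.approx(2.5 * s1, rel=1e-12)

    def test_stepped_vs_standard_stress_ratio(self):
        """Width-stepping concentrates root stress ~5x vs a plain cantilever."""
        stepped = CantileverGeometry(l=2.6e-3, c=2.6e-3, l_n=0.8e-3,
                                     c_n=0.115e-3, h=5e-6)
        standard = CantileverGeometry(l=4.35e-3, c=4.35e-3, l_n=1.0e-3,
                                      c_n=4.35e-3 / 2, h=5e-6)
        ratio = estimate_root_stress(stepped, 1.0) / estimate_root_stress(standard, 1.0)
        assert 4.0 <= ratio <= 6.0
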
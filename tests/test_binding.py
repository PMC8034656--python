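import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import K11, K12, PHI_D11, PHI_D12, two_step_equilibrium_speciation
from doxorigami.binding import (
    BindingParameters,
    TitrationFitConfig,
    TitrationSeries,
    dissociation_half_time,
    fit_absorbance_deltas,
    fit_exponential_kinetics,
    fit_fluorescence_titration,
    forward_delta,
    fraction_bound,
    invert_quantum_yield,
    loading_density_increase,
    max_bound_per_bp,
    max_bound_per_bp_numerical,
    solve_free_bp,
)
from doxorigami.errors import DomainError, SaturationError, ValidationError
from doxorigami.synthetic import GeneratorConfig, gen_titration


def bisection_root(c_bp0, c_dox0, k11, k12, iterations=100):
    """Independent bisection oracle on the mass-balance residual."""
    a = k11 * k12
    b = k11 * (2.0 * k12 * c_dox0 - k12 * c_bp0 + 1.0)
    c = k11 * (c_dox0 - c_bp0) + 1.0

    def g(x):
        return ((a * x + b) * x + c) * x - c_bp0

    lo, hi = 0.0, c_bp0
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestForwardDelta:
    def test_zero_bp_gives_zero(self):
        assert forward_delta(0.0, K11, K12, PHI_D11, PHI_D12) == 0.0

    def test_saturation_limit_is_y12(self):
        assert forward_delta(1.0, K11, K12, PHI_D11, PHI_D12) == pytest.approx(
            PHI_D12, rel=1e-4
        )

    def test_against_species_fraction_evaluation(self):
        # independent route: weight the deltas by the complex mole fractions
        c = 10e-6
        denom = 1.0 + K11 * c + K11 * K12 * c * c
        theta11 = K11 * c / denom
        theta12 = K11 * K12 * c * c / denom
        expected = PHI_D11 * theta11 + PHI_D12 * theta12
        assert forward_delta(c, K11, K12, PHI_D11, PHI_D12) == pytest.approx(expected)
        assert expected == pytest.approx(-0.709, abs=5e-4)

    @given(st.floats(min_value=0, max_value=1e-3))
    @settings(max_examples=100, deadline=None)
    def test_bounded_for_quenching_deltas(self, c):
        val = forward_delta(c, K11, K12, PHI_D11, PHI_D12)
        assert min(PHI_D11, PHI_D12) - 1e-12 <= val <= 0.0


class TestSolveFreeBp:
    def test_no_dox_returns_total(self):
        assert solve_free_bp(28e-6, 0.0, K11, K12) == 28e-6

    def test_no_bp_returns_zero(self):
        assert solve_free_bp(0.0, 3e-6, K11, K12) == 0.0

    def test_reference_point(self):
        # oracle: bisection on the monotone mass-balance residual
        got = solve_free_bp(28e-6, 3e-6, K11, K12)
        oracle = bisection_root(28e-6, 3e-6, K11, K12)
        assert got == pytest.approx(oracle, rel=1e-9)
        assert got == pytest.approx(22.6e-6, rel=5e-3)

    @given(
        st.floats(min_value=1e-9, max_value=1e-2),
        st.floats(min_value=1e-9, max_value=1e-2),
        st.floats(min_value=1e2, max_value=1e7),
        st.floats(min_value=1e2, max_value=1e7),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bisection_oracle(self, c_bp0, c_dox0, k11, k12):
        got = solve_free_bp(c_bp0, c_dox0, k11, k12)
        oracle = bisection_root(c_bp0, c_dox0, k11, k12)
        assert 0.0 <= got <= c_bp0
        assert got == pytest.approx(oracle, rel=1e-8, abs=1e-20)

    def test_matches_two_step_speciation_oracle(self):
        for c_bp0, c_dox0 in [(28e-6, 3e-6), (5e-6, 3e-6), (100e-6, 6e-6)]:
            _, free_bp = two_step_equilibrium_speciation(c_dox0, c_bp0, K11, K12)
            assert solve_free_bp(c_bp0, c_dox0, K11, K12) == pytest.approx(
                free_bp, rel=1e-6
            )

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            solve_free_bp(-1e-6, 3e-6, K11, K12)
        with pytest.raises(DomainError):
            solve_free_bp(1e-6, 3e-6, -K11, K12)


class TestFractionBound:
    def test_limits(self):
        assert fraction_bound(0.0, K11, K12) == 0.0
        assert fraction_bound(1.0, K11, K12) == pytest.approx(1.0, abs=1e-9)

    def test_reference_point_vs_speciation_oracle(self):
        c_ub = 22.6e-6
        assert fraction_bound(c_ub, K11, K12) == pytest.approx(0.969, abs=1e-3)
        # brute-force two-step equilibrium: f_b = 1 - free_dox/c_dox0
        free_dox, free_bp = two_step_equilibrium_speciation(3e-6, 28e-6, K11, K12)
        assert fraction_bound(free_bp, K11, K12) == pytest.approx(
            1.0 - free_dox / 3e-6, rel=1e-9
        )

    @given(st.lists(st.floats(min_value=0, max_value=1e-3), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_free_bp(self, concentrations):
        cs = sorted(concentrations)
        fb = [fraction_bound(c, K11, K12) for c in cs]
        assert all(b >= a - 1e-15 for a, b in zip(fb, fb[1:]))

    def test_mass_conservation_along_titration(self):
        c_dox0 = 3e-6
        for c_bp0 in np.linspace(0, 200e-6, 40):
            c_ub = solve_free_bp(float(c_bp0), c_dox0, K11, K12)
            f_b = fraction_bound(c_ub, K11, K12)
            c_dox_b = f_b * c_dox0
            assert c_dox_b <= c_dox0 + 1e-18
            # bp bound in complexes never exceeds the supplied bp
            denom = 1.0 + K11 * c_ub + K11 * K12 * c_ub**2
            bp_in_complexes = c_dox0 * (K11 * c_ub + 2 * K11 * K12 * c_ub**2) / denom
            assert bp_in_complexes <= c_bp0 + 1e-15


class TestMaxBoundPerBp:
    def test_closed_form_value(self):
        assert max_bound_per_bp(3e-6, K11) == pytest.approx(0.375)

    def test_limits(self):
        assert max_bound_per_bp(1.0, 1e12) == pytest.approx(1.0, abs=1e-9)
        assert max_bound_per_bp(1e-12, 1e-3) == pytest.approx(0.0, abs=1e-9)

    def test_numerical_scan_converges_to_closed_form(self):
        numerical = max_bound_per_bp_numerical(3e-6, K11, K12)
        assert numerical == pytest.approx(max_bound_per_bp(3e-6, K11), rel=1e-3)


class TestInvertQuantumYield:
    def test_zero_observable_gives_zero(self):
        assert invert_quantum_yield(0.0, K11, K12, PHI_D11, PHI_D12) == 0.0

    @given(st.floats(min_value=1e-8, max_value=1e-3))
    @settings(max_examples=200, deadline=None)
    def test_forward_inverse_identity(self, c_true):
        dphi = forward_delta(c_true, K11, K12, PHI_D11, PHI_D12)
        c_back = invert_quantum_yield(dphi, K11, K12, PHI_D11, PHI_D12)
        assert c_back == pytest.approx(c_true, rel=1e-6)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            invert_quantum_yield(PHI_D12, K11, K12, PHI_D11, PHI_D12)

    def test_positive_observable_rejected(self):
        with pytest.raises(DomainError):
            invert_quantum_yield(0.1, K11, K12, PHI_D11, PHI_D12)

    def test_below_saturation_rejected(self):
        with pytest.raises(DomainError):
            invert_quantum_yield(PHI_D12 - 0.01, K11, K12, PHI_D11, PHI_D12)


class TestBindingParameters:
    def test_positive_constants_required(self):
        with pytest.raises(ValidationError):
            BindingParameters(k11=-1.0, k12=K12)

    def test_deltas_must_be_in_unit_interval(self):
        with pytest.raises(ValidationError):
            BindingParameters(k11=K11, k12=K12, phi_delta_11={494.0: -1.5},
                              phi_delta_12={494.0: -0.9})

    def test_channel_lookup(self, planted_params):
        assert planted_params.phi_deltas(494.0) == (PHI_D11, PHI_D12)
        with pytest.raises(KeyError):
            planted_params.phi_deltas(450.0)


class TestTitrationSeries:
    def test_rejects_decreasing_grid(self):
        with pytest.raises(ValidationError):
            TitrationSeries(
                c_dox_total=3e-6,
                c_bp_total=np.array([1e-6, 0.5e-6]),
                delta_phi={494.0: np.array([-0.1, -0.2])},
            )

    def test_rejects_positive_delta_phi(self):
        with pytest.raises(ValidationError, match="quenching only"):
            TitrationSeries(
                c_dox_total=3e-6,
                c_bp_total=np.array([0.0, 1e-6]),
                delta_phi={494.0: np.array([0.0, 0.3])},
            )


class TestFitFluorescenceTitration:
    def test_noiseless_recovery(self):
        synth = gen_titration(GeneratorConfig(seed=0, noise_phi=0.0))
        params = fit_fluorescence_titration(synth.series)
        assert params.k11 == pytest.approx(K11, rel=1e-3)
        assert params.k12 == pytest.approx(K12, rel=1e-3)
        for ch in synth.series.channels:
            assert params.phi_delta_11[ch] == pytest.approx(PHI_D11, rel=1e-3)
            assert params.phi_delta_12[ch] == pytest.approx(PHI_D12, rel=1e-3)

    def test_noisy_recovery_within_decilog(self):
        synth = gen_titration(GeneratorConfig(seed=1, noise_phi=0.01))
        params = fit_fluorescence_titration(synth.series)
        assert abs(np.log10(params.k11 / K11)) <= 0.1
        assert abs(np.log10(params.k12 / K12)) <= 0.1
        assert "k11" in params.uncertainties

    def test_too_few_points_rejected(self):
        series = TitrationSeries(
            c_dox_total=3e-6,
            c_bp_total=np.array([0.0, 1e-6, 1e-5]),
            delta_phi={494.0: np.array([0.0, -0.2, -0.6])},
        )
        with pytest.raises(ValidationError, match="at least 6"):
            fit_fluorescence_titration(series)

    def test_narrow_span_rejected(self):
        grid = np.linspace(1e-6, 2e-6, 8)
        series = TitrationSeries(
            c_dox_total=3e-6,
            c_bp_total=grid,
            delta_phi={494.0: -0.3 * np.ones(8)},
        )
        with pytest.raises(ValidationError, match="10-fold"):
            fit_fluorescence_titration(series)


class TestFitAbsorbanceDeltas:
    def test_noiseless_linear_recovery(self):
        synth = gen_titration(
            GeneratorConfig(seed=0, noise_phi=0.0, noise_a=0.0), with_absorbance=True
        )
        eps = fit_absorbance_deltas(synth.series, K11, K12)
        e11, e12 = eps[494.0]
        assert e11 == pytest.approx(-4200.0, rel=1e-9)
        assert e12 == pytest.approx(-3300.0, rel=1e-9)

    def test_zero_absorbance_gives_zero_deltas(self):
        grid = np.array([0, 1, 2, 5, 10, 20, 40], dtype=float) * 3e-6
        series = TitrationSeries(
            c_dox_total=3e-6,
            c_bp_total=grid,
            delta_phi={},
            delta_a={494.0: np.zeros(grid.size)},
        )
        eps = fit_absorbance_deltas(series, K11, K12)
        assert eps[494.0] == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_missing_absorbance_rejected(self):
        grid = np.array([0, 1e-6, 1e-5])
        series = TitrationSeries(
            c_dox_total=3e-6, c_bp_total=grid, delta_phi={494.0: np.zeros(3)}
        )
        with pytest.raises(ValidationError, match="no absorbance"):
            fit_absorbance_deltas(series, K11, K12)


class TestFitExponentialKinetics:
    def test_planted_recovery(self):
        t = np.linspace(0, 10, 10)
        v = 1.0 * np.exp(-0.5 * t) + 0.2
        fit = fit_exponential_kinetics(t, v)
        assert fit.a == pytest.approx(1.0, rel=1e-3)
        assert fit.b == pytest.approx(0.5, rel=1e-3)
        assert fit.c == pytest.approx(0.2, rel=1e-3)
        assert fit.half_life == pytest.approx(np.log(2) / 0.5, rel=1e-3)

    def test_constant_data_flags_no_decay(self):
        fit = fit_exponential_kinetics(np.linspace(0, 10, 6), np.full(6, 0.2))
        assert fit.no_decay
        assert fit.a == 0.0
        assert fit.c == pytest.approx(0.2)
        assert fit.half_life == np.inf

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match="at least 4"):
            fit_exponential_kinetics(np.array([0.0, 1.0]), np.array([1.0, 0.5]))


class TestWorkedArithmetic:
    def test_loading_density_increase(self):
        assert loading_density_increase(0.17, 0.25) == pytest.approx(47.06, abs=0.01)
        assert loading_density_increase(0.10, 0.16) == pytest.approx(60.0)

    def test_dissociation_half_time(self):
        assert dissociation_half_time(2.07) == pytest.approx(0.335, abs=0.001)
        with pytest.raises(DomainError):
            dissociation_half_time(0.0)
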
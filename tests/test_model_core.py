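"""Unit checks of the FvCB components and the two ODE right-hand sides.

Frozen expected values were computed by direct single-line evaluation
of each closed-form expression with the default tomato parameter set.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import photodyn as P
from photodyn import model

TL25 = 298.15


@pytest.mark.parametrize(
    "Tl, c, dHa, expected",
    [
        (TL25, 19.02, 37.83, 42.89266271111762),  # Gamma* (umol/mol)
        (TL25, 12.3772, 23.72, 16.578843123126067),  # Ko (kPa)
        (TL25, 37.96, 79.43, 371.11651447010826),  # Kc (umol/mol)
    ],
)
def test_arrhenius_scaling_values(Tl, c, dHa, expected):
    assert P.temperature_response(Tl, c, dHa) == pytest.approx(expected, rel=1e-12)


def test_arrhenius_unity_when_exponent_vanishes():
    c, dHa, R1 = 19.02, 37.83, 0.008314
    Tl = dHa / (R1 * c)  # exponent exactly zero
    assert P.temperature_response(Tl, c, dHa, R1) == pytest.approx(1.0, abs=1e-14)


def test_arrhenius_monotone_in_temperature(params):
    Tl = np.linspace(278.15, 318.15, 200)
    for c, dHa in [(params.c1, params.dHa1), (params.c2, params.dHa2),
                   (params.c3, params.dHa3)]:
        vals = P.temperature_response(Tl, c, dHa, params.R1)
        assert np.all(np.diff(vals) > 0)


def test_arrhenius_rejects_nonpositive_temperature():
    with pytest.raises(ValueError):
        P.temperature_response(-1.0, 19.02, 37.83)


class TestElectronTransport:
    def test_dark_and_reference_values(self, params):
        J = lambda I: P.electron_transport(I, params.Jmax, params.theta, params.gamma)
        assert J(0.0) == 0.0
        assert J(200.0) == pytest.approx(76.81749684264769, rel=1e-12)
        assert J(1e6) == pytest.approx(params.Jmax, rel=0.01)

    def test_negative_irradiance_rejected(self, params):
        with pytest.raises(ValueError):
            P.electron_transport(-1.0, params.Jmax, params.theta, params.gamma)

    def test_satisfies_defining_quadratic(self):
        """J is the smaller root of γx² − (Jmax+θI)x + JmaxθI = 0."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            I = rng.uniform(0.0, 2000.0)
            Jmax = rng.uniform(50.0, 400.0)
            theta = rng.uniform(0.1, 1.5)
            gamma = rng.uniform(0.05, 1.0)
            J = P.electron_transport(I, Jmax, theta, gamma)
            roots = np.roots([gamma, -(Jmax + theta * I), Jmax * theta * I])
            assert J == pytest.approx(min(roots.real), rel=1e-10, abs=1e-10)

    def test_monotone_and_bounded(self, params):
        I = np.linspace(0.0, 5000.0, 500)
        J = P.electron_transport(I, params.Jmax, params.theta, params.gamma)
        assert np.all(np.diff(J) >= 0)
        assert np.all((0 <= J) & (J <= params.Jmax))

    def test_initial_slope_is_theta(self, params):
        """For θI ≪ Jmax the hyperbola reduces to J ≈ θI."""
        I = 1e-3
        J = P.electron_transport(I, params.Jmax, params.theta, 1.0)
        assert J / I == pytest.approx(params.theta, rel=1e-4)


class TestCarboxylationRates:
    def test_rubisco_limited_reference(self, params):
        assert P.rubisco_limited_rate(400.0, TL25, params) == pytest.approx(
            31.985165622493557, rel=1e-12)

    def test_rubisco_limits(self, params):
        assert P.rubisco_limited_rate(1e9, TL25, params) == pytest.approx(
            params.Vcmax, rel=1e-6)
        assert P.rubisco_limited_rate(1e-9, TL25, params) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            P.rubisco_limited_rate(-10.0, TL25, params)

    def test_transport_limited_reference(self, params):
        assert P.transport_limited_rate(400.0, TL25, 200.0, params) == pytest.approx(
            15.813054207818938, rel=1e-12)

    def test_transport_limits(self, params):
        assert P.transport_limited_rate(400.0, TL25, 0.0, params) == 0.0
        J = P.electron_transport(500.0, params.Jmax, params.theta, params.gamma)
        assert P.transport_limited_rate(1e9, TL25, 500.0, params) == pytest.approx(
            J / 4.0, rel=1e-6)

    def test_rates_monotone_in_ci(self, params):
        gs = P.gamma_star(TL25, params)
        ci = np.linspace(gs + 1.0, 2000.0, 300)
        for Tl, I in [(TL25, 100.0), (290.0, 800.0), (305.0, 1500.0)]:
            wc = P.rubisco_limited_rate(ci, Tl, params)
            wj = P.transport_limited_rate(ci, Tl, I, params)
            an, _ = P.steady_state_assimilation(ci, Tl, I, params)
            assert np.all(np.diff(wc) > 0)
            assert np.all(np.diff(wj) > 0)
            assert np.all(np.diff(an) >= 0)


class TestSteadyStateAssimilation:
    def test_reference_value_is_transport_limited(self, params):
        an, lim = P.steady_state_assimilation(400.0, TL25, 200.0, params)
        assert an == pytest.approx(13.117394206397446, rel=1e-12)
        assert lim == "Wj"

    def test_at_compensation_point_only_respiration(self, params):
        gs = P.gamma_star(TL25, params)
        an, _ = P.steady_state_assimilation(gs, TL25, 1000.0, params)
        assert an == pytest.approx(-params.Rd, abs=1e-12)

    def test_high_light_low_ci_is_rubisco_limited(self, params):
        _, lim = P.steady_state_assimilation(100.0, TL25, 1200.0, params)
        assert lim == "Wc"

    def test_tie_reports_rubisco(self, params):
        an, lim = P.steady_state_assimilation(400.0, TL25, 0.0, params)
        # dark: Wj = 0 < Wc, so Wj; equality only when both rates match
        assert lim == "Wj"
        # construct an exact tie by comparing a rate against itself
        wc = P.rubisco_limited_rate(300.0, TL25, params)
        assert np.where(wc <= wc, "Wc", "Wj") == "Wc"


@pytest.mark.parametrize(
    "gtc, ca, ci, expected", [(0.2, 400.0, 300.0, 20.0), (0.15, 400.0, 400.0, 0.0),
                              (0.1, 400.0, 500.0, -10.0)])
def test_fick_flux(gtc, ca, ci, expected):
    assert P.fick_assimilation(gtc, ca, ci) == pytest.approx(expected, rel=1e-12)


def test_fick_requires_positive_conductance():
    with pytest.raises(ValueError):
        P.fick_assimilation(0.0, 400.0, 300.0)


class TestStomatalTarget:
    @pytest.mark.parametrize("I, expected", [(0.0, 0.1), (500.0, 0.265), (2000.0, 0.325)])
    def test_saturating_linear_400(self, params, I, expected):
        assert P.stomatal_target(I, 400.0, params) == pytest.approx(expected, rel=1e-12)

    def test_800_regime_and_nearest_fallback(self, params):
        assert P.stomatal_target(0.0, 800.0, params) == pytest.approx(0.165)
        # ca between the regimes snaps to the nearest one
        assert P.stomatal_target(0.0, 550.0, params) == pytest.approx(0.1)

    def test_bounds_and_monotone(self, params):
        I = np.linspace(0.0, 3000.0, 400)
        G = P.stomatal_target(I, 400.0, params)
        assert np.all(np.diff(G) >= 0)
        assert np.all((0.1 <= G) & (G <= 0.325))


class TestStomatalRhs:
    def test_opening_rate(self, params):
        # G(606.06..., 400) = 0.3; target above state -> ku branch
        I = (0.3 - 0.1) / 0.00033
        assert P.stomatal_rhs(0.2, I, 400.0, params) == pytest.approx(
            0.1 / 179.4, rel=1e-9)

    def test_closing_rate(self, params):
        I = (0.2 - 0.1) / 0.00033
        assert P.stomatal_rhs(0.3, I, 400.0, params) == pytest.approx(
            -0.1 / 830.3, rel=1e-9)

    def test_fixed_point_and_continuity(self, params):
        I = (0.25 - 0.1) / 0.00033
        G = P.stomatal_target(I, 400.0, params)
        assert P.stomatal_rhs(G, I, 400.0, params) == 0.0
        eps = 1e-12
        assert abs(P.stomatal_rhs(G - eps, I, 400.0, params)) < 1e-13
        assert abs(P.stomatal_rhs(G + eps, I, 400.0, params)) < 1e-13


class TestCiRhs:
    def test_prefactor_magnitude(self, params):
        """R·Tl/(d·Pa) ≈ 242.9 m² mol⁻¹ at 296 K."""
        state = P.LeafState(gtc=0.2, ci=300.0)
        env = P.EnvironmentSample(t=0.0, I=300.0, Tl=296.0, ca=400.0)
        an_fvcb, _ = P.steady_state_assimilation(300.0, 296.0, 300.0, params)
        expected = 242.87628916851713 * (0.2 * 100.0 - an_fvcb)
        assert P.ci_rhs(state, env, params) == pytest.approx(expected, rel=1e-12)

    def test_zero_at_steady_state(self, params):
        env = P.EnvironmentSample(t=0.0, I=300.0, Tl=296.0, ca=400.0)
        state = P.steady_state_solve(env, params)
        assert abs(P.ci_rhs(state, env, params)) < 1e-6

    def test_zero_when_bracket_constructed_to_vanish(self, params):
        ci, Tl, I = 350.0, 296.0, 400.0
        an_fvcb, _ = P.steady_state_assimilation(ci, Tl, I, params)
        gtc = an_fvcb / (400.0 - ci)  # Fick flux equals FvCB assimilation
        state = P.LeafState(gtc=gtc, ci=ci)
        env = P.EnvironmentSample(t=0.0, I=I, Tl=Tl, ca=400.0)
        assert P.ci_rhs(state, env, params) == pytest.approx(0.0, abs=1e-10)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    I=st.floats(0.0, 2500.0),
    Tl=st.floats(263.0, 323.0),
    ca=st.floats(50.0, 1500.0),
    gtc=st.floats(1e-3, 1.0),
    ci=st.floats(1.0, 2000.0),
    scale=st.floats(0.5, 1.5),
)
def test_all_outputs_finite_over_parameter_neighbourhood(I, Tl, ca, gtc, ci, scale):
    """Finiteness across valid inputs and the tomato set scaled ±50%."""
    p = P.ModelParameters().replace(
        Vcmax=99.25 * scale, Jmax=190.68 * scale, Rd=1.0 * scale,
        ku=179.4 * scale, kd=830.3 * scale,
    )
    env = P.EnvironmentSample(t=0.0, I=I, Tl=Tl, ca=ca)
    state = P.LeafState(gtc=gtc, ci=ci)
    values = [
        P.electron_transport(I, p.Jmax, p.theta, p.gamma),
        P.rubisco_limited_rate(ci, Tl, p),
        P.transport_limited_rate(ci, Tl, I, p),
        P.steady_state_assimilation(ci, Tl, I, p)[0],
        P.fick_assimilation(gtc, ca, ci),
        P.stomatal_target(I, ca, p),
        P.stomatal_rhs(gtc, I, ca, p),
        P.ci_rhs(state, env, p),
    ]
    assert np.all(np.isfinite(values))
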
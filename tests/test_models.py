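"""Model-layer checks: amplitude building blocks, limit reductions,
quadrature convergence, intensities and model-free analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sansfit as sf
from sansfit.models import _polymer_ev_form_factor


# --------------------------------------------------------------------------
# amplitude building blocks


@pytest.mark.parametrize("u,expected,atol", [
    (0.0, 1.0, 0.0),
    (4.4934, 0.0, 1e-4),          # first zero, root of tan u = u
    (np.pi, 3 / np.pi ** 2, 1e-12),
])
def test_sphere_amplitude_values(u, expected, atol):
    assert sf.sphere_amplitude(u) == pytest.approx(expected, abs=max(atol, 1e-12))


def test_sphere_amplitude_continuous_at_origin():
    u = np.array([0.0, 1e-6, 1e-4, 2e-4, 1e-3])
    amp = sf.sphere_amplitude(u)
    assert np.all(np.abs(amp - 1) <= 2e-7)  # 1 - u^2/10 at u = 1e-3
    # decreasing up to rounding jitter in the cancellation-prone region
    assert np.all(np.diff(amp) <= 1e-7)


def test_ellipsoid_amplitude_degeneracies():
    q = np.linspace(0.0, 0.4, 30)
    # polar view: only the polar semi-axis matters
    np.testing.assert_allclose(
        sf.ellipsoid_amplitude(q, 0.0, 30.0, 50.0),
        sf.sphere_amplitude(q * 30.0), rtol=1e-12)
    # spherical degeneracy: alpha-independent
    for alpha in (0.0, 0.4, np.pi / 2):
        np.testing.assert_allclose(
            sf.ellipsoid_amplitude(q, alpha, 25.0, 25.0),
            sf.sphere_amplitude(q * 25.0), rtol=1e-12)
    assert sf.ellipsoid_amplitude(0.0, 0.3, 30.0, 50.0) == pytest.approx(1.0)


def test_cylinder_amplitude_limits():
    from scipy.special import j1
    q = np.linspace(0.01, 0.4, 30)
    assert sf.cylinder_amplitude(0.0, 0.3, 20.0, 100.0) == pytest.approx(1.0)
    np.testing.assert_allclose(
        sf.cylinder_amplitude(q, np.pi / 2, 20.0, 100.0),
        2 * j1(q * 20) / (q * 20), rtol=1e-10)
    np.testing.assert_allclose(
        sf.cylinder_amplitude(q, 0.0, 20.0, 100.0),
        np.sin(0.5 * q * 100) / (0.5 * q * 100), rtol=1e-10)


# --------------------------------------------------------------------------
# dumbbell amplitude: closed vs numeric


def test_closed_forward_limit_is_volume_difference():
    p = sf.DumbbellParams(60, 25, 40, 10)
    ve = 4 / 3 * np.pi * 25 * 40 ** 2
    vc = np.pi * 10 ** 2 * (60 + 50)
    assert sf.dumbbell_amplitude_closed(0.0, 0.0, p) == pytest.approx(
        2 * ve - vc, rel=1e-12)


def test_closed_coincident_spheres_superposition():
    # d = 0, no hole, spherical lobes: amplitudes superpose to 2 V A(qR)
    R = 30.0
    p = sf.DumbbellParams(0.0, R, R, 0.0)
    q = np.linspace(0.0, 0.3, 40)
    vs = 4 / 3 * np.pi * R ** 3
    np.testing.assert_allclose(
        sf.dumbbell_amplitude_closed(q, 0.7, p),
        2 * vs * sf.sphere_amplitude(q * R), rtol=1e-10)


def test_numeric_matches_closed_when_exact():
    # no overlap and no hole: the superposition is exact
    p = sf.DumbbellParams(80, 30, 40, 0.0)
    q = np.linspace(0.005, 0.24, 50)   # q L_tot < 20 regime and beyond
    for alpha in (0.2, 0.9, 1.4):
        fc = sf.dumbbell_amplitude_closed(q, alpha, p)
        fn = sf.dumbbell_amplitude_numeric(q, alpha, p)
        assert np.max(np.abs(fn - fc)) < 5e-3 * np.max(np.abs(fc))


def test_numeric_forward_limit_matches_monte_carlo_volume():
    p = sf.ANKAIC_DUMBBELL
    f0 = float(sf.dumbbell_amplitude_numeric(np.array([0.0]), 0.0, p)[0])
    vol, se = sf.mc_volume(p, n=400_000, seed=3)
    assert abs(f0 - vol) < max(3 * se, 0.01 * vol)
    assert f0 == pytest.approx(p.volume(), rel=1e-10)


def test_numeric_sphere_degeneracy():
    # coincident spherical lobes reduce to one sphere (overlap counted once)
    R = 28.0
    p = sf.DumbbellParams(0.0, R, R, 0.0)
    q = np.linspace(0.0, 0.35, 60)
    vs = 4 / 3 * np.pi * R ** 3
    ref = vs * sf.sphere_amplitude(q * R)
    fn = sf.dumbbell_amplitude_numeric(q, 0.5, p)
    assert np.max(np.abs(fn - ref)) < 2e-3 * vs


def test_numeric_convergence_check_raises_when_coarse():
    with pytest.raises(sf.QuadratureError):
        sf.dumbbell_amplitude_numeric(
            np.linspace(0.3, 0.5, 5), 0.1, sf.ANKAIC_DUMBBELL,
            n_z=3, check=True)
    # converged at the default
    sf.dumbbell_amplitude_numeric(
        np.linspace(0.3, 0.5, 5), 0.1, sf.ANKAIC_DUMBBELL, check=True)


def test_closed_approximation_error_documented_scale():
    # overlapping reference geometry: closed form is a few-percent-level
    # approximation of the exact indicator amplitude, not equal to it
    p = sf.ANKAIC_DUMBBELL
    fc = float(sf.dumbbell_amplitude_closed(0.05, np.pi / 4, p))
    fn = float(sf.dumbbell_amplitude_numeric(np.array([0.05]),
                                             np.pi / 4, p)[0])
    assert abs(fc - fn) / abs(fn) < 0.6
    assert fc != pytest.approx(fn, rel=1e-3)


# --------------------------------------------------------------------------
# orientational average and intensities


def test_orientational_average_isotropic_exact():
    q = np.linspace(0.0, 0.3, 20)
    R = 30.0
    avg = sf.orientational_average(
        lambda qq, al: sf.sphere_amplitude(qq * R) * np.ones_like(al), q)
    np.testing.assert_allclose(avg, sf.sphere_amplitude(q * R) ** 2,
                               rtol=1e-10)


def test_orientational_average_node_doubling_stable():
    p = sf.ANKAIC_DUMBBELL
    q = sf.make_q_grid(0.005, 0.3, 30)

    def amp(qq, al):
        return sf.dumbbell_amplitude_numeric(qq, al, p)

    a76 = sf.orientational_average(amp, q, n_nodes=76, check=False)
    a152 = sf.orientational_average(amp, q, n_nodes=152, check=False)
    assert np.max(np.abs(a76 - a152)) < 1e-4 * np.max(a152)


def test_dumbbell_intensity_forward_normalization(q_grid):
    p = sf.DumbbellParams(53, 35.4, 45.5, 17.4, scale=2.5, background=0.01)
    tiny = sf.dumbbell_intensity(np.array([1e-5, 2e-5]), p)
    assert tiny.I[0] == pytest.approx(2.5 + 0.01, rel=1e-6)


def test_dumbbell_intensity_upturn_diverges_low_q():
    p_up = sf.DumbbellParams(53, 35.4, 45.5, 17.4, scale=1.0,
                             upturn_amplitude=1e-7, upturn_exponent=3.0)
    q = np.array([1e-4, 1e-3, 0.005])
    I = sf.dumbbell_intensity(q, p_up).I
    assert I[0] > 50 * I[2]          # power-law blow-up below the knee
    assert I[0] == pytest.approx(1e-7 * 1e12 + 1.0, rel=1e-2)


def test_intensity_bounded_below_by_background():
    rng = np.random.default_rng(7)
    q = sf.make_q_grid(0.005, 0.5, 60)
    for _ in range(5):
        p = sf.DumbbellParams(
            rng.uniform(0, 80), rng.uniform(10, 50), rng.uniform(20, 60),
            rng.uniform(0, 15), scale=rng.uniform(0.5, 2),
            background=rng.uniform(0, 0.01),
            upturn_amplitude=rng.uniform(0, 1e-6))
        I = sf.dumbbell_intensity(q, p).I
        assert np.all(I >= p.background - 1e-15)


def test_dumbbell_high_q_slope_near_porod():
    # oscillation-averaged high-q slope of a sharp-interface body is ~ -4
    p = sf.DumbbellParams(50, 32.4, 44.5, 16.8)
    q = sf.make_q_grid(0.005, 0.5, 300)
    c = sf.dumbbell_intensity(q, p)
    expo = sf.porod_exponent(
        sf.ScatteringCurve(q, c.I, np.zeros_like(q)), (0.15, 0.5))
    assert 3.3 < expo < 4.7


def test_closed_method_warns_on_overlap(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="sansfit.models"):
        sf.dumbbell_intensity(np.array([0.01, 0.1]), sf.ANKAIC_DUMBBELL,
                              method="closed", n_alpha=32)
    assert any("overlap" in r.message for r in caplog.records)


# --------------------------------------------------------------------------
# polymer excluded-volume model


def test_polymer_forward_limit():
    p = sf.PolymerEVParams(rg=3.4, porod_exponent=3.0, scale=2.0,
                           background=0.05)
    I = sf.polymer_ev_intensity(np.array([1e-6, 1e-5]), p).I
    assert I[0] == pytest.approx(2.05, rel=1e-8)


def test_polymer_reduces_to_debye_coil_at_m2():
    # m = 2 (nu = 1/2) must equal the Gaussian-coil Debye function
    rg_A = 30.0
    q = sf.make_q_grid(0.001, 0.5, 200)
    x = q ** 2 * rg_A ** 2
    debye = 2 * (np.exp(-x) - 1 + x) / x ** 2
    P = _polymer_ev_form_factor(q, rg_A, 2.0)
    assert np.max(np.abs(P - debye)) < 1e-8


def test_polymer_debye_value_at_x1():
    P = _polymer_ev_form_factor(np.array([1.0 / 30.0]), 30.0, 2.0)
    assert P[0] == pytest.approx(0.73576, abs=1e-5)


def test_polymer_high_q_asymptotic_slope():
    p = sf.PolymerEVParams(rg=3.4, porod_exponent=3.0)
    rg_A = 34.0
    q = np.geomspace(5 / rg_A, 15 / rg_A, 60)
    P = _polymer_ev_form_factor(q, rg_A, 3.0)
    slope = np.polyfit(np.log(q), np.log(P), 1)[0]
    assert slope == pytest.approx(-3.0, abs=0.1)


def test_polymer_parameter_validation():
    with pytest.raises(sf.ParameterError):
        sf.PolymerEVParams(rg=3.0, porod_exponent=1.0)
    with pytest.raises(sf.ParameterError):
        sf.PolymerEVParams(rg=-1.0, porod_exponent=3.0)


# --------------------------------------------------------------------------
# parameter containers


def test_dumbbell_params_validation_and_flags():
    with pytest.raises(sf.ParameterError):
        sf.DumbbellParams(50, -1, 40, 10)
    with pytest.raises(sf.ParameterError):
        sf.DumbbellParams(50, 30, 40, 45)      # hole wider than equator
    p = sf.ANKAIC_DUMBBELL
    assert p.overlapping                        # 2a = 70.8 > d = 53
    assert p.axial_length == pytest.approx(123.8)
    assert not sf.DumbbellParams(80, 30, 40, 0).overlapping


def test_volume_closed_form_sphere_and_ellipsoid():
    R = 10.0
    assert sf.DumbbellParams(0, R, R, 0).volume() == pytest.approx(
        4 / 3 * np.pi * R ** 3, rel=1e-12)
    assert sf.DumbbellParams(0, 20, 35, 0).volume() == pytest.approx(
        4 / 3 * np.pi * 20 * 35 ** 2, rel=1e-12)
    # non-overlapping pair without hole: exactly two ellipsoids
    assert sf.DumbbellParams(100, 20, 35, 0).volume() == pytest.approx(
        2 * 4 / 3 * np.pi * 20 * 35 ** 2, rel=1e-12)


# --------------------------------------------------------------------------
# Guinier / Porod


def test_guinier_sphere_closed_form():
    R = 30.0
    q = sf.make_q_grid(0.005, 0.2, 200)
    I = sf.sphere_amplitude(q * R) ** 2
    res = sf.guinier_fit(sf.ScatteringCurve(q, I, 0.01 * I))
    assert res.rg == pytest.approx(R * np.sqrt(3 / 5), rel=0.02)


def test_guinier_dumbbell_matches_monte_carlo_rg():
    p = sf.ANKAIC_DUMBBELL
    q = sf.make_q_grid(0.005, 0.3, 150)
    c = sf.dumbbell_intensity(q, sf.DumbbellParams(
        p.center_distance, p.polar_semiaxis, p.equatorial_semiaxis,
        p.hole_radius))
    res = sf.guinier_fit(sf.ScatteringCurve(q, c.I, 0.01 * c.I))
    rg_mc, se = sf.mc_rg(p, n=400_000, seed=11)
    assert abs(res.rg - rg_mc) / rg_mc < 0.03


def test_guinier_error_when_window_unpopulated():
    # all points beyond Q Rg = 1.3 for this large body
    q = sf.make_q_grid(0.05, 0.5, 60)
    R = 120.0
    I = np.exp(-q ** 2 * R ** 2 / 3) + 1e-12
    with pytest.raises(RuntimeError):
        sf.guinier_fit(sf.ScatteringCurve(q, I, 0.01 * I))


@pytest.mark.parametrize("exponent", [4.0, 0.0])
def test_porod_exponent_pure_power_law(exponent):
    q = sf.make_q_grid(0.01, 0.5, 80)
    I = q ** -exponent if exponent else np.ones_like(q)
    got = sf.porod_exponent(sf.ScatteringCurve(q, I, 0.01 * I), (0.02, 0.4))
    assert got == pytest.approx(exponent, abs=1e-10)


def test_porod_exponent_rejects_nonpositive():
    q = sf.make_q_grid(0.01, 0.5, 50)
    I = q ** -4.0 - 20.0   # negative at high q
    with pytest.raises(ValueError):
        sf.porod_exponent(sf.ScatteringCurve(q, I, np.zeros_like(q)),
                          (0.02, 0.5))


def test_polymer_curve_porod_window_recovers_m():
    rg_A = 34.0
    q = sf.make_q_grid(0.005, 15.5 / rg_A, 200)
    P = _polymer_ev_form_factor(q, rg_A, 3.0)
    got = sf.porod_exponent(sf.ScatteringCurve(q, P, np.zeros_like(q)),
                            (5 / rg_A, 15 / rg_A))
    assert got == pytest.approx(3.0, abs=0.1)


# --------------------------------------------------------------------------
# shape comparison


def test_compare_shapes_identical_is_zero():
    cmp = sf.compare_shapes(sf.KAIC_DUMBBELL, sf.KAIC_DUMBBELL,
                            n_mc=50_000, seed=0)
    assert cmp.axial_length_pct == 0.0
    assert cmp.equatorial_pct == 0.0
    assert cmp.volume_pct == 0.0
    assert abs(cmp.rg_pct) < 3 * 100 * cmp.rg_se / cmp.rg_ref


def test_compare_shapes_reference_geometries():
    cmp = sf.compare_shapes(sf.KAIC_DUMBBELL, sf.ANKAIC_DUMBBELL,
                            n_mc=200_000, seed=1)
    # axial lengths 123.8 vs 114.8 A
    assert cmp.axial_length_pct == pytest.approx(7.8, abs=0.1)
    assert cmp.rg_pct > 0        # ancestral geometry is larger by Rg too
    assert cmp.volume_pct > 0


# --------------------------------------------------------------------------
# property tests


@settings(derandomize=True, max_examples=30)
@given(u=st.floats(0.0, 60.0))
def test_sphere_amplitude_bounded(u):
    amp = float(sf.sphere_amplitude(u))
    assert -0.1 <= amp <= 1.0


@settings(derandomize=True, max_examples=20, deadline=None)
@given(d=st.floats(0.0, 90.0), a=st.floats(15.0, 45.0),
       req=st.floats(25.0, 60.0))
def test_numeric_forward_amplitude_equals_volume(d, a, req):
    rh = 0.3 * req
    p = sf.DumbbellParams(d, a, req, rh)
    f0 = float(sf.dumbbell_amplitude_numeric(np.array([0.0]), 0.2, p)[0])
    assert f0 == pytest.approx(p.volume(), rel=1e-9)
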
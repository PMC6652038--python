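"""Characteristic equation, crossings, delay ladders and transversality."""

import cmath
import dataclasses
import math

import numpy as np
import pytest

import virhopf as vh
from virhopf.errors import ConsistencyError
from virhopf.stability import CharCoefficients, FCoefficients, _f_derivative, f_value

from conftest import numeric_jacobian_tau0


# ---------------------------------------------------------------------------
# infection-free equilibrium


def test_e0_stable_when_r0_below_one(scenarios):
    weak = dataclasses.replace(
        scenarios["case1a"].params,
        f1=vh.IncidenceSpec.bilinear(1e-8),
        f2=vh.IncidenceSpec.bilinear(1e-8),
    )
    res = vh.e0_eigen_analysis(weak)
    assert res.verdict == "stable"
    assert max(r.real for r in res.roots) < 0


def test_e0_unstable_when_r0_above_one(case2a):
    res = vh.e0_eigen_analysis(case2a)
    assert res.verdict == "unstable"
    assert max(r.real for r in res.roots) > 0


def test_e0_marginal_at_threshold(scenarios):
    base = scenarios["case1a"].params
    beta2 = base.d2 * base.d1 / base.s
    marginal = dataclasses.replace(
        base, f1=vh.IncidenceSpec.bilinear(0.0), f2=vh.IncidenceSpec.bilinear(beta2)
    )
    res = vh.e0_eigen_analysis(marginal)
    assert res.verdict == "marginal"
    assert min(abs(r) for r in res.roots) < 1e-12  # one zero root


def test_e0_roots_match_jacobian(scenarios):
    """The quartic's roots at tau=0 equal the eigenvalues of the Jacobian at E0."""
    weak = dataclasses.replace(
        scenarios["case1a"].params,
        f1=vh.IncidenceSpec.bilinear(1e-8),
        f2=vh.IncidenceSpec.bilinear(1e-8),
    )
    jac = numeric_jacobian_tau0(weak, (weak.u0, 0.0, 0.0, 0.0))
    expected = np.sort_complex(np.linalg.eigvals(jac))
    got = np.sort_complex(np.array(vh.e0_eigen_analysis(weak).roots))
    np.testing.assert_allclose(got, expected, rtol=1e-5, atol=1e-8)


# ---------------------------------------------------------------------------
# coefficients at E*


def test_q_terms_bilinear_closed_form(case1b):
    eq = vh.find_positive_equilibrium(case1b)
    q0, q1, q2 = vh.q_terms(eq, case1b)
    b1, b2 = case1b.f1.beta, case1b.f2.beta
    assert q0 == pytest.approx(b1 * eq.v + b2 * eq.w, rel=1e-12)
    assert q1 == pytest.approx(b1 * eq.u, rel=1e-12)
    assert q2 == pytest.approx(b2 * eq.u, rel=1e-12)


def test_q_terms_nonnegative_all_fixtures(scenarios):
    for sc in scenarios.values():
        eq = vh.find_positive_equilibrium(sc.params)
        for q in vh.q_terms(eq, sc.params):
            assert q >= 0.0, sc.name


def test_q_terms_reject_infection_free(case2a):
    with pytest.raises(ValueError):
        vh.q_terms(vh.infection_free_equilibrium(case2a), case2a)


def test_char_coefficients_positive_and_b_structure(scenarios):
    for sc in scenarios.values():
        p = sc.params
        eq = vh.find_positive_equilibrium(p)
        coef = vh.char_coefficients(eq, p)
        for name in ("A3", "A2", "A1", "A0", "B2", "B1", "B0"):
            assert getattr(coef, name) > 0, (sc.name, name)
        # the delay part carries the factor p*w*c and the two fixed ratios
        assert coef.B2 == pytest.approx(p.p * eq.w * p.c, rel=1e-12)
        assert coef.B1 / coef.B2 == pytest.approx(p.d1 + p.d3 + coef.Q0, rel=1e-12)
        assert coef.B0 / coef.B2 == pytest.approx(p.d3 * (p.d1 + coef.Q0), rel=1e-12)


def test_tau0_quartic_matches_numeric_jacobian(scenarios):
    """Oracle: the tau=0 characteristic quartic has exactly the eigenvalues of
    the finite-difference Jacobian (delay column folded in) at E*."""
    for sc in scenarios.values():
        p = sc.params
        eq = vh.find_positive_equilibrium(p)
        coef = vh.char_coefficients(eq, p)
        jac = numeric_jacobian_tau0(p, eq.state)
        expected = np.sort_complex(np.linalg.eigvals(jac))
        got = np.sort_complex(np.roots(coef.delay_free_quartic()))
        np.testing.assert_allclose(got, expected, rtol=1e-5, atol=1e-7, err_msg=sc.name)


def test_effective_decay_identity(scenarios):
    """d2 + p z* - Q2 = f1* k/d3 - (df2/dw) w* > 0 at every E*."""
    for sc in scenarios.values():
        p = sc.params
        eq = vh.find_positive_equilibrium(p)
        _, _, q2 = vh.q_terms(eq, p)
        f1s = vh.incidence_value(p.f1, eq.u, eq.v)
        _, f2w = vh.incidence_partials(p.f2, eq.u, eq.w)
        lhs = p.d2 + p.p * eq.z - q2
        rhs = f1s * p.k / p.d3 - f2w * eq.w
        assert lhs == pytest.approx(rhs, rel=1e-9)
        assert lhs > 0


# ---------------------------------------------------------------------------
# Routh-Hurwitz


def _quartic_coef(a3, a2, a1, a0):
    """CharCoefficients with the given tau=0 sums (B split off arbitrarily)."""
    return CharCoefficients(
        A3=a3, A2=a2 / 2, A1=a1 / 2, A0=a0 / 2, B2=a2 / 2, B1=a1 / 2, B0=a0 / 2,
        Q0=0.0, Q1=0.0, Q2=0.0,
    )


def test_routh_hurwitz_known_stable_quartic():
    # (x+1)(x+2)(x+3)(x+4): roots all in the left half plane
    rh = vh.routh_hurwitz_tau0(_quartic_coef(10.0, 35.0, 50.0, 24.0))
    assert rh.H1 > 0 and rh.H2 > 0 and rh.stable


def test_routh_hurwitz_agrees_with_root_oracle(rng):
    """Verdict equals direct root-sign computation on random positive quartics."""
    checked = stable_seen = 0
    while checked < 300:
        a3, a2, a1, a0 = 10 ** rng.uniform(-1.5, 1.5, size=4)
        rh = vh.routh_hurwitz_tau0(_quartic_coef(a3, a2, a1, a0))
        roots = np.roots([1.0, a3, a2, a1, a0])
        margin = max(r.real for r in roots)
        if abs(margin) < 1e-9:  # undecidable at float precision
            continue
        assert rh.stable == (margin < 0), (a3, a2, a1, a0)
        checked += 1
        stable_seen += rh.stable
    assert 0 < stable_seen < checked  # both outcomes exercised


def test_case2a_stable_at_zero_delay(case2a):
    eq = vh.find_positive_equilibrium(case2a)
    rh = vh.routh_hurwitz_tau0(vh.char_coefficients(eq, case2a))
    assert rh.stable


# ---------------------------------------------------------------------------
# F polynomial and crossings


def test_f_poly_is_squared_modulus_difference(scenarios):
    """F(omega^2) = |P(i omega)|^2 - |Q(i omega)|^2 as an identity in omega."""
    for name in ("case1b", "case2a", "case4b"):
        p = scenarios[name].params
        eq = vh.find_positive_equilibrium(p)
        coef = vh.char_coefficients(eq, p)
        m = vh.f_poly(coef)
        for omega in (0.1, 0.5, 1.0, 2.7):
            lam = 1j * omega
            p_mod = abs(lam**4 + coef.A3 * lam**3 + coef.A2 * lam**2 + coef.A1 * lam + coef.A0) ** 2
            q_mod = abs(coef.B2 * lam**2 + coef.B1 * lam + coef.B0) ** 2
            assert f_value(m, omega**2) == pytest.approx(p_mod - q_mod, rel=1e-10)


def test_positive_crossings_constructed_factorization():
    # F(z) = (z-1)(z-4)(z+2)(z+3) = z^4 - 15 z^2 - 10 z + 24
    m = FCoefficients(M3=0.0, M2=-15.0, M1=-10.0, M0=24.0)
    crossings = vh.positive_crossings(m)
    assert [c.omega for c in crossings] == pytest.approx([2.0, 1.0], rel=1e-12)
    # beyond the largest root F increases: the largest crossing is destabilizing
    assert crossings[0].delta == 1


def test_positive_crossings_match_grid_scan(scenarios):
    """Grid-scan + bisection oracle for the positive roots of F."""
    for sc in scenarios.values():
        p = sc.params
        eq = vh.find_positive_equilibrium(p)
        m = vh.f_poly(vh.char_coefficients(eq, p))
        crossings = vh.positive_crossings(m)
        z_max = 2.0 * max([1.0] + [c.z for c in crossings])
        grid = np.linspace(0.0, z_max, 40_001)[1:]
        vals = np.array([f_value(m, z) for z in grid])
        signs = np.sign(vals)
        idx = np.where(np.diff(signs) != 0)[0]
        scan_roots = []
        for i in idx:
            lo, hi = grid[i], grid[i + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if np.sign(f_value(m, mid)) == np.sign(f_value(m, lo)):
                    lo = mid
                else:
                    hi = mid
            scan_roots.append(0.5 * (lo + hi))
        assert sorted(c.z for c in crossings) == pytest.approx(scan_roots, rel=1e-8), sc.name


def test_no_crossings_without_delay_feedback(case2a):
    """Weak CTL production removes the imaginary-axis crossing entirely."""
    p = dataclasses.replace(case2a, c=0.1)
    summary = vh.hopf_summary(p)
    assert summary.regime == "stable_for_all_tau"
    assert summary.crossings == ()
    assert summary.tau_star is None


# ---------------------------------------------------------------------------
# delay ladders


def test_ladder_spacing_and_residuals(case2a):
    summary = vh.hopf_summary(case2a)
    coef = summary.coefficients
    for crossing in summary.crossings:
        delays = crossing.delays
        assert np.all(np.diff(delays) > 0)
        np.testing.assert_allclose(
            np.diff(delays), 2.0 * math.pi / crossing.omega, rtol=1e-12
        )
        for tau in delays:
            assert vh.char_residual(crossing.omega, tau, coef) < 1e-8


def test_non_crossing_frequency_rejected(case2a):
    eq = vh.find_positive_equilibrium(case2a)
    coef = vh.char_coefficients(eq, case2a)
    with pytest.raises(ConsistencyError):
        vh.critical_delays(17.3, coef, j_max=2)


def test_smallest_critical_delay_saturation_fixture(case2a):
    """Frozen Hopf point of the saturation fixture (cross-checked in scratch
    work by direct DDE simulation: perturbations decay at tau=4.85 and grow
    at tau=4.95)."""
    summary = vh.hopf_summary(case2a)
    assert summary.tau_star == pytest.approx(4.94566487994553, rel=1e-9)
    assert summary.omega_star == pytest.approx(0.48721043105560774, rel=1e-9)
    assert summary.delta == 1
    assert summary.regime == "stable_below_tau_star"


def test_stability_windows_bilinear_fixture(case1b):
    """The bilinear fixture has interleaved destabilizing/stabilizing rungs:
    stable on [0, 3.723), oscillatory, restabilized on (10.524, 16.808)."""
    summary = vh.hopf_summary(case1b)
    assert summary.tau_star == pytest.approx(3.723074970810989, rel=1e-8)
    rungs = sorted(
        (float(tau), c.delta) for c in summary.crossings for tau in c.delays if tau <= 20.0
    )
    assert [d for _, d in rungs] == [1, -1, 1]
    assert rungs[1][0] == pytest.approx(10.5237, abs=2e-4)
    assert rungs[2][0] == pytest.approx(16.8082, abs=2e-4)


# ---------------------------------------------------------------------------
# transversality


def _track_root_real_part(coef: CharCoefficients, omega: float, tau: float) -> float:
    """Newton-track the characteristic root near i*omega at the given tau."""
    lam = 1j * omega

    def char(l):
        return (
            l**4 + coef.A3 * l**3 + coef.A2 * l**2 + coef.A1 * l + coef.A0
            + (coef.B2 * l**2 + coef.B1 * l + coef.B0) * cmath.exp(-l * tau)
        )

    def dchar(l):
        e = cmath.exp(-l * tau)
        return (
            4 * l**3 + 3 * coef.A3 * l**2 + 2 * coef.A2 * l + coef.A1
            + (2 * coef.B2 * l + coef.B1) * e
            - tau * (coef.B2 * l**2 + coef.B1 * l + coef.B0) * e
        )

    for _ in range(60):
        step = char(lam) / dchar(lam)
        lam -= step
        if abs(step) < 1e-14 * (1.0 + abs(lam)):
            break
    return lam.real


def test_transversality_matches_root_tracking(scenarios):
    """The sign of F'(omega*^2) equals the tracked crossing direction of the
    characteristic root across each rung."""
    for name in ("case1b", "case2a"):
        summary = vh.hopf_summary(scenarios[name].params)
        coef = summary.coefficients
        for crossing in summary.crossings:
            tau0 = float(crossing.delays[0])
            dtau = 1e-3 * max(1.0, tau0)
            before = _track_root_real_part(coef, crossing.omega, tau0 - dtau)
            after = _track_root_real_part(coef, crossing.omega, tau0 + dtau)
            slope_sign = 1 if after > before else -1
            assert slope_sign == crossing.delta, (name, tau0)


def test_degenerate_double_root_flagged():
    # F(z) = (z-1)^2 (z+2)(z+3) has a repeated positive root at z=1
    poly = np.polynomial.polynomial.polyfromroots([1.0, 1.0, -2.0, -3.0])[::-1]
    m = FCoefficients(M3=poly[1], M2=poly[2], M1=poly[3], M0=poly[4])
    assert vh.transversality(1.0, m) == 0
    assert abs(_f_derivative(m, 1.0)) < 1e-9


def test_hopf_summary_requires_positive_equilibrium(scenarios):
    weak = dataclasses.replace(
        scenarios["case1a"].params,
        f1=vh.IncidenceSpec.bilinear(1e-8),
        f2=vh.IncidenceSpec.bilinear(1e-8),
    )
    with pytest.raises(ValueError):
        vh.hopf_summary(weak)
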
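"""Reduced-model dynamics: flow identities, fixed points with an independent
linearization oracle, closed forms vs. integration, symmetries."""

import numpy as np
import pytest

from relapath import reduced as rm


R = np.sqrt(0.1)
FP = R / np.sqrt(2.0)


def numeric_jacobian(state, params, eps=1e-7):
    """Finite-difference linearization — independent stability oracle."""
    state = np.asarray(state, float)
    J = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = eps
        J[:, j] = (rm.flow(state + e, params) - rm.flow(state - e, params)) \
            / (2 * eps)
    return J


def test_flow_identities():
    p = rm.ReducedParams(alpha=0.5)
    np.testing.assert_allclose(rm.flow((FP, FP), p), 0.0, atol=1e-15)
    np.testing.assert_allclose(rm.flow((0.0, 0.0), p), 0.0, atol=1e-15)
    # lam = 0, alpha = 1, state (-a, a): dDZ/dt = 2a, dtheta/dt = -2a
    p0 = rm.ReducedParams(alpha=1.0, lambda_reg=0.0)
    a = 0.3
    np.testing.assert_allclose(rm.flow((-a, a), p0), [2 * a, -2 * a])


@pytest.mark.parametrize("lam,n_expected", [(0.1, 3), (5.0, 3), (20.0, 5)])
def test_fixed_point_census_and_stability(lam, n_expected):
    p = rm.ReducedParams(alpha=0.7, lambda_reg=lam)
    fps = rm.find_fixed_points(p)
    assert len(fps) == n_expected
    stable = [f for f in fps if f.stability == "stable"]
    assert len(stable) == 2
    for f in stable:
        assert f.delta_z == pytest.approx(f.theta)
        assert abs(f.delta_z) == pytest.approx(FP, abs=1e-12)
    for f in fps:
        assert np.linalg.norm(rm.flow((f.delta_z, f.theta), p)) < 1e-10
        eig = np.linalg.eigvals(numeric_jacobian((f.delta_z, f.theta), p))
        oracle = "stable" if np.all(eig.real < 0) else "unstable"
        assert f.stability == oracle
    if lam > 10.0:  # lam > 1/r^2: anti-diagonal unstable pair appears
        anti = sorted(f.delta_z for f in fps if f.theta == -f.delta_z
                      and f.delta_z != 0.0)
        q = np.sqrt((0.1 - 1.0 / lam) / 2.0)
        np.testing.assert_allclose(anti, [-q, q])
        assert all(f.stability == "unstable" for f in fps
                   if f.theta == -f.delta_z and f.delta_z != 0.0)


def test_line_attractor_closed_form():
    assert rm.line_attractor_point(0.4, 0.4, 2.7) == pytest.approx(0.4)
    assert rm.line_attractor_point(-0.2, 0.2, 1.0) == pytest.approx(0.0)
    # symmetric reversal start: (r/sqrt2)(a^2-1)/(a^2+1), zero at alpha=1
    for a in (0.3, 1.0, 2.5):
        got = rm.line_attractor_point(-FP, FP, a)
        assert got == pytest.approx(FP * (a ** 2 - 1) / (a ** 2 + 1))
    assert rm.line_attractor_point(-FP, FP, 1.0) == 0.0


def test_unregularized_integration_matches_closed_form(rng):
    """lam = 0 integration lands on the line-attractor point (<= 1e-6)."""
    for _ in range(8):
        dz0, th0 = rng.uniform(-0.5, 0.5, size=2)
        alpha = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
        p = rm.ReducedParams(alpha=alpha, lambda_reg=0.0)
        res = rm.integrate((dz0, th0), p)
        expect = rm.line_attractor_point(dz0, th0, alpha)
        assert res.converged
        assert res.terminal[0] == pytest.approx(expect, abs=1e-6)
        assert res.terminal[1] == pytest.approx(expect, abs=1e-6)


def test_conservation_under_lam_zero(rng):
    alpha = 1.8
    p = rm.ReducedParams(alpha=alpha, lambda_reg=0.0)
    res = rm.integrate((0.35, -0.1), p)
    inv = res.states[0] + alpha ** 2 * res.states[1]
    np.testing.assert_allclose(inv, inv[0], atol=1e-6)


def test_loss_nonincreasing_along_trajectories():
    for alpha in (0.4, 2.2):
        p = rm.ReducedParams(alpha=alpha)
        res = rm.integrate(rm.reversal_start(p.r), p)
        losses = rm.reduced_loss(res.states, p)
        assert np.all(np.diff(losses) <= 1e-10)


def test_general_endpoint():
    assert rm.general_endpoint(1.0, 1.0, R) == 0.0
    assert rm.general_endpoint(2.0, 0.5, R) == 0.0  # product exactly 1
    got = rm.general_endpoint(2.0, 1.0, R)
    assert got == pytest.approx(np.sqrt(0.05) * 0.5 / 2.0)
    assert got > 0  # representational side
    # reduces to the symmetric closed form
    for a in (0.5, 1.7):
        assert rm.general_endpoint(a, a, R) == \
            pytest.approx(rm.line_attractor_point(-FP, FP, a))
    with pytest.raises(ValueError):
        rm.general_endpoint(-1.0, 1.0, R)


def test_integration_stays_at_fixed_points_and_selects_basins():
    p = rm.ReducedParams(alpha=0.9)
    res = rm.integrate((FP, FP), p)
    assert res.terminal == pytest.approx((FP, FP), abs=1e-9)
    # strong violation from the post-reversal state -> representational
    res2 = rm.integrate(rm.reversal_start(R), rm.ReducedParams(alpha=2.0))
    assert res2.fixed_point is not None
    assert res2.fixed_point.theta == pytest.approx(FP)
    # weak violation -> relational (theta flips)
    res3 = rm.integrate(rm.reversal_start(R), rm.ReducedParams(alpha=0.5))
    assert res3.fixed_point.theta == pytest.approx(-FP)


def test_alpha_inverse_swap_symmetry(rng):
    """If (ΔZ(t), θ(t)) solves the flow at α, then the coordinate-swapped
    path solves it at 1/α (up to a time rescaling): terminal states swap."""
    for _ in range(5):
        a, b = rng.uniform(0.05, 0.45, size=2)
        alpha = float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))
        t1 = rm.integrate((-a, b), rm.ReducedParams(alpha=alpha)).terminal
        t2 = rm.integrate((b, -a),
                          rm.ReducedParams(alpha=1.0 / alpha)).terminal
        assert t2[0] == pytest.approx(t1[1], abs=1e-6)
        assert t2[1] == pytest.approx(t1[0], abs=1e-6)


def test_predict_pathway_rule():
    assert rm.predict_pathway(2.0, 2.0) == "representational"
    assert rm.predict_pathway(0.5, 0.5) == "relational"
    assert rm.predict_pathway(1.0, 1.0) == "boundary"
    assert rm.predict_pathway(4.0, 0.3) == "representational"


def test_pathway_map_agrees_with_product_rule_off_boundary():
    grid = [0.3, 0.7, 1.5, 3.0]
    labels = rm.pathway_map(grid, grid, lambda_reg=0.01)
    for i, a2 in enumerate(grid):
        for j, a1 in enumerate(grid):
            want = rm.predict_pathway(a1, a2)
            if want != "boundary":
                assert labels[i, j] == want, (a1, a2)


def test_nonfinite_start_rejected():
    with pytest.raises(ValueError):
        rm.integrate((np.nan, 0.0), rm.ReducedParams(alpha=1.0))
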
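"""Restricted pure-deviation payoffs, the logit fixed-point residual, and
the QRE solvers."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qrepd import (
    PayoffMatrix,
    RestrictedPayoffs,
    SolverConfig,
    count_local_minima,
    expected_payoff,
    logit_response,
    qre_residual,
    restricted_payoffs,
    restricted_stationary,
    solve_qre,
    trace_qre,
)
from qrepd.qre import _residual_grid

INTERIOR = st.floats(0.01, 0.99, allow_nan=False)


# ---------------------------------------------------------------------------
# closed forms of the four pure-deviation payoffs, written out term by term
# as an independent transcription oracle against the composed computation.
# The gamma-deviation expressions circulate in print with leading (-p1)
# terms that contradict the very probability formulas they substitute; the
# forms below carry the leading terms implied by those probabilities, and
# the verbatim variants are kept for the documented-inconsistency check.
# ---------------------------------------------------------------------------

def _printed_u_alpha0(a, g):
    den = g * (a - g) + 1
    return -4 * a**2 * g / den**2 - a * g / den + 9 * a / den + 1


def _printed_u_alpha1(a, g):
    den = -(a - g) * (1 - g) + 1
    return (
        -4 * g * (-a * (1 - g) + 1) / den**2
        + 9 * g / den
        - (-a * (1 - g) + 1) / den
        + 1
    )


def _printed_u_gamma0(a, g, leading="corrected"):
    den = -a * (a - g) + 1
    lead = -(a - a**2) if leading == "corrected" else -(a**2 + a)
    return (
        lead / den
        - 4 * (-(a**2) + a) * (-a * (a - g) + a) / den**2
        + 9 * (-a * (a - g) + a) / den
        + 1
    )


def _printed_u_gamma1(a, g, leading="corrected"):
    den = -(a - 1) * (a - g) + 1
    lead = -(2 * a - a**2) if leading == "corrected" else -(a * (a - 1) + a)
    return (
        lead / den
        - 4 * (-a * (a - 1) + a) * (-a * (a - g) + a) / den**2
        + 9 * (-a * (a - g) + a) / den
        + 1
    )


@pytest.mark.parametrize(
    "which,expected",
    [
        ("alpha=0", (0.25, 0.5)),
        ("alpha=1", (0.75, 0.5)),
        ("gamma=0", (0.25, 0.5)),
        ("gamma=1", (0.75, 0.5)),
    ],
)
def test_restricted_stationary_at_center(which, expected):
    assert restricted_stationary(0.5, 0.5, which) == pytest.approx(expected)


def test_restricted_stationary_alpha0_vanishes_with_alpha():
    for g in (0.1, 0.5, 0.9):
        assert restricted_stationary(0.0, g, "alpha=0") == (0.0, 0.0)


def test_restricted_stationary_rejects_unknown_case():
    with pytest.raises(ValueError):
        restricted_stationary(0.5, 0.5, "alpha=2")


def test_restricted_payoffs_center_values():
    rp = restricted_payoffs(0.5, 0.5)
    assert rp.u_alpha0 == pytest.approx(4.75)
    assert rp.u_gamma0 == pytest.approx(4.75)
    assert rp.u_alpha1 == pytest.approx(3.25)
    assert rp.u_gamma1 == pytest.approx(3.25)


def test_restricted_payoffs_match_printed_closed_forms(rng):
    """The composed pipeline (pure-deviation stationary pairs into the
    bilinear payoff) agrees with the independent closed-form transcriptions
    on 500 random interior points."""
    oracles = (
        _printed_u_alpha0,
        _printed_u_alpha1,
        _printed_u_gamma0,
        _printed_u_gamma1,
    )
    for _ in range(500):
        a, g = rng.uniform(0.01, 0.99, size=2)
        rp = restricted_payoffs(a, g)
        got = (rp.u_alpha0, rp.u_alpha1, rp.u_gamma0, rp.u_gamma1)
        for val, oracle in zip(got, oracles):
            assert val == pytest.approx(oracle(a, g), abs=1e-10)


def test_verbatim_gamma_deviation_forms_are_inconsistent():
    """The verbatim leading terms of the two gamma-deviation payoff
    expressions contradict the probability formulas they substitute: at the
    central point they shift the payoffs by exactly -0.5 and +0.5."""
    rp = restricted_payoffs(0.5, 0.5)
    assert _printed_u_gamma0(0.5, 0.5, leading="verbatim") == pytest.approx(
        rp.u_gamma0 - 0.5
    )
    assert _printed_u_gamma1(0.5, 0.5, leading="verbatim") == pytest.approx(
        rp.u_gamma1 + 0.5
    )


def test_restricted_payoffs_compose_stationary_into_payoff(rng):
    a, g = 0.37, 0.81
    rp = restricted_payoffs(a, g)
    for which, val in zip(
        ("alpha=0", "alpha=1", "gamma=0", "gamma=1"),
        (rp.u_alpha0, rp.u_alpha1, rp.u_gamma0, rp.u_gamma1),
    ):
        p1, p2 = restricted_stationary(a, g, which)
        assert val == pytest.approx(expected_payoff(p1, p2), abs=1e-12)


def test_logit_response_uniform_at_zero_rationality():
    rp = RestrictedPayoffs(2.0, -3.0, 100.0, 7.5)
    assert logit_response(rp, 0.0) == (0.5, 0.5)


def test_logit_response_direct_evaluation():
    rp = RestrictedPayoffs(4.75, 3.25, 4.75, 3.25)
    ar, gr = logit_response(rp, 1.0)
    assert ar == pytest.approx(1.0 / (1.0 + math.exp(1.5)))
    assert gr == pytest.approx(1.0 / (1.0 + math.exp(1.5)))


def test_logit_response_saturates():
    rp = RestrictedPayoffs(u_alpha0=0.0, u_alpha1=1e9, u_gamma0=0.0, u_gamma1=-1e9)
    ar, gr = logit_response(rp, 1.0)
    assert ar == pytest.approx(1.0)
    assert gr == pytest.approx(0.0)


def test_residual_zero_at_uniform_point_for_zero_rationality():
    assert qre_residual(0.5, 0.5, 0.0) == 0.0


@given(alpha=INTERIOR, gamma=INTERIOR, lam=st.floats(0.0, 50.0))
def test_residual_nonnegative(alpha, gamma, lam):
    assert qre_residual(alpha, gamma, lam) >= 0.0


def test_residual_finite_at_extreme_rationality():
    """Exponent clamping keeps the objective finite at lambda = 1e6 on the
    restart lattice (away from the two degenerate corners)."""
    axis = np.linspace(0.0, 1.0, 21)
    R = _residual_grid(1e6, axis, PayoffMatrix())
    assert np.isinf(R).sum() <= 2  # only the (0,1)/(1,0) degeneracies
    assert np.isfinite(R[R != np.inf]).all()


def test_solve_at_zero_rationality_returns_uniform_point():
    sol = solve_qre(0.0)
    assert (sol.alpha, sol.gamma) == pytest.approx((0.5, 0.5), abs=1e-9)
    assert sol.residual < 1e-12
    assert sol.converged


@pytest.mark.parametrize("lam", [0.5, 1.0, 2.0, 3.0])
def test_solver_matches_dense_grid_argmin(lam):
    """Multistart minimum agrees with a 401x401 brute-force grid argmin."""
    axis = np.linspace(0.0, 1.0, 401)
    R = _residual_grid(lam, axis, PayoffMatrix())
    i, j = np.unravel_index(np.argmin(R), R.shape)
    sol = solve_qre(lam)
    assert abs(sol.alpha - axis[i]) < 1e-3 + (axis[1] - axis[0])
    assert abs(sol.gamma - axis[j]) < 1e-3 + (axis[1] - axis[0])


def test_converged_solutions_are_fixed_points():
    for lam in (0.25, 1.5, 3.5):
        sol = solve_qre(lam)
        assert sol.converged
        rp = restricted_payoffs(sol.alpha, sol.gamma)
        ar, gr = logit_response(rp, lam)
        assert abs(ar - sol.alpha) < 1e-5
        assert abs(gr - sol.gamma) < 1e-5


def test_trace_is_connected_at_small_rationality():
    cfg = SolverConfig(lambda_grid=np.round(np.arange(0.0, 4.0, 0.01), 6))
    tr = trace_qre(cfg)
    first = tr.solutions[0]
    assert (first.lam, first.alpha, first.gamma) == pytest.approx((0.0, 0.5, 0.5))
    for a, b in zip(tr.solutions, tr.solutions[1:]):
        assert math.hypot(a.alpha - b.alpha, a.gamma - b.gamma) < 0.05
        assert b.converged


@pytest.mark.parametrize("lam", [0.0, 0.5])
def test_unique_local_minimum_at_very_small_rationality(lam):
    assert count_local_minima(lam, 201) == 1


def test_shallow_secondary_minimum_appears_by_lambda_two():
    """From rationality near 1 the residual develops a shallow strict local
    minimum near (0.27, 0.95) (depth ~0.04, a precursor of the
    high-cooperation fixed-point branch), so the census counts two well
    before the multi-equilibrium regime."""
    assert count_local_minima(2.0, 201) == 2


def test_multiple_local_minima_at_moderate_rationality():
    assert count_local_minima(6.0, 201) >= 2


def test_count_local_minima_rejects_coarse_grids():
    with pytest.raises(ValueError):
        count_local_minima(1.0, 51)
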
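"""Symmetric logit quantal response equilibrium (QRE) for the memory-one
Prisoner's Dilemma.

At a symmetric profile (alpha, gamma), each coordinate of the strategy is
treated as a binary choice whose two "pure" deviations (setting player 1's
own alpha, or gamma, to 0 or 1 while everything else stays symmetric) carry
stationary payoffs ``u_alpha0, u_alpha1, u_gamma0, u_gamma1``.  The logit
response with precision (rationality) ``lambda`` maps these payoffs back to
choice probabilities, and a QRE is a fixed point:

    alpha = exp(lam*u_alpha1) / (exp(lam*u_alpha0) + exp(lam*u_alpha1))
    gamma = exp(lam*u_gamma1) / (exp(lam*u_gamma0) + exp(lam*u_gamma1))

The pure-deviation payoffs use the *asymmetric-substitution* convention: the
pure value is substituted for player 1 in the asymmetric stationary formulas
first, and the remaining parameters are symmetrized afterwards.  The
expressions for the two players' cooperation probabilities therefore differ,
and the "alpha = 0" form still contains alpha; substituting symmetrically
first collapses the four cases to a much poorer family and is deliberately
not used here.

Fixed points are found by minimizing the squared fixed-point residual over
the unit square with a deterministic multistart, and the equilibrium curve
is traced by sweeping lambda with warm-start continuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter
from scipy.optimize import minimize

from .game import PayoffMatrix

__all__ = [
    "RestrictedPayoffs",
    "SolverConfig",
    "QRESolution",
    "QRETrace",
    "restricted_stationary",
    "restricted_payoffs",
    "logit_response",
    "qre_residual",
    "solve_qre",
    "trace_qre",
    "count_local_minima",
]

_EXP_CLAMP = 700.0
_TIE_TOL = 1e-8
_MERGE_RADIUS = 0.02


@dataclass(frozen=True)
class RestrictedPayoffs:
    """Stationary payoffs of player 1's four pure coordinate deviations."""

    u_alpha0: float
    u_alpha1: float
    u_gamma0: float
    u_gamma1: float


@dataclass
class SolverConfig:
    """Configuration of the QRE fixed-point solver and lambda sweep.

    ``lambda_grid`` defaults to 0..200 in steps of 0.01; tests and the
    landmark analysis use truncated grids.  The multistart restart lattice is
    ``restart_grid_size`` points per axis.  Restarts are deterministic, so
    ``seed`` is carried only for provenance.
    """

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 200.0 + 1e-9, 0.01), 6)
    )
    restart_grid_size: int = 21
    local_tol: float = 1e-12
    residual_tol: float = 1e-10
    continuation: bool = True
    seed: int = 0
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("lambda_grid must be a non-empty 1-D array")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("lambda_grid must be strictly ascending")
        if grid[0] < 0:
            raise ValueError("lambda values must be non-negative")
        self.lambda_grid = grid
        if self.restart_grid_size < 2:
            raise ValueError("restart_grid_size must be at least 2")


@dataclass(frozen=True)
class QRESolution:
    lam: float
    alpha: float
    gamma: float
    residual: float
    n_minima_found: int
    converged: bool


@dataclass(frozen=True)
class QRETrace:
    solutions: list[QRESolution]

    def __post_init__(self) -> None:
        lams = [s.lam for s in self.solutions]
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("trace lambda values must be strictly increasing")

    def __iter__(self):
        return iter(self.solutions)

    def __len__(self) -> int:
        return len(self.solutions)


# ---------------------------------------------------------------------------
# restricted stationary probabilities and payoffs
# ---------------------------------------------------------------------------

def _restricted_pairs(alpha, gamma):
    """The four (p1, p2) pure-deviation pairs, vectorized over numpy inputs.

    Order: alpha=0, alpha=1, gamma=0, gamma=1.
    """
    a, g = alpha, gamma
    d = a - g
    den_a0 = 1.0 + g * d
    den_a1 = 1.0 - (1.0 - g) * d
    den_g0 = 1.0 - a * d
    den_g1 = 1.0 - (a - 1.0) * d
    return (
        (a * g / den_a0, a / den_a0),
        ((1.0 - a + a * g) / den_a1, g / den_a1),
        ((a - a * a) / den_g0, (a - a * a + a * g) / den_g0),
        ((2.0 * a - a * a) / den_g1, (a - a * a + a * g) / den_g1),
    )


_WHICH = {"alpha=0": 0, "alpha=1": 1, "gamma=0": 2, "gamma=1": 3}


def restricted_stationary(alpha: float, gamma: float, which: str) -> tuple[float, float]:
    """Stationary cooperation pair (p1, p2) when player 1's alpha or gamma is
    pinned to a pure value (asymmetric-substitution convention).

    ``which`` is one of ``'alpha=0'``, ``'alpha=1'``, ``'gamma=0'``,
    ``'gamma=1'``.
    """
    if which not in _WHICH:
        raise ValueError(f"which must be one of {sorted(_WHICH)}, got {which!r}")
    if not (0.0 <= alpha <= 1.0) or not (0.0 <= gamma <= 1.0):
        raise ValueError(f"inputs must lie in [0, 1], got ({alpha}, {gamma})")
    d = alpha - gamma
    dens = (
        1.0 + gamma * d,
        1.0 - (1.0 - gamma) * d,
        1.0 - alpha * d,
        1.0 - (alpha - 1.0) * d,
    )
    idx = _WHICH[which]
    if abs(dens[idx]) < 1e-12:
        raise ZeroDivisionError(
            f"degenerate denominator for {which} at ({alpha}, {gamma})"
        )
    pair = _restricted_pairs(alpha, gamma)[idx]
    return (float(pair[0]), float(pair[1]))


def restricted_payoffs(
    alpha: float, gamma: float, payoffs: PayoffMatrix | None = None
) -> RestrictedPayoffs:
    """Player 1's stationary payoff for each of the four pure coordinate
    deviations at the symmetric point (alpha, gamma)."""
    if payoffs is None:
        payoffs = PayoffMatrix()
    a_, b_, c_, d_ = payoffs.bilinear
    vals = []
    for p1, p2 in _restricted_pairs(alpha, gamma):
        vals.append(a_ * p1 * p2 + b_ * p1 + c_ * p2 + d_)
    return RestrictedPayoffs(*map(float, vals))


def logit_response(restricted: RestrictedPayoffs, lam: float) -> tuple[float, float]:
    """Logit (softmax) choice probabilities for the two binary coordinates.

    Computed as ``1 / (1 + exp(lam * (u0 - u1)))`` with the exponent clamped
    to +-700, so the result is finite (and in (0, 1) up to floating point)
    for any finite payoffs and lambda.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    za = min(max(lam * (restricted.u_alpha0 - restricted.u_alpha1), -_EXP_CLAMP), _EXP_CLAMP)
    zg = min(max(lam * (restricted.u_gamma0 - restricted.u_gamma1), -_EXP_CLAMP), _EXP_CLAMP)
    return 1.0 / (1.0 + math.exp(za)), 1.0 / (1.0 + math.exp(zg))


def _check_denominators(alpha: float, gamma: float) -> None:
    d = alpha - gamma
    for name, den in (
        ("alpha=0", 1.0 + gamma * d),
        ("alpha=1", 1.0 - (1.0 - gamma) * d),
        ("gamma=0", 1.0 - alpha * d),
        ("gamma=1", 1.0 - (alpha - 1.0) * d),
    ):
        if abs(den) < 1e-12:
            raise ZeroDivisionError(
                f"degenerate denominator for {name} at ({alpha}, {gamma})"
            )


def qre_residual(
    alpha: float, gamma: float, lam: float, payoffs: PayoffMatrix | None = None
) -> float:
    """Squared fixed-point deviation
    ``(alpha_response - alpha)**2 + (gamma_response - gamma)**2``;
    zero exactly at a symmetric logit QRE."""
    _check_denominators(alpha, gamma)
    rp = restricted_payoffs(alpha, gamma, payoffs)
    ar, gr = logit_response(rp, lam)
    return (ar - alpha) ** 2 + (gr - gamma) ** 2


def _residual_or_inf(z, lam: float, payoffs: PayoffMatrix) -> float:
    """Solver objective: +inf instead of an exception at the two degenerate
    unit-square corners, so bounded line searches can step past them."""
    with np.errstate(all="ignore"):
        try:
            val = qre_residual(float(z[0]), float(z[1]), lam, payoffs)
        except ZeroDivisionError:
            return np.inf
    return val if np.isfinite(val) else np.inf


def _residual_grid(
    lam: float, axis: np.ndarray, payoffs: PayoffMatrix
) -> np.ndarray:
    """Vectorized residual on the lattice axis x axis (alpha-major).  Lattice
    points with a degenerate pure-deviation denominator come back as +inf."""
    a_, b_, c_, d_ = payoffs.bilinear
    A, G = np.meshgrid(axis, axis, indexing="ij")
    with np.errstate(divide="ignore", invalid="ignore"):
        pairs = _restricted_pairs(A, G)
        us = [a_ * p1 * p2 + b_ * p1 + c_ * p2 + d_ for p1, p2 in pairs]
        za = np.clip(lam * (us[0] - us[1]), -_EXP_CLAMP, _EXP_CLAMP)
        zg = np.clip(lam * (us[2] - us[3]), -_EXP_CLAMP, _EXP_CLAMP)
        ar = 1.0 / (1.0 + np.exp(za))
        gr = 1.0 / (1.0 + np.exp(zg))
        R = (ar - A) ** 2 + (gr - G) ** 2
    return np.where(np.isfinite(R), R, np.inf)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _refine(start, lam, payoffs, local_tol):
    res = minimize(
        lambda z: _residual_or_inf(z, lam, payoffs),
        np.asarray(start, dtype=float),
        method="L-BFGS-B",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        options={"ftol": local_tol * 1e-3, "gtol": 1e-12, "maxiter": 500},
    )
    return res.x, float(res.fun)


def _lattice_start_points(lam, config):
    axis = np.linspace(0.0, 1.0, config.restart_grid_size)
    R = _residual_grid(lam, axis, config.payoffs)
    is_min = (R == minimum_filter(R, size=3, mode="nearest")) & np.isfinite(R)
    starts = [(axis[i], axis[j]) for i, j in np.argwhere(is_min)]
    if not starts:  # pathological; fall back to the global lattice minimum
        i, j = np.unravel_index(np.argmin(R), R.shape)
        starts = [(axis[i], axis[j])]
    return starts


def solve_qre(
    lam: float,
    config: SolverConfig | None = None,
    warm_start: tuple[float, float] | None = None,
) -> QRESolution:
    """Best symmetric QRE candidate at one lambda by deterministic multistart.

    The fixed-point residual is screened on the restart lattice; bounded
    local minimization (L-BFGS-B) is run from every lattice local minimum
    plus the warm start, refined minima closer than 0.02 are merged, and the
    lowest-residual minimum is returned.  When several minima tie within
    1e-8 of the best residual and a warm start is given, the one closest to
    the warm start wins (branch continuity along a continuation sweep).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if config is None:
        config = SolverConfig()
    starts = _lattice_start_points(lam, config)
    if warm_start is not None:
        starts = [tuple(warm_start)] + starts

    minima: list[tuple[np.ndarray, float]] = []
    for s in starts:
        try:
            z, f = _refine(s, lam, config.payoffs, config.local_tol)
        except (ZeroDivisionError, FloatingPointError):
            continue
        if not np.isfinite(f):
            continue
        for k, (zm, fm) in enumerate(minima):
            if np.hypot(z[0] - zm[0], z[1] - zm[1]) < _MERGE_RADIUS:
                if f < fm:
                    minima[k] = (z, f)
                break
        else:
            minima.append((z, f))

    fbest = min(f for _, f in minima)
    tied = [(z, f) for z, f in minima if f <= fbest + _TIE_TOL]
    if warm_start is not None and len(tied) > 1:
        w = np.asarray(warm_start, dtype=float)
        z, f = min(tied, key=lambda zf: float(np.hypot(*(zf[0] - w))))
    else:
        z, f = min(tied, key=lambda zf: zf[1])
    return QRESolution(
        lam=float(lam),
        alpha=float(z[0]),
        gamma=float(z[1]),
        residual=f,
        n_minima_found=len(minima),
        converged=bool(f < config.residual_tol),
    )


def trace_qre(config: SolverConfig | None = None) -> QRETrace:
    """Sweep lambda over ``config.lambda_grid`` ascending, warm-starting each
    solve from the previous solution when continuation is enabled."""
    if config is None:
        config = SolverConfig()
    sols: list[QRESolution] = []
    warm: tuple[float, float] | None = None
    for lam in config.lambda_grid:
        sol = solve_qre(float(lam), config, warm_start=warm)
        sols.append(sol)
        if config.continuation:
            warm = (sol.alpha, sol.gamma)
    return QRETrace(solutions=sols)


def count_local_minima(
    lam: float,
    grid_resolution: int = 201,
    payoffs: PayoffMatrix | None = None,
) -> int:
    """Number of distinct strict local minima of the fixed-point residual on
    an interior lattice (8-neighbour comparison), after refining each lattice
    candidate by bounded local minimization and merging refined minima closer
    than 0.02."""
    if grid_resolution < 101:
        raise ValueError("grid_resolution must be at least 101")
    if payoffs is None:
        payoffs = PayoffMatrix()
    axis = np.linspace(0.0, 1.0, grid_resolution)
    R = _residual_grid(lam, axis, payoffs)
    interior = R[1:-1, 1:-1]
    neigh_min = minimum_filter(R, size=3, mode="nearest")[1:-1, 1:-1]
    cand = np.argwhere((interior <= neigh_min) & np.isfinite(interior)) + 1

    merged: list[tuple[float, float]] = []
    for i, j in cand:
        try:
            z, f = _refine((axis[i], axis[j]), lam, payoffs, 1e-12)
        except (ZeroDivisionError, FloatingPointError):
            continue
        if not np.isfinite(f):
            continue
        if all(np.hypot(z[0] - a, z[1] - g) >= _MERGE_RADIUS for a, g in merged):
            merged.append((float(z[0]), float(z[1])))
    return len(merged)
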
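"""Landmarks of the QRE continuation curve.

Three quantities summarize how the traced symmetric QRE relates to the Nash
curve and to pure defection:

* the first intersection of the continuation branch (started at the
  lambda = 0 equilibrium (0.5, 0.5)) with the symmetric totally mixed Nash
  curve;
* the defection-collapse threshold: the rationality beyond which numerical
  fixed-point search is captured by the basin anchored at the pure-defection
  corner (0, 0).  This basin's local minimum of the fixed-point residual is
  born at a saddle-node bifurcation; from that lambda on, bounded descent
  started at (0.5, 0.5) lands in it, and its minimizer tends to (0, 0) as
  lambda grows.  The threshold is a property of the residual landscape, not
  of a particular solver trajectory;
* the small-rationality segment: the traced (alpha, gamma) polyline for
  lambda below the first intersection, which acts as a boundary separating
  low- and high-cooperation empirical strategies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nash import nash_implicit
from .qre import QRETrace, SolverConfig, _refine, solve_qre

__all__ = [
    "Landmarks",
    "NoCrossingError",
    "NoCollapseError",
    "find_nash_intersection",
    "find_collapse_threshold",
    "find_defection_onset",
    "small_rationality_segment",
    "classify_point",
    "compute_landmarks",
]

DEFECTION_CAPTURE_RADIUS = 0.4
"""Membership radius of the defection basin.  At its birth the basin's
minimum sits ~0.26 from (0, 0) and then moves monotonically toward the
corner, while every other residual minimum stays at distance > 0.55; any
radius in roughly (0.3, 0.55) yields the same threshold."""


class NoCrossingError(RuntimeError):
    """The trace never crosses the Nash curve."""


class NoCollapseError(RuntimeError):
    """The trace (or descent sweep) never settles near pure defection."""


@dataclass(frozen=True)
class Landmarks:
    lambda_intersect: float
    alpha_intersect: float
    gamma_intersect: float
    lambda_collapse: float
    segment: list[tuple[float, float]]


def _clip01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def _implicit_at(sol) -> float:
    return nash_implicit(_clip01(sol.alpha), _clip01(sol.gamma), variant="derived")


def find_nash_intersection(
    trace: QRETrace, config: SolverConfig | None = None
) -> tuple[float, float, float]:
    """First crossing of the traced QRE branch with the derived Nash curve.

    Walks the trace for the first sign change of the Nash implicit function,
    then refines lambda by bisection (re-solving with warm starts) to width
    1e-3.  Returns ``(lambda, alpha, gamma)`` at the crossing.
    """
    if config is None:
        config = SolverConfig()
    sols = trace.solutions
    prev_val = _implicit_at(sols[0])
    bracket = None
    for prev, cur in zip(sols, sols[1:]):
        cur_val = _implicit_at(cur)
        if prev_val == 0.0:
            return (prev.lam, prev.alpha, prev.gamma)
        if prev_val * cur_val < 0.0:
            bracket = (prev, cur, prev_val)
            break
        prev_val = cur_val
    if bracket is None:
        raise NoCrossingError("trace never crosses the Nash curve")

    lo, hi, lo_val = bracket
    lam_lo, z_lo = lo.lam, (lo.alpha, lo.gamma)
    lam_hi, z_hi = hi.lam, (hi.alpha, hi.gamma)
    while lam_hi - lam_lo > 1e-3:
        lam_mid = 0.5 * (lam_lo + lam_hi)
        sol = solve_qre(lam_mid, config, warm_start=z_lo)
        val = _implicit_at(sol)
        if val == 0.0:
            return (sol.lam, sol.alpha, sol.gamma)
        if lo_val * val < 0.0:
            lam_hi, z_hi = lam_mid, (sol.alpha, sol.gamma)
        else:
            lam_lo, z_lo, lo_val = lam_mid, (sol.alpha, sol.gamma), val
    # linear interpolation of the crossing inside the final bracket
    sol_lo = solve_qre(lam_lo, config, warm_start=z_lo)
    sol_hi = solve_qre(lam_hi, config, warm_start=z_hi)
    v0, v1 = _implicit_at(sol_lo), _implicit_at(sol_hi)
    w = 0.5 if v1 == v0 else v0 / (v0 - v1)
    return (
        lam_lo + w * (lam_hi - lam_lo),
        sol_lo.alpha + w * (sol_hi.alpha - sol_lo.alpha),
        sol_lo.gamma + w * (sol_hi.gamma - sol_lo.gamma),
    )


def find_collapse_threshold(trace: QRETrace, delta: float = 0.05) -> float:
    """Smallest grid lambda such that every trace solution at that lambda and
    beyond lies within Euclidean distance ``delta`` of (0, 0).

    Raises :class:`NoCollapseError` when the tail never enters and stays in
    the delta-ball.  Note that the global-minimum trace keeps exact
    high-cooperation fixed points at large rationality, so with small delta
    this criterion typically does not trigger; the defection-capture onset
    (:func:`find_defection_onset`) is the robust collapse diagnostic.
    """
    sols = trace.solutions
    inside = [np.hypot(s.alpha, s.gamma) <= delta for s in sols]
    threshold = None
    for sol, ok in zip(reversed(sols), reversed(inside)):
        if ok:
            threshold = sol.lam
        else:
            break
    if threshold is None:
        raise NoCollapseError(
            f"trace never remains within {delta} of the defection point"
        )
    return float(threshold)


def find_defection_onset(
    lambda_max: float = 10.0,
    step: float = 0.01,
    config: SolverConfig | None = None,
    capture_radius: float = DEFECTION_CAPTURE_RADIUS,
    start: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Smallest grid lambda from which bounded descent started at the
    lambda = 0 equilibrium is captured by the defection basin for that and
    every later grid lambda.

    Capture means the refined minimizer lies within ``capture_radius`` of
    (0, 0).  The onset coincides with the saddle-node birth of the
    defection-basin residual minimum.
    """
    if config is None:
        config = SolverConfig()
    lams = np.round(np.arange(0.0, lambda_max + 1e-9, step), 6)
    onset = None
    for lam in lams:
        z, _ = _refine(start, float(lam), config.payoffs, config.local_tol)
        captured = float(np.hypot(z[0], z[1])) < capture_radius
        if captured and onset is None:
            onset = float(lam)
        elif not captured:
            onset = None
    if onset is None:
        raise NoCollapseError(
            f"descent from {start} is never captured by the defection basin "
            f"for lambda up to {lambda_max}"
        )
    return onset


def small_rationality_segment(
    trace: QRETrace, lambda_intersect: float
) -> list[tuple[float, float]]:
    """The traced (alpha, gamma) polyline for lambda from 0 up to the first
    Nash-curve intersection."""
    seg = [
        (s.alpha, s.gamma) for s in trace.solutions if s.lam <= lambda_intersect
    ]
    if not seg:
        raise ValueError("no trace points at or below lambda_intersect")
    return seg


def classify_point(
    alpha_hat: float,
    gamma_hat: float,
    segment: list[tuple[float, float]],
    near_band: float = 0.05,
) -> tuple[str, float]:
    """Position of an empirical strategy relative to the small-rationality
    segment.

    Returns ``(label, distance)`` where distance is to the nearest point of
    the segment polyline and label is ``'near'`` if the distance is below
    ``near_band``, else ``'above'``/``'below'`` according to whether
    gamma_hat exceeds the gamma-coordinate of that nearest point.
    """
    if not segment:
        raise ValueError("segment must be non-empty")
    pts = np.asarray(segment, dtype=float)
    q = np.array([alpha_hat, gamma_hat], dtype=float)
    if len(pts) == 1:
        nearest = pts[0]
        dist = float(np.hypot(*(q - nearest)))
    else:
        a = pts[:-1]
        b = pts[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.zeros(len(a))
        nz = denom > 0
        t[nz] = np.einsum("ij,ij->i", (q - a)[nz], ab[nz]) / denom[nz]
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.hypot(proj[:, 0] - q[0], proj[:, 1] - q[1])
        k = int(np.argmin(d))
        nearest = proj[k]
        dist = float(d[k])
    if dist < near_band:
        return ("near", dist)
    return ("above" if gamma_hat > nearest[1] else "below", dist)


def compute_landmarks(
    config: SolverConfig | None = None,
    lambda_max_trace: float = 8.0,
    lambda_max_collapse: float = 10.0,
    step: float = 0.01,
) -> Landmarks:
    """Trace the QRE and extract all landmarks in one call."""
    from .qre import trace_qre  # local import to keep module import light

    base = config if config is not None else SolverConfig()
    cfg = SolverConfig(
        lambda_grid=np.round(np.arange(0.0, lambda_max_trace + 1e-9, step), 6),
        restart_grid_size=base.restart_grid_size,
        local_tol=base.local_tol,
        residual_tol=base.residual_tol,
        continuation=True,
        seed=base.seed,
        payoffs=base.payoffs,
    )
    trace = trace_qre(cfg)
    lam_x, a_x, g_x = find_nash_intersection(trace, cfg)
    lam_c = find_defection_onset(lambda_max=lambda_max_collapse, step=step, config=cfg)
    seg = small_rationality_segment(trace, lam_x)
    return Landmarks(
        lambda_intersect=lam_x,
        alpha_intersect=a_x,
        gamma_intersect=g_x,
        lambda_collapse=lam_c,
        segment=seg,
    )
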
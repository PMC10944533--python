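"""Steady-state transcriptional activity and dose-response sensitivity.

The transcriptional activity of a switch is the stationary probability that
the promoter is in a transcribing state, as a function of the normalized
repressor load (R_T/K_r for the cooperative model, the molar ratio R_T/A_T
for the sequestration family).  The sharpness of the on->off transition is
summarised by the effective Hill coefficient

    n_eff = log 81 / log(EC10 / EC90),

where EC90 and EC10 are the loads at which the activity crosses 0.9 and 0.1.
A Michaelis-Menten response gives n_eff = 1; larger values mean
ultrasensitivity.

For the sequestration family the default backend treats the titration of
activator by repressor deterministically (mean-field), with the single
promoter copy included in the conservation totals, and solves the 2- or
3-state promoter chain at the resulting free-molecule levels.  The exact
chemical master equation marginal is available as ``backend="cme"`` and is
used as the oracle in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .model_core import (
    Architecture,
    NormalizedParameters,
    ParameterSet,
    ValidationError,
    build_network,
)

__all__ = [
    "ActivityCurve",
    "HillSummary",
    "BracketingError",
    "cooperative_activity",
    "sequestration_activity",
    "activity_curve",
    "ec_thresholds",
    "effective_hill",
    "hill_summary",
    "meanfield_point",
]


class BracketingError(ValueError):
    """An EC target is not bracketed by the activity grid."""


class ConvergenceError(RuntimeError):
    """The mean-field fixed point failed to converge."""


@dataclass(frozen=True)
class ActivityCurve:
    """Activity versus normalized repressor load for one architecture."""

    grid: np.ndarray
    activity: np.ndarray
    architecture: Architecture
    normalized: Optional[NormalizedParameters] = None
    backend: str = "meanfield"

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "activity", np.asarray(self.activity, dtype=float))
        if self.grid.shape != self.activity.shape:
            raise ValueError("grid and activity must have matching shapes")

    def interp(self, load: float) -> float:
        return float(np.interp(load, self.grid, self.activity))


@dataclass(frozen=True)
class HillSummary:
    """EC90/EC10 crossing loads and the effective Hill coefficient."""

    EC90: float
    EC10: float
    n_eff: float


def cooperative_activity(Rt_tilde, c: float):
    """Equilibrium activity of the three-site cooperative-repression model.

    Statistical weights of the promoter microstates with ``x = R_T/K_r``:
    empty 1, one site bound 3x, two sites 3x^2/c, all three x^3/c^3 (the
    successive dissociation constants are K_r, c*K_r, c^2*K_r).  The
    activity is the probability that at least one site is unoccupied,
    1 - w_111/Z.  Free repressor is approximated by R_T (one gene copy
    depletes at most 3 molecules).
    """
    if not 0 < c <= 1:
        raise ValidationError(f"cooperativity factor c must be in (0, 1], got {c}")
    x = np.asarray(Rt_tilde, dtype=float)
    if (x < 0).any():
        raise ValidationError("normalized load must be >= 0")
    z_open = 1.0 + 3.0 * x + 3.0 * x**2 / c
    w_full = x**3 / c**3
    act = z_open / (z_open + w_full)
    return float(act) if np.isscalar(Rt_tilde) else act


def _promoter_chain_occupancy(
    architecture: Architecture,
    a: float,
    r: float,
    ra: float,
    params: ParameterSet,
) -> tuple[float, float]:
    """Stationary (P(E_A), P(E_R)) of the promoter chain at fixed free levels.

    All transitions share the association constant k_on, which cancels from
    the stationary distribution; for a driven displacement cycle the result
    still depends on how each K splits into on/off rates, and this is the
    configured splitting (common k_on).
    """
    if not architecture.has_blocking:
        p_a = a / (a + params.K_a)
        return p_a, 0.0
    kd = params.K_d if architecture.has_displacement else 0.0
    ra_bind = ra if architecture.has_displacement else 0.0
    # states ordered (E_F, E_A, E_R); columns hold outflow on the diagonal
    Q = np.array(
        [
            [-(a + ra_bind), params.K_a, kd],
            [a, -(params.K_a + r), params.K_b],
            [ra_bind, r, -(params.K_b + kd)],
        ]
    )
    A = np.vstack([Q[:2, :], np.ones(3)])
    b = np.array([0.0, 0.0, 1.0])
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return float(pi[1]), float(pi[2])


def _titrate(a_tot: float, r_tot: float, K_s: float) -> float:
    """Complex level R_A from the solution equilibrium A*R = K_s*R_A with
    conservation a_tot = A + R_A, r_tot = R + R_A (stable quadratic root)."""
    s = a_tot + r_tot + K_s
    disc = s * s - 4.0 * a_tot * r_tot
    return 2.0 * a_tot * r_tot / (s + math.sqrt(max(disc, 0.0)))


def meanfield_point(
    architecture: Architecture,
    params: ParameterSet,
    R_T: Optional[float] = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> dict:
    """Self-consistent mean-field steady state at one repressor load.

    Iterates between (i) the titration equilibrium for free A, free R and
    the complex R_A given the activator/repressor not held on the promoter,
    and (ii) the stationary occupancy of the promoter chain at those free
    levels, until the occupancies are stationary to ``tol``.
    """
    if not architecture.sequestration_family:
        raise ValidationError("meanfield_point applies to the sequestration family")
    r_total = float(params.R_T if R_T is None else R_T)
    a_total = float(params.A_T)
    p_a, p_r = 0.0, 0.0
    for _ in range(max_iter):
        a_eff = max(a_total - p_a - p_r, 0.0)
        r_eff = max(r_total - p_r, 0.0)
        ra = _titrate(a_eff, r_eff, params.K_s)
        a = max(a_eff - ra, 0.0)
        r = max(r_eff - ra, 0.0)
        p_a_new, p_r_new = _promoter_chain_occupancy(architecture, a, r, ra, params)
        resid = max(abs(p_a_new - p_a), abs(p_r_new - p_r))
        p_a = (1.0 - damping) * p_a + damping * p_a_new
        p_r = (1.0 - damping) * p_r + damping * p_r_new
        if resid < tol:
            return {
                "activity": p_a_new,
                "p_EA": p_a_new,
                "p_ER": p_r_new,
                "A_free": a,
                "R_free": r,
                "R_A": ra,
            }
    raise ConvergenceError(
        f"mean-field fixed point did not converge at load R_T={r_total} "
        f"(residual after {max_iter} iterations)"
    )


def _cme_activity_point(
    architecture: Architecture, params: ParameterSet, R_T: int
) -> float:
    from . import cme  # deferred to avoid an import cycle

    network = build_network(architecture, params.replace(R_T=int(round(R_T))))
    return cme.activity_probability(network)


def sequestration_activity(
    architecture: Architecture,
    params: ParameterSet,
    loads: Optional[Sequence[float]] = None,
    backend: str = "meanfield",
) -> ActivityCurve:
    """Activity curve over a grid of molar ratios R_T/A_T."""
    if isinstance(architecture, str):
        architecture = Architecture.from_name(architecture)
    if not architecture.sequestration_family:
        raise ValidationError("sequestration_activity applies to the sequestration family")
    params.validate(architecture)
    grid = np.linspace(0.0, 2.0, 400) if loads is None else np.asarray(loads, dtype=float)
    if backend == "meanfield":
        act = np.array(
            [meanfield_point(architecture, params, R_T=x * params.A_T)["activity"] for x in grid]
        )
    elif backend == "cme":
        act = np.array(
            [_cme_activity_point(architecture, params, round(x * params.A_T)) for x in grid]
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return ActivityCurve(
        grid,
        act,
        architecture,
        NormalizedParameters.from_params(params, architecture),
        backend=backend,
    )


def activity_curve(
    architecture: Architecture,
    params: ParameterSet,
    loads: Optional[Sequence[float]] = None,
    backend: str = "meanfield",
) -> ActivityCurve:
    """Activity versus normalized load for any architecture."""
    if isinstance(architecture, str):
        architecture = Architecture.from_name(architecture)
    if architecture is Architecture.COOPERATIVE:
        params.validate(architecture)
        grid = (
            np.geomspace(1e-2, 1e2, 400) if loads is None else np.asarray(loads, dtype=float)
        )
        return ActivityCurve(
            grid,
            cooperative_activity(grid, params.c),
            architecture,
            NormalizedParameters.from_params(params, architecture),
            backend="closed_form",
        )
    return sequestration_activity(architecture, params, loads, backend=backend)


def _bisect_crossing(
    f: Callable[[float], float], lo: float, hi: float, target: float, tol: float = 1e-6
) -> float:
    """Bisection for the load where a non-increasing activity crosses target."""
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo >= target >= f_hi):
        raise BracketingError(
            f"activity target {target} not bracketed on [{lo}, {hi}] "
            f"(activity {f_lo:.4g}..{f_hi:.4g}); extend the load grid"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target) < tol or (hi - lo) < 1e-14 * max(1.0, abs(hi)):
            return mid
        if f_mid >= target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ec_thresholds(
    curve: ActivityCurve,
    f: Optional[Callable[[float], float]] = None,
    targets: tuple[float, float] = (0.9, 0.1),
) -> tuple[float, float]:
    """Loads at which activity crosses the EC90 and EC10 targets.

    Brackets each crossing on the (monotone, interpolated) grid and refines
    by bisection - on the continuous model when a callable is supplied,
    otherwise on the piecewise-linear interpolant.
    """
    grid, act = curve.grid, curve.activity
    out = []
    for target in targets:
        below = np.nonzero(act <= target)[0]
        above = np.nonzero(act >= target)[0]
        if len(below) == 0 or len(above) == 0:
            raise BracketingError(
                f"activity target {target} not bracketed by the grid "
                f"(range {act.min():.4g}..{act.max():.4g}); extend the load grid"
            )
        hi_idx = below[0]  # first point at/below the target
        lo_idx = max(hi_idx - 1, 0)
        lo, hi = grid[lo_idx], grid[hi_idx]
        if f is None:
            func = curve.interp
        else:
            func = f
        if lo == hi:
            out.append(float(lo))
        else:
            out.append(_bisect_crossing(func, float(lo), float(hi), target))
    ec90, ec10 = out
    return ec90, ec10


def effective_hill(ec90: float, ec10: float) -> float:
    """log 81 / log(EC10/EC90); 1 for Michaelis-Menten, n for Hill-n."""
    if not 0 < ec90 < ec10:
        raise ValidationError(f"require 0 < EC90 < EC10, got EC90={ec90}, EC10={ec10}")
    return math.log(81.0) / math.log(ec10 / ec90)


def hill_summary(
    architecture: Architecture,
    params: ParameterSet,
    loads: Optional[Sequence[float]] = None,
    backend: str = "meanfield",
    max_extensions: int = 8,
) -> HillSummary:
    """EC thresholds and effective Hill coefficient for one parameter set.

    The load grid is extended automatically (towards 0 and larger loads)
    when the default grid fails to bracket an EC target.
    """
    if isinstance(architecture, str):
        architecture = Architecture.from_name(architecture)
    curve = activity_curve(architecture, params, loads, backend=backend)
    if architecture is Architecture.COOPERATIVE:
        f = lambda x: cooperative_activity(x, params.c)  # noqa: E731
    elif backend == "meanfield":
        f = lambda x: meanfield_point(architecture, params, R_T=x * params.A_T)["activity"]  # noqa: E731
    else:
        f = None
    for _ in range(max_extensions):
        try:
            ec90, ec10 = ec_thresholds(curve, f=f)
            return HillSummary(ec90, ec10, effective_hill(ec90, ec10))
        except BracketingError:
            lo = curve.grid[curve.grid > 0].min() / 10.0
            hi = curve.grid.max() * 2.0
            n = len(curve.grid)
            if architecture is Architecture.COOPERATIVE:
                new_grid = np.geomspace(lo, hi, n)
            else:
                new_grid = np.linspace(0.0, hi, n)
            curve = activity_curve(architecture, params, new_grid, backend=backend)
    raise BracketingError(
        "EC targets not bracketed after automatic grid extension; the activity "
        "curve may not span 0.9/0.1 for these parameters"
    )
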
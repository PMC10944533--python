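"""Exact stationary distributions from the truncated chemical master equation.

The reachable state space of a :class:`~switchnoise.model_core.ReactionNetwork`
is enumerated exhaustively under per-species caps (the mRNA count is truncated
at ``M_max``, and the free repressor under turnover at a Poisson-tail bound).
Truncation is reflecting: transitions that would leave the truncated box are
dropped, which is the standard choice for stationary solutions.  The sparse
generator is solved for its null vector by sparse LU with one row replaced by
the normalization constraint; a uniformized power iteration is the fallback.
Solutions are accepted only if the residual ||Q p||_inf < 1e-10 and the
probability mass on every truncation boundary is below 1e-8 (``solve``
doubles the caps until the tail criterion passes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_core import Architecture, ParameterSet, ReactionNetwork, build_network

__all__ = [
    "StateSpace",
    "SteadyStateDistribution",
    "NoiseSummary",
    "TruncationError",
    "StateSpaceSizeError",
    "enumerate_states",
    "build_generator",
    "steady_state",
    "noise_summary",
    "noise_moments",
    "activity_probability",
    "solve",
    "fano_curve",
    "default_M_max",
]


class TruncationError(RuntimeError):
    """Probability mass at the truncation boundary exceeds tolerance."""


class StateSpaceSizeError(RuntimeError):
    """Enumeration exceeded the configured state-count cap."""


@dataclass
class StateSpace:
    """Exhaustive reachable enumeration of a truncated network."""

    network: ReactionNetwork
    states: np.ndarray  # (n_states, n_species) int64
    caps: dict  # species name -> max count enforced during enumeration

    def __post_init__(self):
        # mixed-radix integer key per state for O(log n) vectorized lookup;
        # rows outside the per-species range must be rejected before keying
        self._maxima = self.states.max(axis=0).astype(np.int64)
        radix = self._maxima + 1
        if int(np.prod(radix.astype(object))) > 2**62:
            raise StateSpaceSizeError(
                "state box too large for integer keying; reduce copy numbers"
            )
        mult = np.ones(len(radix), dtype=np.int64)
        for i in range(len(radix) - 2, -1, -1):
            mult[i] = mult[i + 1] * radix[i + 1]
        self._mult = mult
        keys = self.states @ mult
        order = np.argsort(keys)
        self._sorted_keys = keys[order]
        self._order = order
        if len(np.unique(self._sorted_keys)) != len(keys):
            raise RuntimeError("duplicate states in enumeration")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def lookup(self, states: np.ndarray) -> np.ndarray:
        """Indices of rows of ``states`` in the enumeration; -1 if absent."""
        arr = np.asarray(states, dtype=np.int64)
        in_range = ((arr >= 0) & (arr <= self._maxima)).all(axis=1)
        keys = arr @ self._mult
        pos = np.searchsorted(self._sorted_keys, keys)
        pos = np.clip(pos, 0, len(self._sorted_keys) - 1)
        found = in_range & (self._sorted_keys[pos] == keys)
        idx = np.where(found, self._order[pos], -1)
        return idx


def default_M_max(params: ParameterSet) -> int:
    """Initial mRNA truncation: mean + 10 sd of the constitutive Poisson
    bound alpha/beta (auto-doubled until the tail criterion passes)."""
    lam = params.alpha / params.beta
    return int(math.ceil(lam + 10.0 * math.sqrt(max(lam, 1.0)))) + 1


def _default_caps(network: ReactionNetwork, M_max: int) -> dict:
    caps = {network.mrna_species: int(M_max)}
    params = network.params
    if params is not None and params.turnover is not None and "R" in network.index:
        lam = params.turnover.mean_copy_number
        base = params.R_T if params.R_T > 0 else 0
        caps["R"] = int(math.ceil(max(lam, base) + 10.0 * math.sqrt(max(lam, 1.0)))) + 1
    return caps


def enumerate_states(
    network: ReactionNetwork,
    M_max: int,
    caps: Optional[dict] = None,
    max_states: int = 2_000_000,
) -> StateSpace:
    """Breadth-first enumeration of all states reachable from the initial
    condition under the truncation caps."""
    if M_max < 0:
        raise ValueError("M_max must be >= 0")
    all_caps = _default_caps(network, M_max)
    if caps:
        all_caps.update(caps)
    cap_vec = np.full(network.n_species, np.iinfo(np.int64).max, dtype=np.int64)
    for name, cap in all_caps.items():
        cap_vec[network.index[name]] = cap
    deltas = network.stoichiometry()
    frontier = np.ascontiguousarray(network.init_state[None, :].astype(np.int64))
    seen = {frontier.tobytes()}
    chunks = [frontier]
    n_seen = 1
    while len(frontier):
        cands = []
        for j, rxn in enumerate(network.reactions):
            ok = np.ones(len(frontier), dtype=bool)
            for i, nreq in rxn.reactants:
                ok &= frontier[:, i] >= nreq
            if not ok.any():
                continue
            t = frontier[ok] + deltas[j]
            inside = ((t >= 0) & (t <= cap_vec)).all(axis=1)
            if inside.any():
                cands.append(t[inside])
        if not cands:
            break
        cand = np.unique(np.concatenate(cands), axis=0)
        cand = np.ascontiguousarray(cand)
        row_bytes = cand.tobytes()
        width = cand.shape[1] * 8
        new_mask = np.fromiter(
            (row_bytes[i * width : (i + 1) * width] not in seen for i in range(len(cand))),
            dtype=bool,
            count=len(cand),
        )
        frontier = np.ascontiguousarray(cand[new_mask])
        if len(frontier):
            fb = frontier.tobytes()
            seen.update(fb[i * width : (i + 1) * width] for i in range(len(frontier)))
            chunks.append(frontier)
            n_seen += len(frontier)
            if n_seen > max_states:
                raise StateSpaceSizeError(
                    f"reachable state count exceeds {max_states}; reduce "
                    "copy numbers (A_T, R_T) or the truncation caps"
                )
    states = np.concatenate(chunks)
    order = np.lexsort(states.T[::-1])
    states = states[order]
    return StateSpace(network, states, all_caps)


def build_generator(network: ReactionNetwork, space: StateSpace) -> sp.csc_matrix:
    """Sparse CME generator Q with Q[j, i] the rate from state i to state j;
    every column sums to zero."""
    n = space.n_states
    states = space.states
    deltas = network.stoichiometry()
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for j, rxn in enumerate(network.reactions):
        prop = np.full(n, rxn.rate)
        for i, cnt in rxn.reactants:
            col = states[:, i].astype(float)
            if cnt == 1:
                prop = prop * col
            else:
                ff = col.copy()
                for k in range(1, cnt):
                    ff *= col - k
                prop = prop * ff
        active = prop > 0
        if not active.any():
            continue
        targets = states[active] + deltas[j]
        tidx = space.lookup(targets)
        keep = tidx >= 0  # transitions leaving the truncation are dropped
        src = np.nonzero(active)[0][keep]
        dst = tidx[keep]
        a = prop[active][keep]
        rows.append(dst)
        cols.append(src)
        vals.append(a)
        np.add.at(diag, src, -a)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    Q = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    colsum = np.abs(np.asarray(Q.sum(axis=0)).ravel())
    if colsum.max() > 1e-9:
        raise RuntimeError(
            f"generator column sums deviate from zero by {colsum.max():.3g}"
        )
    return Q


@dataclass
class SteadyStateDistribution:
    """Stationary probability over the enumerated states."""

    space: StateSpace
    p: np.ndarray
    residual: float

    @property
    def network(self) -> ReactionNetwork:
        return self.space.network

    def marginal(self, species: str) -> np.ndarray:
        """Marginal pmf of one species, indexed by copy number 0..max."""
        counts = self.space.states[:, self.network.index[species]]
        return np.bincount(counts, weights=self.p, minlength=int(counts.max()) + 1)

    def mrna_marginal(self) -> np.ndarray:
        return self.marginal(self.network.mrna_species)

    def promoter_marginal(self) -> dict:
        return {
            name: float(self.p[self.space.states[:, self.network.index[name]] == 1].sum())
            for name in self.network.promoter_species
        }

    def transcribing_probability(self) -> float:
        pm = self.promoter_marginal()
        return sum(pm[name] for name in self.network.transcribing_species)

    def boundary_mass(self) -> dict:
        """Probability on each truncation boundary (species at its cap)."""
        out = {}
        for name, cap in self.space.caps.items():
            col = self.space.states[:, self.network.index[name]]
            out[name] = float(self.p[col == cap].sum())
        return out


def steady_state(
    Q: sp.csc_matrix,
    space: StateSpace,
    residual_tol: float = 1e-10,
    tail_tol: float = 1e-8,
    check_tail: bool = True,
) -> SteadyStateDistribution:
    """Null-space solve of the generator (sparse LU, one row replaced by the
    normalization constraint), with a uniformized power-iteration fallback."""
    n = Q.shape[0]
    p = None
    try:
        A = Q.tolil(copy=True)
        A[-1, :] = 1.0
        b = np.zeros(n)
        b[-1] = 1.0
        lu = spla.splu(A.tocsc())
        p = lu.solve(b)
    except Exception:
        p = None
    if p is not None:
        if p.min() < -1e-9 * max(p.max(), 1.0):
            p = None  # badly signed solution; fall back
    if p is None:
        # power iteration on the uniformized transition matrix
        lam = 1.1 * float(np.abs(Q.diagonal()).max()) + 1e-12
        P = sp.eye(n, format="csr") + Q.tocsr() / lam
        p = np.full(n, 1.0 / n)
        for _ in range(200_000):
            p_new = P @ p
            p_new = np.clip(p_new, 0.0, None)
            p_new /= p_new.sum()
            if np.abs(Q @ p_new).max() < residual_tol:
                p = p_new
                break
            p = p_new
    if p.min() < -1e-12:
        raise RuntimeError(f"negative stationary probabilities ({p.min():.3g})")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    resid = float(np.abs(Q @ p).max())
    if resid > residual_tol:
        raise RuntimeError(
            f"stationary residual ||Qp||_inf = {resid:.3g} exceeds {residual_tol}"
        )
    dist = SteadyStateDistribution(space, p, resid)
    if check_tail:
        tails = dist.boundary_mass()
        bad = {k: v for k, v in tails.items() if v > tail_tol}
        if bad:
            raise TruncationError(
                f"truncation tail mass {bad} exceeds {tail_tol}; increase the caps"
            )
    return dist


def solve(
    network: ReactionNetwork,
    M_max: Optional[int] = None,
    caps: Optional[dict] = None,
    check_tail: bool = True,
    max_doublings: int = 6,
    max_states: int = 2_000_000,
) -> SteadyStateDistribution:
    """Stationary distribution with automatic cap doubling until the
    truncation-tail criterion passes."""
    if M_max is None:
        M_max = default_M_max(network.params) if network.params is not None else 100
    caps = dict(caps or {})
    for _ in range(max_doublings + 1):
        space = enumerate_states(network, M_max, caps=caps, max_states=max_states)
        Q = build_generator(network, space)
        try:
            return steady_state(Q, space, check_tail=check_tail)
        except TruncationError:
            dist = steady_state(Q, space, check_tail=False)
            tails = dist.boundary_mass()
            for name, mass in tails.items():
                if mass > 1e-8:
                    if name == network.mrna_species:
                        M_max *= 2
                    else:
                        caps[name] = 2 * space.caps[name]
    raise TruncationError(
        "tail criterion still failing after repeated cap doubling; the "
        "distribution may not be truncatable at a tractable size"
    )


@dataclass(frozen=True)
class NoiseSummary:
    """Moments and modality of the stationary mRNA copy-number marginal.

    ``modes`` is None when the summary was computed from exact moment
    equations without materializing the full distribution."""

    mean: float
    variance: float
    fano: float
    cv: Optional[float]
    modes: Optional[int]

    @classmethod
    def from_marginal(cls, pm: np.ndarray, peak_threshold: float = 1e-4) -> "NoiseSummary":
        pm = np.asarray(pm, dtype=float)
        pm = pm / pm.sum()
        m = np.arange(len(pm))
        mean = float(pm @ m)
        var = float(pm @ (m - mean) ** 2)
        if mean > 0:
            fano = var / mean
            cv = math.sqrt(var) / mean
        else:
            fano = 1.0 if var == 0 else math.nan
            cv = None
        return cls(mean, var, fano, cv, _count_modes(pm, peak_threshold))


def _count_modes(pm: np.ndarray, peak_threshold: float) -> int:
    """Local maxima of the pmf after merging equal-valued plateaus; peaks
    carrying less than ``peak_threshold`` probability are ignored."""
    vals = []
    for v in pm:
        if not vals or v != vals[-1]:
            vals.append(float(v))
    modes = 0
    for i, v in enumerate(vals):
        if v < peak_threshold:
            continue
        left = vals[i - 1] if i > 0 else -1.0
        right = vals[i + 1] if i < len(vals) - 1 else -1.0
        if v > left and v > right:
            modes += 1
    return modes


def noise_summary(
    dist: SteadyStateDistribution, peak_threshold: float = 1e-4
) -> NoiseSummary:
    """Mean, variance, Fano factor, CV and mode count of the mRNA marginal."""
    return NoiseSummary.from_marginal(dist.mrna_marginal(), peak_threshold)


def noise_moments(network: ReactionNetwork, caps: Optional[dict] = None) -> NoiseSummary:
    """Exact stationary mRNA moments without enumerating the mRNA dimension.

    The mRNA count is a linear birth-death process driven by the promoter
    indicator xi (transcription alpha*xi, decay beta per molecule) and does
    not feed back on the rest of the network, so

        E[m]   = (alpha/beta) E[xi],
        Var(m) = E[m] + (alpha^2/beta) * xi' (beta I - Q)^-1 (xi o pi - E[xi] pi),

    where Q and pi are the generator and stationary distribution of the
    promoter/complex chain alone and the resolvent term integrates the
    exponentially filtered autocovariance of xi.  This matches the full
    truncated-CME solution to solver precision at a fraction of the cost;
    modality is not available from moments (``modes`` is None).
    """
    params = network.params
    if params is None:
        raise ValueError("noise_moments requires a network with parameters attached")
    space = enumerate_states(network, M_max=0, caps=caps)
    Q = build_generator(network, space)
    dist = steady_state(Q, space, check_tail=False)
    tails = {k: v for k, v in dist.boundary_mass().items() if k != network.mrna_species}
    bad = {k: v for k, v in tails.items() if v > 1e-8}
    if bad:
        raise TruncationError(f"truncation tail mass {bad} exceeds 1e-8; increase caps")
    pi = dist.p
    cols = [network.index[s] for s in network.transcribing_species]
    xi = (space.states[:, cols].sum(axis=1) > 0).astype(float)
    mean_xi = float(xi @ pi)
    alpha, beta = params.alpha, params.beta
    mean_m = alpha / beta * mean_xi
    n = Q.shape[0]
    A = (beta * sp.eye(n, format="csc")) - Q
    rhs = xi * pi - mean_xi * pi
    y = spla.splu(A).solve(rhs)
    var = mean_m + (alpha**2 / beta) * float(xi @ y)
    if mean_m > 0:
        fano = var / mean_m
        cv = math.sqrt(max(var, 0.0)) / mean_m
    else:
        fano = 1.0 if var == 0 else math.nan
        cv = None
    return NoiseSummary(mean_m, var, fano, cv, None)


def fano_curve(
    architecture: Architecture,
    params: ParameterSet,
    loads: Sequence[float],
    M_max: Optional[int] = None,
    method: str = "moments",
) -> pd.DataFrame:
    """Noise statistics along a grid of normalized repressor loads.

    One exact stationary computation per load; the repressor copy number at
    each load is the nearest integer realisation of the normalized load.
    ``method="moments"`` uses the promoter-chain moment equations (fast;
    no modality), ``method="distribution"`` the full truncated joint.
    Errors are re-raised with the failing load identified.
    """
    if isinstance(architecture, str):
        architecture = Architecture.from_name(architecture)
    if method not in ("moments", "distribution"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for load in loads:
        p = params.with_load(architecture, load)
        try:
            network = build_network(architecture, p)
            if method == "moments":
                ns = noise_moments(network)
                act = activity_probability(network)
            else:
                dist = solve(network, M_max=M_max)
                ns = noise_summary(dist)
                act = dist.transcribing_probability()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise type(exc)(f"fano_curve failed at load {load}: {exc}") from exc
        rows.append(
            {
                "load": float(load),
                "R_T": p.R_T,
                "mean": ns.mean,
                "variance": ns.variance,
                "fano": ns.fano,
                "cv": ns.cv if ns.cv is not None else math.nan,
                "modes": ns.modes if ns.modes is not None else math.nan,
                "activity": act,
            }
        )
    return pd.DataFrame(rows)


def activity_probability(network: ReactionNetwork) -> float:
    """Exact stationary probability of a transcribing promoter state."""
    space = enumerate_states(network, M_max=0)
    Q = build_generator(network, space)
    dist = steady_state(Q, space, check_tail=False)
    return dist.transcribing_probability()
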
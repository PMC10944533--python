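"""Gillespie stochastic simulation (direct method) with stationary estimators.

The direct method is statistically exact for the networks built by
:mod:`switchnoise.model_core`; copy numbers are small enough that approximate
accelerations (tau-leaping) are unnecessary.  Two entry points are provided:

``simulate``
    Full event log (a :class:`Trajectory`), used for timeseries figures and
    promoter dwell-time analysis.

``stationary_moments``
    Streaming time-averaged mRNA moments with batch-means standard errors,
    used as the independent oracle for the chemical-master-equation engine.
    It never materializes the event log, so arbitrarily long runs are cheap
    in memory.

Identical seeds give bitwise-identical trajectories.  Kernels are compiled
with numba when available and fall back to pure Python otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import InvariantViolationError, ReactionNetwork

try:  # pragma: no cover - exercised implicitly
    import numba

    _njit = numba.njit(cache=False)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def _njit(f):
        return f

    HAVE_NUMBA = False

__all__ = [
    "Trajectory",
    "StationaryEstimate",
    "simulate",
    "stationary_estimate",
    "stationary_moments",
    "occupancy_timeline",
    "mean_dwell_times",
]


@_njit
def _ssa_event_kernel(state, ridx, rcnt, rates, deltas, t_end, seed, max_events):
    n_r = rates.shape[0]
    np.random.seed(seed)
    times = np.empty(max_events, dtype=np.float64)
    which = np.empty(max_events, dtype=np.int32)
    props = np.empty(n_r, dtype=np.float64)
    t = 0.0
    n = 0
    while True:
        a0 = 0.0
        for j in range(n_r):
            a = rates[j]
            for k in range(ridx.shape[1]):
                c = rcnt[j, k]
                if c > 0:
                    a *= state[ridx[j, k]]
            props[j] = a
            a0 += a
        if a0 <= 0.0:
            break
        t += -math.log(np.random.random()) / a0
        if t > t_end:
            break
        target = np.random.random() * a0
        acc = 0.0
        j = 0
        for jj in range(n_r):
            acc += props[jj]
            if acc >= target:
                j = jj
                break
        for i in range(deltas.shape[1]):
            state[i] += deltas[j, i]
        times[n] = t
        which[n] = j
        n += 1
        if n >= max_events:
            return times[:n], which[:n], state, 1
    return times[:n], which[:n], state, 0


@_njit
def _ssa_moments_kernel(
    state, ridx, rcnt, rates, deltas, m_index, t_end, batch_edges, seed
):
    """Time-weighted first/second mRNA moments per batch window.

    ``batch_edges`` are increasing times starting at the burn-in and ending
    at ``t_end``; the occupation integral of m and m**2 is accumulated per
    window.  Returns (batch_T, batch_m, batch_m2, n_events).
    """
    n_r = rates.shape[0]
    nb = batch_edges.shape[0] - 1
    np.random.seed(seed)
    props = np.empty(n_r, dtype=np.float64)
    batch_T = np.zeros(nb, dtype=np.float64)
    batch_m = np.zeros(nb, dtype=np.float64)
    batch_m2 = np.zeros(nb, dtype=np.float64)
    t = 0.0
    n_events = 0
    while t < t_end:
        a0 = 0.0
        for j in range(n_r):
            a = rates[j]
            for k in range(ridx.shape[1]):
                if rcnt[j, k] > 0:
                    a *= state[ridx[j, k]]
            props[j] = a
            a0 += a
        if a0 <= 0.0:
            t_next = t_end
        else:
            t_next = t + (-math.log(np.random.random()) / a0)
            if t_next > t_end:
                t_next = t_end
        # deposit the dwell [t, t_next) into the batch windows
        m = float(state[m_index])
        lo, hi = t, t_next
        for b in range(nb):
            e0 = batch_edges[b]
            e1 = batch_edges[b + 1]
            if hi <= e0 or lo >= e1:
                continue
            seg = min(hi, e1) - max(lo, e0)
            batch_T[b] += seg
            batch_m[b] += seg * m
            batch_m2[b] += seg * m * m
        if a0 <= 0.0 or t_next >= t_end:
            break
        t = t_next
        target = np.random.random() * a0
        acc = 0.0
        j = 0
        for jj in range(n_r):
            acc += props[jj]
            if acc >= target:
                j = jj
                break
        for i in range(deltas.shape[1]):
            state[i] += deltas[j, i]
        n_events += 1
    return batch_T, batch_m, batch_m2, n_events


@dataclass
class Trajectory:
    """Event log of one stochastic realisation.

    ``times[i]`` is the time of event i and ``reaction_indices[i]`` the
    reaction that fired; states are reconstructed on demand from the initial
    state and the stoichiometry, so the log is compact.
    """

    network: ReactionNetwork
    times: np.ndarray
    reaction_indices: np.ndarray
    initial_state: np.ndarray
    final_state: np.ndarray
    t_end: float
    seed: int

    _states: Optional[np.ndarray] = None

    @property
    def n_events(self) -> int:
        return len(self.times)

    def states(self) -> np.ndarray:
        """(n_events + 1, n_species) array: row 0 is the initial state, row
        i the state after event i."""
        if self._states is None:
            deltas = self.network.stoichiometry()
            out = np.empty((self.n_events + 1, self.network.n_species), dtype=np.int64)
            out[0] = self.initial_state
            if self.n_events:
                np.cumsum(deltas[self.reaction_indices], axis=0, out=out[1:])
                out[1:] += self.initial_state
        else:
            return self._states
        self._states = out
        return out

    def sample_times(self) -> np.ndarray:
        """Times bounding each constant-state interval (len n_events + 2)."""
        return np.concatenate([[0.0], self.times, [self.t_end]])

    def species_series(self, name: str) -> np.ndarray:
        return self.states()[:, self.network.index[name]]


def simulate(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    init_state: Optional[np.ndarray] = None,
    max_events: int = 20_000_000,
) -> Trajectory:
    """Exact direct-method SSA run over [0, t_end].

    The default initial condition is the network's (free promoter, fully
    unbound, zero mRNA) state.  Identical seeds reproduce identical event
    sequences.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    state0 = np.array(
        network.init_state if init_state is None else init_state, dtype=np.int64
    )
    if (state0 < 0).any():
        raise InvariantViolationError("initial state has negative copy numbers")
    ridx, rcnt, rates = network.reactant_arrays()
    deltas = network.stoichiometry()
    times, which, final, truncated = _ssa_event_kernel(
        state0.copy(), ridx, rcnt, rates, deltas, float(t_end), int(seed) & 0x7FFFFFFF,
        int(max_events),
    )
    if truncated:
        raise RuntimeError(
            f"event capacity {max_events} reached at t={times[-1]:.3g} < t_end; "
            "increase max_events or use stationary_moments for long runs"
        )
    return Trajectory(
        network=network,
        times=np.array(times),
        reaction_indices=np.array(which),
        initial_state=state0,
        final_state=np.array(final),
        t_end=float(t_end),
        seed=int(seed),
    )


@dataclass(frozen=True)
class StationaryEstimate:
    """Time-averaged stationary mRNA statistics with batch-means errors."""

    mean: float
    variance: float
    fano: float
    se_mean: float
    se_fano: float
    n_batches: int
    t_span: float
    n_events: int

    def consistent_with(self, mean: float, fano: float, n_se: float = 3.0) -> bool:
        """Whether reference values lie within n_se standard errors."""
        return (
            abs(self.mean - mean) <= n_se * self.se_mean
            and abs(self.fano - fano) <= n_se * self.se_fano
        )


def _batch_statistics(
    batch_T: np.ndarray, batch_m: np.ndarray, batch_m2: np.ndarray, n_events: int
) -> StationaryEstimate:
    nb = len(batch_T)
    if nb < 20:
        raise ValueError("need at least 20 batches for batch-means errors")
    if (batch_T <= 0).any():
        raise ValueError("empty batch window; insufficient post-burn-in span")
    mu_k = batch_m / batch_T
    s2_k = batch_m2 / batch_T
    w = batch_T / batch_T.sum()
    mu = float(w @ mu_k)
    s2 = float(w @ s2_k)
    var = s2 - mu * mu
    if mu <= 0:
        raise ValueError("zero mean mRNA over the averaging window")
    fano = var / mu
    se_mu = float(np.std(mu_k, ddof=1) / math.sqrt(nb))
    # delta method on F(mu, s2) = s2/mu - mu
    cov = np.cov(np.vstack([mu_k, s2_k]), ddof=1) / nb
    g = np.array([-s2 / mu**2 - 1.0, 1.0 / mu])
    var_f = float(g @ cov @ g)
    se_f = math.sqrt(max(var_f, 0.0))
    return StationaryEstimate(
        mean=mu,
        variance=var,
        fano=fano,
        se_mean=max(se_mu, 1e-300),
        se_fano=max(se_f, 1e-300),
        n_batches=nb,
        t_span=float(batch_T.sum()),
        n_events=int(n_events),
    )


def stationary_estimate(
    trajectory: Trajectory, burn_in: Optional[float] = None, n_batches: int = 20
) -> StationaryEstimate:
    """Batch-means stationary estimate from an event log.

    ``burn_in`` defaults to 10% of the run; the remaining span is divided
    into equal batch windows and the mRNA occupation integrals are
    accumulated per window.
    """
    t_end = trajectory.t_end
    if burn_in is None:
        burn_in = 0.1 * t_end
    if burn_in >= t_end:
        raise ValueError(f"burn_in {burn_in} is not shorter than the run ({t_end})")
    edges = np.linspace(burn_in, t_end, n_batches + 1)
    bounds = trajectory.sample_times()
    m_series = trajectory.species_series(trajectory.network.mrna_species).astype(float)
    m_vals = np.concatenate([m_series, m_series[-1:]])  # value on each interval
    batch_T = np.zeros(n_batches)
    batch_m = np.zeros(n_batches)
    batch_m2 = np.zeros(n_batches)
    lo = np.maximum(bounds[:-1], burn_in)
    hi = np.minimum(bounds[1:], t_end)
    for b in range(n_batches):
        seg = np.clip(np.minimum(hi, edges[b + 1]) - np.maximum(lo, edges[b]), 0.0, None)
        batch_T[b] = seg.sum()
        batch_m[b] = seg @ m_vals[:-1]
        batch_m2[b] = seg @ (m_vals[:-1] ** 2)
    return _batch_statistics(batch_T, batch_m, batch_m2, trajectory.n_events)


def stationary_moments(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    burn_in: Optional[float] = None,
    n_batches: int = 20,
    init_state: Optional[np.ndarray] = None,
) -> StationaryEstimate:
    """Streaming stationary estimate (no event log kept in memory)."""
    if burn_in is None:
        burn_in = 0.1 * t_end
    if burn_in >= t_end:
        raise ValueError(f"burn_in {burn_in} is not shorter than the run ({t_end})")
    state0 = np.array(
        network.init_state if init_state is None else init_state, dtype=np.int64
    )
    ridx, rcnt, rates = network.reactant_arrays()
    deltas = network.stoichiometry()
    edges = np.linspace(burn_in, t_end, n_batches + 1)
    batch_T, batch_m, batch_m2, n_events = _ssa_moments_kernel(
        state0.copy(),
        ridx,
        rcnt,
        rates,
        deltas,
        network.mrna_index,
        float(t_end),
        edges,
        int(seed) & 0x7FFFFFFF,
    )
    return _batch_statistics(
        np.array(batch_T), np.array(batch_m), np.array(batch_m2), n_events
    )


def occupancy_timeline(trajectory: Trajectory) -> pd.DataFrame:
    """Promoter dwell intervals: columns (state, start, duration).

    Consecutive events that leave the promoter unchanged are merged, so each
    row is one maximal dwell in one promoter state; the final dwell extends
    to the end of the run.
    """
    network = trajectory.network
    states = trajectory.states()
    cols = [network.index[s] for s in network.promoter_species]
    promoter = np.argmax(states[:, cols], axis=1)
    bounds = trajectory.sample_times()
    change = np.nonzero(np.diff(promoter))[0] + 1  # index into state rows
    starts = np.concatenate([[0], change])
    start_times = bounds[starts]
    end_times = np.concatenate([bounds[change], [trajectory.t_end]])
    labels = [network.promoter_species[promoter[i]] for i in starts]
    return pd.DataFrame(
        {
            "state": labels,
            "start": start_times,
            "duration": end_times - start_times,
        }
    )


def mean_dwell_times(trajectory: Trajectory) -> dict:
    """Mean dwell time per promoter state over one trajectory."""
    df = occupancy_timeline(trajectory)
    return df.groupby("state")["duration"].mean().to_dict()
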
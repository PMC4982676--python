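"""Full plasticity dynamics: STDP drift, heterosynaptic competition,
self-depression, constant growth, and hard bounds.

The excitatory weights evolve as

    dW_ij/dt = eta * ( Delta_STDP_ij - psi*(Din_i + Dout_j) - mu*W_ij + gamma ),

clipped to [0, w_max] after every step.  Din_i (Dout_j) is the amount by which
the total excitatory input to neuron i (output of neuron j) exceeds W_max =
M * w_max; the Heaviside convention theta(0) = 1 is used, which is immaterial
since the excess is zero at equality.  The learning rate eta multiplies the
whole right-hand side: the convention that the self-depression rate is
eta*mu fixes the relative scale of the slow terms against the STDP
drift (eta*Delta); a config switch restores the variant where the slow terms
are not scaled by eta.

Deterministic mode evaluates the drift from the correlation theory (exact
frequency-domain integral, or the motif expansion truncated at a chosen
order) and advances with an adaptive Euler step whose size is set so the
largest weight change per step equals ``step_cap``.  Stochastic mode runs the
spiking simulator and applies pair-based STDP increments continuously through
exponential traces, with the slow terms applied every simulation step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .kernels import STDPFunction, SynapticKernel, make_alpha_kernel, make_stdp
from .motifs import (MotifCoefficientTable, coefficient_table, default_frequency_grid,
                     exact_drift, truncated_drift, DriftMatrix)
from .network import (ConnectivityState, InstabilityError, RateVector,
                      effective_connectivity, stationary_rates)

__all__ = [
    "PlasticityConfig",
    "Trajectory",
    "competition_terms",
    "deterministic_step",
    "run_deterministic",
    "run_stochastic",
    "generate_initial_weights",
]

CONVERGENCE_TOL = float(np.exp(-15.0))  # the literal e^-15 elementwise criterion


@dataclass
class PlasticityConfig:
    """All parameters of one plasticity run.

    Rates psi, mu, gamma are in 1/s and share the learning-rate scale eta
    (see module docstring).  ``W_max`` defaults to M * w_max.  ``drift_mode``
    is 'exact', 'truncated' (with ``truncation_order``), or 'stochastic'
    (implicit in run_stochastic).  ``coefficient_overrides`` replaces computed
    motif coefficients with prescribed values for motif-selection experiments;
    with ``unit_rates`` the rate factors in the expansion are set to one
    (used when the external drive is zero and the rate scale is absorbed
    into the overridden coefficients).
    """

    n: int = 20
    eta: float = 1e-8
    psi: float = 5e4
    mu: float = 0.0
    gamma: float = 225.0
    M: int = 5
    w_max: float = 0.18
    W_max: Optional[float] = None
    b: float = 15.0
    kernel: Optional[SynapticKernel] = None
    stdp: Optional[STDPFunction] = None
    drift_mode: str = "exact"
    truncation_order: int = 3
    coefficient_overrides: Optional[dict] = None
    f0_override: Optional[float] = None
    unit_rates: bool = False
    include_inhibition: bool = True
    slow_terms_scaled_by_eta: bool = True
    step_cap: float = 0.02
    convergence_tol: float = CONVERGENCE_TOL
    convergence_window: int = 10
    max_iters: int = 20000
    duration: float = 3600.0
    dt: float = 2.5e-4
    seed: int = 0
    init_scale: float = 1.0
    checkpoint_interval: Optional[int] = None  # None -> geometric cadence

    def __post_init__(self):
        if self.eta < 0 or self.psi < 0 or self.gamma < 0 or self.mu < 0:
            raise ValueError("eta, psi, mu, gamma must be non-negative")
        if self.W_max is None:
            self.W_max = self.M * self.w_max
        if self.kernel is None:
            self.kernel = make_alpha_kernel(5e-3, 1.0, 0.0)
        if self.stdp is None:
            self.stdp = make_stdp("antisymmetric")

    def motif_table(self) -> MotifCoefficientTable:
        """Coefficient table for truncated mode, honouring overrides."""
        if self.coefficient_overrides is not None:
            coeffs = {}
            for order in range(1, self.truncation_order + 1):
                for alpha in range(order + 1):
                    coeffs[(alpha, order - alpha)] = float(
                        self.coefficient_overrides.get((alpha, order - alpha), 0.0))
            f0 = self.f0_override if self.f0_override is not None else 0.0
            return MotifCoefficientTable(f0=f0, coeffs=coeffs, provenance="frequency_domain")
        table = coefficient_table(self.stdp, self.kernel, self.truncation_order)
        if self.f0_override is not None:
            table = MotifCoefficientTable(f0=self.f0_override, coeffs=table.coeffs,
                                          provenance=table.provenance)
        return table


@dataclass
class Trajectory:
    """Checkpointed history of one plasticity run."""

    times: List[float]
    snapshots: List[np.ndarray]
    scores: List[Optional[float]]
    converged: bool
    final_state: ConnectivityState
    n_iters: int
    aborted: bool = False


def competition_terms(W_ex: np.ndarray, W_max: float) -> Tuple[np.ndarray, np.ndarray]:
    """Heterosynaptic excess of row sums (inputs) and column sums (outputs).

    Din_i = max(sum_k W_ik - W_max, 0) and Dout_j likewise on columns; the
    Heaviside convention theta(0)=1 changes nothing since the excess vanishes
    at equality.
    """
    W_ex = np.asarray(W_ex, dtype=float)
    d_in = np.clip(W_ex.sum(axis=1) - W_max, 0.0, None)
    d_out = np.clip(W_ex.sum(axis=0) - W_max, 0.0, None)
    return d_in, d_out


def _rates_for(config: PlasticityConfig, W_eff: np.ndarray) -> RateVector:
    n = W_eff.shape[0]
    if config.unit_rates:
        return RateVector(r=np.ones(n), b=np.full(n, config.b))
    return stationary_rates(W_eff, np.full(n, config.b))


def _drift(config: PlasticityConfig, state: ConnectivityState,
           table: Optional[MotifCoefficientTable],
           omega_grid) -> DriftMatrix:
    W_eff = effective_connectivity(state, config.include_inhibition)
    rates = _rates_for(config, W_eff)
    if config.drift_mode == "exact":
        return exact_drift(state, config.kernel, config.stdp, rates, W=W_eff,
                           omega_grid=omega_grid)
    if config.drift_mode == "truncated":
        return truncated_drift(state, rates, table, config.truncation_order, W=W_eff)
    raise ValueError(f"unknown drift_mode {config.drift_mode!r}")


def deterministic_step(state: ConnectivityState, config: PlasticityConfig,
                       drift: DriftMatrix) -> Tuple[ConnectivityState, float, float]:
    """One adaptive Euler step of the averaged dynamics.

    Returns (new state, elapsed model time in s, max elementwise change).
    The step size h is chosen so the largest |dW| equals ``step_cap`` (before
    clipping at the bounds).
    """
    if not np.all(np.isfinite(drift.offdiag())):
        raise RuntimeError("non-finite drift; aborting")
    W = state.W_ex
    d_in, d_out = competition_terms(W, config.W_max)
    slow = -config.psi * (d_in[:, None] + d_out[None, :]) - config.mu * W + config.gamma
    slow_scale = config.eta if config.slow_terms_scaled_by_eta else 1.0
    G = config.eta * np.nan_to_num(drift.delta, nan=0.0) + slow_scale * slow  # true dW/dt
    np.fill_diagonal(G, 0.0)
    if state.adjacency_mask is not None:
        G = np.where(state.adjacency_mask, G, 0.0)
    gmax = float(np.max(np.abs(G)))
    if gmax == 0.0:
        return state.copy(), 0.0, 0.0
    h = config.step_cap / gmax  # seconds of model time
    W_new = np.clip(W + h * G, 0.0, config.w_max)
    np.fill_diagonal(W_new, 0.0)
    if state.adjacency_mask is not None:
        W_new = np.where(state.adjacency_mask, W_new, 0.0)
    change = float(np.max(np.abs(W_new - W)))
    new_state = ConnectivityState(W_new, state.w_max, state.adjacency_mask)
    return new_state, h, change


def _should_checkpoint(it: int, interval: Optional[int]) -> bool:
    if interval is not None:
        return it % interval == 0
    return it & (it - 1) == 0  # powers of two -> geometric cadence


def run_deterministic(W0: ConnectivityState, config: PlasticityConfig,
                      score_fn=None) -> Trajectory:
    """Iterate the averaged dynamics until convergence or the iteration cap.

    Convergence: the max elementwise |change| stayed below e^-15 (~3.06e-7)
    over the last ``convergence_window`` iterations.  On instability of the
    linear network the run aborts, returning the last stable snapshot.
    """
    state = W0.copy()
    table = config.motif_table() if config.drift_mode == "truncated" else None
    omega_grid = default_frequency_grid() if config.drift_mode == "exact" else None
    times, snaps, scores = [], [], []
    t = 0.0
    recent: List[float] = []
    converged = False
    aborted = False
    it = 0

    def checkpoint(it):
        times.append(t)
        snaps.append(state.W_ex.copy())
        scores.append(score_fn(state.W_ex) if score_fn is not None else None)

    checkpoint(0)
    for it in range(1, config.max_iters + 1):
        try:
            drift = _drift(config, state, table, omega_grid)
        except InstabilityError:
            aborted = True
            break
        state, dt_step, change = deterministic_step(state, config, drift)
        t += dt_step
        recent.append(change)
        if len(recent) > config.convergence_window:
            recent.pop(0)
        if _should_checkpoint(it, config.checkpoint_interval):
            checkpoint(it)
        if (len(recent) == config.convergence_window
                and max(recent) < config.convergence_tol):
            converged = True
            break
    if times and not np.array_equal(snaps[-1], state.W_ex):
        checkpoint(it)
    return Trajectory(times=times, snapshots=snaps, scores=scores,
                      converged=converged, final_state=state, n_iters=it,
                      aborted=aborted)


# ---------------------------------------------------------------------------
# Stochastic (spiking) plasticity
# ---------------------------------------------------------------------------

@njit(cache=True)
def _stochastic_chunk(W, b_scalar, a0, q1, q2, n_delay, dt, n_steps, inhibition,
                      cp, p1p, p2p, cm, p1m, p2m,
                      eta, psi, mu, gamma, w_max, W_cap,
                      e1, e2, ring, t1, t2, u1, u2, m0):  # pragma: no cover - numba
    n = W.shape[0]
    d1 = np.exp(-q1 * dt)
    d2 = np.exp(-q2 * dt)
    fp1 = np.exp(-p1p * dt)
    fp2 = np.exp(-p2p * dt)
    fm1 = np.exp(-p1m * dt)
    fm2 = np.exp(-p2m * dt)
    L = ring.shape[0]
    filt = np.zeros(n)
    spk = np.zeros(n, dtype=np.uint8)
    row = np.zeros(n)
    col = np.zeros(n)
    for mm in range(n_steps):
        m = m0 + mm
        for k in range(n):
            e1[k] *= d1
            e2[k] *= d2
            t1[k] *= fp1
            t2[k] *= fp2
            u1[k] *= fm1
            u2[k] *= fm2
        if n_delay > 0:
            slot = m % L
            for k in range(n):
                if ring[slot, k]:
                    e1[k] += 1.0
                    e2[k] += 1.0
                ring[slot, k] = 0
        mean_filt = 0.0
        for k in range(n):
            filt[k] = a0 * (e1[k] - e2[k])
            mean_filt += filt[k]
        mean_filt /= n
        for i in range(n):
            lam = b_scalar
            rsum = 0.0
            for k in range(n):
                lam += W[i, k] * filt[k]
                rsum += W[i, k]
            if inhibition:
                lam -= rsum * mean_filt
            if lam < 0.0:
                lam = 0.0
            p = lam * dt
            if p > 1.0:
                p = 1.0
            spk[i] = 1 if np.random.random() < p else 0
        # pair-based STDP increments from this step's spikes
        for i in range(n):
            if spk[i]:
                for j in range(n):
                    if j != i:
                        W[i, j] += eta * cp * (t1[j] - t2[j])
                        W[j, i] += eta * cm * (u1[j] - u2[j])
        # slow terms applied every step, scaled by dt
        for i in range(n):
            row[i] = 0.0
            col[i] = 0.0
        for i in range(n):
            for j in range(n):
                row[i] += W[i, j]
                col[j] += W[i, j]
        for i in range(n):
            row[i] = row[i] - W_cap if row[i] > W_cap else 0.0
            col[i] = col[i] - W_cap if col[i] > W_cap else 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    w = W[i, j] + dt * eta * (-psi * (row[i] + col[j]) - mu * W[i, j] + gamma)
                    if w < 0.0:
                        w = 0.0
                    elif w > w_max:
                        w = w_max
                    W[i, j] = w
        # insert this step's spikes into the delay line / traces
        for i in range(n):
            if spk[i]:
                if n_delay > 0:
                    ring[(m + n_delay) % L, i] = 1
                else:
                    e1[i] += 1.0
                    e2[i] += 1.0
                t1[i] += 1.0
                t2[i] += 1.0
                u1[i] += 1.0
                u2[i] += 1.0


@njit(cache=True)
def _stochastic_chunk_windowed(W, b_scalar, a0, q1, q2, n_delay, dt, n_steps,
                               inhibition, f_lags, n_win,
                               eta, psi, mu, gamma, w_max, W_cap,
                               e1, e2, ring, spike_hist, m0):  # pragma: no cover
    n = W.shape[0]
    d1 = np.exp(-q1 * dt)
    d2 = np.exp(-q2 * dt)
    L = ring.shape[0]
    Lh = spike_hist.shape[0]
    filt = np.zeros(n)
    spk = np.zeros(n, dtype=np.uint8)
    row = np.zeros(n)
    col = np.zeros(n)
    f0_lag = f_lags[n_win]
    for mm in range(n_steps):
        m = m0 + mm
        for k in range(n):
            e1[k] *= d1
            e2[k] *= d2
        if n_delay > 0:
            slot = m % L
            for k in range(n):
                if ring[slot, k]:
                    e1[k] += 1.0
                    e2[k] += 1.0
                ring[slot, k] = 0
        mean_filt = 0.0
        for k in range(n):
            filt[k] = a0 * (e1[k] - e2[k])
            mean_filt += filt[k]
        mean_filt /= n
        for i in range(n):
            lam = b_scalar
            rsum = 0.0
            for k in range(n):
                lam += W[i, k] * filt[k]
                rsum += W[i, k]
            if inhibition:
                lam -= rsum * mean_filt
            if lam < 0.0:
                lam = 0.0
            p = lam * dt
            if p > 1.0:
                p = 1.0
            spk[i] = 1 if np.random.random() < p else 0
        # pair sums against the spike history within the window
        for i in range(n):
            if spk[i]:
                for lag in range(1, n_win + 1):
                    if lag > m:
                        break
                    slot_h = (m - lag) % Lh
                    for j in range(n):
                        if spike_hist[slot_h, j] and j != i:
                            W[i, j] += eta * f_lags[n_win + lag]
                            W[j, i] += eta * f_lags[n_win - lag]
        # simultaneous pairs (tau = 0)
        if f0_lag != 0.0:
            for i in range(n):
                if spk[i]:
                    for j in range(n):
                        if spk[j] and j != i:
                            W[i, j] += eta * f0_lag
        for i in range(n):
            row[i] = 0.0
            col[i] = 0.0
        for i in range(n):
            for j in range(n):
                row[i] += W[i, j]
                col[j] += W[i, j]
        for i in range(n):
            row[i] = row[i] - W_cap if row[i] > W_cap else 0.0
            col[i] = col[i] - W_cap if col[i] > W_cap else 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    w = W[i, j] + dt * eta * (-psi * (row[i] + col[j]) - mu * W[i, j] + gamma)
                    if w < 0.0:
                        w = 0.0
                    elif w > w_max:
                        w = w_max
                    W[i, j] = w
        slot_now = m % Lh
        for i in range(n):
            spike_hist[slot_now, i] = spk[i]
            if spk[i]:
                if n_delay > 0:
                    ring[(m + n_delay) % L, i] = 1
                else:
                    e1[i] += 1.0
                    e2[i] += 1.0


@njit(cache=True)
def _seed_numba(seed):  # pragma: no cover - numba
    np.random.seed(seed)


def run_stochastic(W0: ConnectivityState, config: PlasticityConfig,
                   score_fn=None, checkpoint_every: float = 60.0) -> Trajectory:
    """Spiking-network plasticity: STDP applied spike pair by spike pair.

    Each 0.25 ms step draws spikes from the current weights, adds the
    pair-based STDP increments through exponential traces of the window
    branches, and applies the slow terms (competition, self-depression,
    growth, clipping) scaled by dt.  Checkpoints (and optional structure
    scores) are taken every ``checkpoint_every`` seconds of biological time.
    Identical seeds give identical trajectories.
    """
    kernel = config.kernel
    n = W0.n
    W = W0.W_ex.copy()
    dt = config.dt
    n_delay = int(round(kernel.latency_d / dt))
    e1 = np.zeros(n)
    e2 = np.zeros(n)
    ring = np.zeros((n_delay + 1, n), dtype=np.uint8)
    exponential = config.stdp.is_exponential
    if exponential:
        cp, p1p, p2p, cm, p1m, p2m = config.stdp.branch_decomposition()
        t1 = np.zeros(n)
        t2 = np.zeros(n)
        u1 = np.zeros(n)
        u2 = np.zeros(n)
    else:
        # non-exponential window: pair sums over a spike ring buffer spanning
        # the window support (the Mexican-hat support is ~100 ms)
        window = config.stdp.support(1e-9)
        n_win = int(np.ceil(window / dt))
        f_lags = config.stdp(np.arange(-n_win, n_win + 1) * dt)
        spike_hist = np.zeros((n_win + 1, n), dtype=np.uint8)
    _seed_numba(int(config.seed))
    n_steps_total = int(round(config.duration / dt))
    chunk = max(1, int(round(checkpoint_every / dt)))
    times, snaps, scores = [0.0], [W.copy()], []
    scores.append(score_fn(W) if score_fn is not None else None)
    m0 = 0
    while m0 < n_steps_total:
        n_steps = min(chunk, n_steps_total - m0)
        if exponential:
            _stochastic_chunk(W, float(config.b), kernel.a0, kernel.q1, kernel.q2,
                              n_delay, dt, n_steps, config.include_inhibition,
                              cp, p1p, p2p, cm, p1m, p2m,
                              config.eta, config.psi, config.mu, config.gamma,
                              config.w_max, config.W_max,
                              e1, e2, ring, t1, t2, u1, u2, m0)
        else:
            _stochastic_chunk_windowed(W, float(config.b), kernel.a0, kernel.q1,
                                       kernel.q2, n_delay, dt, n_steps,
                                       config.include_inhibition, f_lags, n_win,
                                       config.eta, config.psi, config.mu,
                                       config.gamma, config.w_max, config.W_max,
                                       e1, e2, ring, spike_hist, m0)
        m0 += n_steps
        times.append(m0 * dt)
        snaps.append(W.copy())
        scores.append(score_fn(W) if score_fn is not None else None)
    final = ConnectivityState(W, config.w_max)
    return Trajectory(times=times, snapshots=snaps, scores=scores,
                      converged=False, final_state=final, n_iters=n_steps_total)


def generate_initial_weights(N: int, M: int, w_max: float, scale: float = 1.0,
                             seed: int = 0) -> ConnectivityState:
    """Random initial connectivity: i.i.d. uniform on [0, scale*w_max*M/N].

    The diagonal is zero.  ``scale`` is 1.0 or 1.5 depending on the
    experiment family.
    """
    rng = np.random.default_rng(seed)
    hi = scale * w_max * M / N
    W = rng.uniform(0.0, hi, size=(N, N))
    np.fill_diagonal(W, 0.0)
    return ConnectivityState(W, w_max)
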
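"""Stationary rates and spike cross-correlations of the linear Poisson network.

Each neuron fires as an inhomogeneous Poisson process whose intensity is a
weighted sum of synaptically filtered network spike trains plus a constant
external drive:

    lambda_i(t) = sum_k W_ik (a * S_k)(t) + b_i .

Because the dynamics are linear, the stationary rates and the full matrix of
pairwise spike correlation functions have closed forms.  In the frequency
domain the correlation matrix is

    C~(w) = 2 pi delta(w) r r^T + (I - a~(w) W)^{-1} D (I - a~(-w) W^T)^{-1},

with r the stationary rate vector, D = diag(r), and a~ the kernel transform.
The delta(w) atom (equivalently the constant r_i r_j baseline in the time
domain) and the diagonal Poisson atoms r_i delta(tau) are carried as separate
symbolic fields, never as grid spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kernels import SynapticKernel

__all__ = [
    "ConnectivityState",
    "RateVector",
    "CorrelationSpectrum",
    "Correlogram",
    "InstabilityError",
    "effective_connectivity",
    "stationary_rates",
    "stability_margin",
    "correlation_spectrum",
    "correlation_time",
]


class InstabilityError(RuntimeError):
    """Raised when the linear network is unstable (spectral radius >= 1)."""


@dataclass
class ConnectivityState:
    """Excitatory connectivity with bounds and optional structural mask.

    Invariants: zero diagonal, 0 <= W_ex <= w_max elementwise, and masked
    entries exactly zero.  ``validate`` enforces them.
    """

    W_ex: np.ndarray
    w_max: float
    adjacency_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.W_ex = np.asarray(self.W_ex, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return self.W_ex.shape[0]

    def validate(self):
        W = self.W_ex
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W_ex must be square")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("W_ex must have a zero diagonal (no self-synapses)")
        if np.any(W < 0.0) or np.any(W > self.w_max + 1e-12):
            raise ValueError("W_ex entries must lie in [0, w_max]")
        if self.adjacency_mask is not None:
            mask = np.asarray(self.adjacency_mask, dtype=bool)
            if mask.shape != W.shape:
                raise ValueError("adjacency mask shape mismatch")
            if np.any(W[~mask] != 0.0):
                raise ValueError("entries outside the adjacency mask must be zero")

    def copy(self) -> "ConnectivityState":
        return ConnectivityState(self.W_ex.copy(), self.w_max,
                                 None if self.adjacency_mask is None else self.adjacency_mask.copy())


@dataclass
class RateVector:
    """Stationary mean rates r (Hz) and the external input b that produced them."""

    r: np.ndarray
    b: np.ndarray

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.r)


def effective_connectivity(state: ConnectivityState, include_inhibition: bool = True) -> np.ndarray:
    """Effective connectivity W = W_ex + W_in with balanced global inhibition.

    The inhibitory component is uniform along each row and balances the total
    excitatory input to the neuron:  W_in[i, k] = -(1/N) sum_l W_ex[i, l].
    Every row of the result sums to zero, which pins the stationary rate at b
    for uniform external input.  The inhibitory component may place a nonzero
    (inhibitory) entry on the diagonal; the zero-diagonal rule applies to the
    excitatory synapses only.
    """
    W = state.W_ex
    if not include_inhibition:
        return W.copy()
    row = W.sum(axis=1, keepdims=True)
    return W - row / state.n


def stability_margin(W: np.ndarray) -> float:
    """1 - max |eigenvalue(W)|; positive iff the linear network is stable."""
    W = np.asarray(W, dtype=float)
    if not np.any(W):
        return 1.0
    return 1.0 - float(np.max(np.abs(np.linalg.eigvals(W))))


def stationary_rates(W: np.ndarray, b) -> RateVector:
    """Solve r = (I - W)^{-1} b (the kernel has unit area, a~(0) = 1)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    b = np.broadcast_to(np.asarray(b, dtype=float), (n,)).copy()
    margin = stability_margin(W)
    if margin <= 0.0:
        raise InstabilityError(
            f"network unstable: max |eigenvalue| = {1.0 - margin:.6g} >= 1")
    r = np.linalg.solve(np.eye(n) - W, b)
    return RateVector(r=r, b=b)


@dataclass
class CorrelationSpectrum:
    """Non-singular part of C~(w) on a frequency grid, plus the delta(w) atom.

    ``values[m]`` is (I - a~(w_m) W)^{-1} D (I - a~(-w_m) W^T)^{-1}; the
    2 pi delta(w) r r^T term is carried symbolically as ``rate_outer``.
    """

    omega: np.ndarray
    values: np.ndarray  # (n_omega, N, N) complex
    rate_outer: np.ndarray  # r r^T


def correlation_spectrum(W: np.ndarray, kernel: SynapticKernel, rates: RateVector,
                         omega_grid) -> CorrelationSpectrum:
    """Exact cross-spectral matrices of the network spike trains."""
    W = np.asarray(W, dtype=float)
    omega = np.asarray(omega_grid, dtype=float)
    if stability_margin(W) <= 0.0:
        raise InstabilityError("network unstable; correlation spectrum undefined")
    n = W.shape[0]
    D = rates.D
    at = kernel.fourier(omega)  # a~(w)
    eye = np.eye(n)
    A = eye[None, :, :] - at[:, None, None] * W[None, :, :]
    # (I - a~ W)^{-1} D
    left = np.linalg.solve(A, np.broadcast_to(D, (omega.size, n, n)))
    # right factor: (I - a~(-w) W^T)^{-1} applied from the right:
    # M = left @ inv(I - conj(a~) W^T)  =>  M^T = solve(I - conj(a~) W, left^T)
    B = eye[None, :, :] - np.conj(at)[:, None, None] * W[None, :, :]
    M = np.linalg.solve(B, np.transpose(left, (0, 2, 1))).transpose(0, 2, 1)
    return CorrelationSpectrum(omega=omega, values=M, rate_outer=np.outer(rates.r, rates.r))


@dataclass
class Correlogram:
    """Time-domain correlation matrices C_ij(tau).

    ``values`` holds the smooth part plus the r_i r_j baseline; the Poisson
    self-correlation atoms r_i delta(tau) are carried in ``delta_weight``
    (diagonal matrix of atom weights at tau = 0).
    """

    tau: np.ndarray
    values: np.ndarray  # (N, N, n_tau) real
    delta_weight: np.ndarray  # (N, N), nonzero on the diagonal
    baseline: np.ndarray  # r r^T

    def symmetry_error(self) -> float:
        """max_tau |C_ij(tau) - C_ji(-tau)| over all pairs (time reversal)."""
        rev = self.values[:, :, ::-1]
        if not np.allclose(self.tau, -self.tau[::-1], atol=1e-15):
            raise ValueError("symmetry check requires a symmetric tau grid")
        return float(np.max(np.abs(self.values - np.transpose(rev, (1, 0, 2)))))


def _fft_omega_grid(n_fft: int, dt: float) -> np.ndarray:
    return 2.0 * np.pi * np.fft.fftfreq(n_fft, d=dt)


def correlation_time(W: np.ndarray, kernel: SynapticKernel, rates: RateVector,
                     tau_grid, dt: Optional[float] = None, pad_factor: float = 4.0) -> Correlogram:
    """Inverse-transform the correlation spectrum onto a time grid.

    The flat high-frequency part D of the spectrum (the Poisson atoms) is
    removed before the FFT and reported separately in ``delta_weight``; the
    remaining smooth part decays like a~(w) and transforms cleanly.  The
    requested ``tau_grid`` values are interpolated from the internal FFT grid.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if dt is None:
        dt = min(kernel.tau1 / 50.0, np.min(np.diff(tau_grid)) if tau_grid.size > 1 else kernel.tau1 / 50.0)
    span = max(np.max(np.abs(tau_grid)), kernel.support()) * pad_factor
    n_fft = int(2 ** np.ceil(np.log2(2.0 * span / dt)))
    omega = _fft_omega_grid(n_fft, dt)
    spec = correlation_spectrum(W, kernel, rates, omega)
    n = spec.values.shape[1]
    D = rates.D
    smooth = spec.values - D[None, :, :]
    # C_smooth(tau_m) = (1/2pi) int e^{i w tau} M^(w) dw  ->  ifft * (1/dt)
    ctime = np.fft.ifft(smooth, axis=0) / dt
    tau_fft = np.fft.fftfreq(n_fft, d=1.0 / (n_fft * dt))  # = m*dt, wrapped
    order = np.argsort(tau_fft)
    tau_sorted = tau_fft[order]
    c_sorted = np.real(ctime[order])
    vals = np.empty((n, n, tau_grid.size))
    for i in range(n):
        for j in range(n):
            vals[i, j] = np.interp(tau_grid, tau_sorted, c_sorted[:, i, j])
    vals += spec.rate_outer[:, :, None]
    return Correlogram(tau=tau_grid, values=vals, delta_weight=D.copy(),
                       baseline=spec.rate_outer)
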
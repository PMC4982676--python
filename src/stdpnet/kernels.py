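"""Synaptic-current kernels and STDP window functions.

The post-synaptic current kernel is a difference of exponentials with a rise
saturation,

    a(t) = a0 * exp(-(t-d)/tau1) * (1 - exp(-(t-d)/tau2))   for t > d,
    a(t) = 0                                                 for t < d,

normalized so that the total transferred charge is one (``integral a(t) dt = 1``).
With this normalization a synapse of efficacy W_ij = 1 adds, on average, one
spike to the post-synaptic neuron per pre-synaptic spike.  The latency ``d``
shifts the onset of the current relative to the pre-synaptic spike.

Three parametric families of STDP window F(tau) are provided (tau = t_post -
t_pre): an antisymmetric window (potentiation for causal pairs, equal and
opposite depression for anti-causal pairs), a symmetric "Mexican hat" window,
and an asymmetric-but-not-antisymmetric window with unequal branch time
constants and amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate

__all__ = [
    "SynapticKernel",
    "STDPFunction",
    "make_alpha_kernel",
    "kernel_value",
    "kernel_fourier",
    "make_stdp",
    "stdp_area",
    "stdp_fourier",
]

# Default grid resolution used when functions are tabulated (s).  The kernel
# and window time constants are >= 3 ms, so 0.05 ms resolves them comfortably.
DEFAULT_DT = 5e-5


class InvalidParameterError(ValueError):
    """Raised for non-physical kernel/STDP parameters."""


@dataclass(frozen=True)
class SynapticKernel:
    """Unit-area post-synaptic current time course.

    Parameters
    ----------
    tau1 : decay time constant (s); default in the model is 5 ms.
    tau2 : rise-saturation time constant (s); default 1 s.
    latency_d : synaptic latency d >= 0 (s).
    a0 : normalization (1/s), computed so that the kernel has unit area.
    """

    tau1: float
    tau2: float
    latency_d: float
    a0: float = field(default=0.0)

    # decay rates of the two exponential components
    @property
    def q1(self) -> float:
        return 1.0 / self.tau1

    @property
    def q2(self) -> float:
        return 1.0 / self.tau1 + 1.0 / self.tau2

    def __call__(self, t):
        return kernel_value(self, t)

    def fourier(self, omega):
        return kernel_fourier(self, omega)

    def support(self, tail_mass: float = 1e-6) -> float:
        """Time T past which the kernel mass is below ``tail_mass``.

        Both exponential components decay at least as fast as exp(-t/tau1),
        so the tail mass beyond T is bounded by exp(-(T-d)/tau1).
        """
        return self.latency_d - self.tau1 * np.log(tail_mass / 2.0)

    def sample(self, dt: float = DEFAULT_DT, tail_mass: float = 1e-6):
        """Tabulate the kernel on a uniform grid [0, T]; returns (t, a(t))."""
        t_max = self.support(tail_mass)
        t = np.arange(0.0, t_max + dt, dt)
        return t, kernel_value(self, t)


def make_alpha_kernel(tau1: float, tau2: float, latency_d: float = 0.0) -> SynapticKernel:
    """Construct the unit-area synaptic current kernel.

    The normalization is exact:  integral = a0*(1/q1 - 1/q2)  with
    q1 = 1/tau1 and q2 = 1/tau1 + 1/tau2, hence a0 = q1*q2*tau2.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise InvalidParameterError(f"time constants must be positive, got tau1={tau1}, tau2={tau2}")
    if latency_d < 0:
        raise InvalidParameterError(f"latency must be non-negative, got {latency_d}")
    q1 = 1.0 / tau1
    q2 = q1 + 1.0 / tau2
    a0 = q1 * q2 * tau2
    return SynapticKernel(tau1=tau1, tau2=tau2, latency_d=latency_d, a0=a0)


def kernel_value(kernel: SynapticKernel, t):
    """Evaluate a(t) (vectorized); zero for t < latency."""
    t = np.asarray(t, dtype=float)
    s = t - kernel.latency_d
    with np.errstate(over="ignore"):
        out = kernel.a0 * (np.exp(-kernel.q1 * np.clip(s, 0.0, None))
                           - np.exp(-kernel.q2 * np.clip(s, 0.0, None)))
    out = np.where(s > 0.0, out, 0.0)
    return out if out.ndim else float(out)


def kernel_fourier(kernel: SynapticKernel, omega):
    """Closed-form transform  a~(w) = a0 e^{-iwd} [1/(q1+iw) - 1/(q2+iw)].

    Uses the convention g~(w) = integral e^{-iwt} g(t) dt, so a~(0) = 1.
    """
    omega = np.asarray(omega, dtype=float)
    iw = 1j * omega
    val = kernel.a0 * (1.0 / (kernel.q1 + iw) - 1.0 / (kernel.q2 + iw))
    out = np.exp(-iw * kernel.latency_d) * val
    return out if out.ndim else complex(out)


# ---------------------------------------------------------------------------
# STDP window functions
# ---------------------------------------------------------------------------

_FAMILIES = ("antisymmetric", "mexican_hat", "asymmetric")


@dataclass(frozen=True)
class STDPFunction:
    """An STDP learning window F(tau), tau = t_post - t_pre.

    ``family`` selects the parametric form; ``params`` holds the family
    scalars.  Exponential families expose a branch decomposition
    (amp_plus, rates_plus, amp_minus, rates_minus) used by the trace-based
    spike-pair accumulator.
    """

    family: str
    params: dict

    def __call__(self, t):
        return _stdp_value(self, np.asarray(t, dtype=float))

    def fourier(self, omega):
        return stdp_fourier(self, omega)

    @property
    def is_exponential(self) -> bool:
        return self.family in ("antisymmetric", "asymmetric")

    def branch_decomposition(self):
        """(c_plus, p1p, p2p, c_minus, p1m, p2m) such that

        F(tau) = c_plus *(e^{-p1p tau} - e^{-p2p tau})  for tau > 0
        F(tau) = c_minus*(e^{ p1m tau} - e^{ p2m tau})  for tau < 0
        """
        if not self.is_exponential:
            raise ValueError("no exponential decomposition for family " + self.family)
        p = self.params
        p1p = 1.0 / p["tau1_plus"]
        p2p = p1p + 1.0 / p["tau2"]
        p1m = 1.0 / p["tau1_minus"]
        p2m = p1m + 1.0 / p["tau2"]
        c_plus = p["h0"] * p["A_plus"]
        c_minus = p["h0"] * p["A_minus"]
        return c_plus, p1p, p2p, c_minus, p1m, p2m

    def support(self, tail_mass: float = 1e-6) -> float:
        if self.is_exponential:
            tau = max(self.params["tau1_plus"], self.params["tau1_minus"])
            return -tau * np.log(tail_mass / 2.0)
        sigma = self.params["sigma"]
        # Gaussian envelope exp(-c t^2); solve c T^2 = -log(tail)
        c = 8.0 / (self.params["exp_denom_scale"] * sigma**2)
        return float(np.sqrt(-np.log(tail_mass) / c)) + 4 * sigma

    def scaled(self, factor: float) -> "STDPFunction":
        """Return a copy with overall amplitude scaled by ``factor``."""
        p = dict(self.params)
        if self.is_exponential:
            p["A_plus"] *= factor
            p["A_minus"] *= factor
        else:
            p["A"] *= factor
        return replace(self, params=p)


def _stdp_value(F: STDPFunction, t):
    p = F.params
    if F.is_exponential:
        tp = np.clip(t, 0.0, None)
        tm = np.clip(-t, 0.0, None)
        p1p = 1.0 / p["tau1_plus"]
        p1m = 1.0 / p["tau1_minus"]
        q2 = 1.0 / p["tau2"]
        pos = p["A_plus"] * np.exp(-p1p * tp) * (1.0 - np.exp(-q2 * tp))
        neg = p["A_minus"] * np.exp(-p1m * tm) * (1.0 - np.exp(-q2 * tm))
        out = p["h0"] * np.where(t > 0, pos, np.where(t < 0, neg, 0.0))
    else:
        sigma = p["sigma"]
        poly = 1.0 - t**2 / (p["poly_denom_scale"] * sigma**2)
        out = p["A"] * poly * np.exp(-8.0 * t**2 / (p["exp_denom_scale"] * sigma**2))
    return out if np.ndim(out) else float(out)


def make_stdp(family: str, **params) -> STDPFunction:
    """Construct an STDP window with the model's default parameters.

    antisymmetric : h0=1e4, tau1=3 ms, tau2=2 s, A+=0.8/tau1, A-=-A+
    mexican_hat   : sigma=12 ms, A=5.2e4;
                    F(t) = A (1 - t^2/sigma^2) exp(-8 t^2 / (5 sigma^2)).
                    ``poly_denom_scale`` (default 1) and ``exp_denom_scale``
                    (default 5) switch to the alternative printed readings
                    (2 sigma^2 in the polynomial, 25 sigma^2 in the exponent).
    asymmetric    : tau1+=3 ms, tau1-=4.5 ms, tau2=2 s, A+=0.8/tau1+,
                    A-=-0.525/tau1-; h0 normalized so the window area is 150.
    """
    if family == "antisymmetric":
        tau1 = params.pop("tau1", 3e-3)
        tau2 = params.pop("tau2", 2.0)
        if tau1 <= 0 or tau2 <= 0:
            raise InvalidParameterError("time constants must be positive")
        A_plus = params.pop("A_plus", 0.8 / tau1)
        p = dict(
            h0=params.pop("h0", 1e4),
            tau1_plus=tau1,
            tau1_minus=tau1,
            tau2=tau2,
            A_plus=A_plus,
            A_minus=params.pop("A_minus", -A_plus),
        )
    elif family == "asymmetric":
        tau1p = params.pop("tau1_plus", 3e-3)
        tau1m = params.pop("tau1_minus", 4.5e-3)
        tau2 = params.pop("tau2", 2.0)
        if tau1p <= 0 or tau1m <= 0 or tau2 <= 0:
            raise InvalidParameterError("time constants must be positive")
        p = dict(
            h0=1.0,
            tau1_plus=tau1p,
            tau1_minus=tau1m,
            tau2=tau2,
            A_plus=params.pop("A_plus", 0.8 / tau1p),
            A_minus=params.pop("A_minus", -0.525 / tau1m),
        )
        area = params.pop("area", 150.0)
        if "h0" in params:
            p["h0"] = params.pop("h0")
        else:
            # h0 = area / integral h(t) dt, so that integral F = area exactly
            raw = STDPFunction(family="asymmetric", params=p)
            p["h0"] = area / stdp_fourier(raw, 0.0).real
    elif family == "mexican_hat":
        sigma = params.pop("sigma", 12e-3)
        if sigma <= 0:
            raise InvalidParameterError("sigma must be positive")
        p = dict(
            A=params.pop("A", 5.2e4),
            sigma=sigma,
            poly_denom_scale=params.pop("poly_denom_scale", 1.0),
            exp_denom_scale=params.pop("exp_denom_scale", 5.0),
        )
    else:
        raise InvalidParameterError(f"unknown STDP family {family!r}; expected one of {_FAMILIES}")
    if params:
        raise InvalidParameterError(f"unknown parameters for family {family!r}: {sorted(params)}")
    return STDPFunction(family=family, params=p)


def stdp_area(F: STDPFunction, tail_mass: float = 1e-10) -> float:
    """f0 = integral F(t) dt, by adaptive quadrature over both branches.

    The integration half-range is extended until the result converges (the
    windows decay exponentially or faster, so a few multiples of the support
    suffice).  For the antisymmetric family the result is zero to quadrature
    tolerance.
    """
    T = F.support(tail_mass)
    prev = None
    for mult in (1.0, 2.0, 4.0):
        pos, _ = integrate.quad(lambda t: F(t), 0.0, mult * T, limit=200)
        neg, _ = integrate.quad(lambda t: F(t), -mult * T, 0.0, limit=200)
        total = pos + neg
        if prev is not None and abs(total - prev) <= 1e-10 * (1.0 + abs(total)):
            return total
        prev = total
    return total


def stdp_fourier(F: STDPFunction, omega):
    """Closed-form transform F~(w) = integral e^{-iwt} F(t) dt."""
    omega = np.asarray(omega, dtype=float)
    iw = 1j * omega
    if F.is_exponential:
        c_plus, p1p, p2p, c_minus, p1m, p2m = F.branch_decomposition()
        pos = c_plus * (1.0 / (p1p + iw) - 1.0 / (p2p + iw))
        neg = c_minus * (1.0 / (p1m - iw) - 1.0 / (p2m - iw))
        out = pos + neg
    else:
        p = F.params
        sigma = p["sigma"]
        c = 8.0 / (p["exp_denom_scale"] * sigma**2)
        gt = np.sqrt(np.pi / c) * np.exp(-(omega**2) / (4.0 * c))
        # transform of t^2 e^{-c t^2} is -d^2/dw^2 of gt
        gpp = gt * (omega**2 / (4.0 * c**2) - 1.0 / (2.0 * c))
        out = p["A"] * (gt + gpp / (p["poly_denom_scale"] * sigma**2)) + 0j
    return out if out.ndim else complex(out)
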
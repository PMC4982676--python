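# Methods

This note documents the model, the numerical choices, and the limitations of
`stdpnet`. It is written for a reader who wants to know exactly what the
package computes and why the defaults are what they are.

## Model

**Neurons.** The network is a linear Poisson (Hawkes-type) point process:
neuron *i* fires with instantaneous intensity

    lambda_i(t) = sum_k W_ik (a * S_k)(t) + b_i,

where `S_k` is the spike train of neuron *k*, `b_i` a constant external drive
(Hz), and `a(t)` the post-synaptic current kernel. Linearity is what makes
every correlation quantity exact; it is also the model's main idealization —
there are no thresholds, refractoriness, or conductance effects, and the
intensity can formally go negative (the simulator floors it at zero; see
below).

**Synaptic kernel.** `a(t) = a0 exp(-(t-d)/tau1)(1-exp(-(t-d)/tau2))` for
`t > d`, zero before the latency `d`. Defaults: `tau1 = 5 ms` (decay),
`tau2 = 1 s` (rise saturation), `d = 0`. `a0` is chosen in closed form so the
kernel has unit area; with that normalization a synapse of efficacy 1 adds on
average one spike to the post-synaptic neuron per pre-synaptic spike, which
fixes the meaning of the weight scale. Note that with `tau2 >> tau1` the two
exponential components nearly cancel: the kernel behaves like
`a0 (t/tau2) exp(-t/tau1)` with effective support of a few tens of ms, not
seconds.

**STDP windows.** Three families of `F(tau)` (`tau = t_post - t_pre`):

- *antisymmetric*: `F = h0 h(t)`, `h` a difference of exponentials on each
  side with `tau1 = 3 ms`, saturation constant `2 s`, `A+ = 0.8/tau1`,
  `A- = -A+`, `h0 = 1e4`. Window area f0 = 0.
- *mexican hat* (symmetric): `F = A (1 - t^2/sigma^2) exp(-8 t^2/(5 sigma^2))`,
  `sigma = 12 ms`, `A = 5.2e4`. The printed form of this window is ambiguous
  in two places; both alternative readings (`t^2/(2 sigma^2)` in the
  polynomial, `25 sigma^2` in the exponent) are exposed as constructor options
  (`poly_denom_scale`, `exp_denom_scale`) and the defaults are the readings
  above. f0 > 0.
- *asymmetric* (but not antisymmetric): branch time constants 3 ms / 4.5 ms,
  `A+ = 0.8/tau1+`, `A- = -0.525/tau1-`, and `h0` normalized so the window
  area is exactly 150. The depression amplitude is taken negative: with both
  amplitudes positive the window would be purely potentiating, which
  contradicts its role as an STDP window; the net area remains positive.

All transforms (`a~`, `F~`) are evaluated in closed form and validated against
discrete transforms of the sampled functions in the tests.

## Drift theory

The expected weight change per unit time ("drift") of synapse j→i under
all-to-all pair STDP is the overlap of the window with the pair correlation
function, `Delta_ij = int F(tau) C_ij(tau) dtau`. For the linear model the
correlation spectrum is exact:

    C~(w) = 2 pi delta(w) r r^T + (I - a~(w)W)^{-1} D (I - a~(-w)W^T)^{-1},

with `r = (I - W)^{-1} b`, `D = diag(r)`. The delta atoms (the `r_i r_j`
baseline and the diagonal Poisson atoms) are carried symbolically, never as
grid spikes, so the `f0 r r^T` term of the drift is exact.

**Quadrature.** The drift integral is evaluated on a composite Simpson grid:
a fine panel `|w| <= 2048 rad/s` at step 4 and a coarse panel to
`2e4 rad/s` at step 32 (~2.2k points total). The flat part `D` of the
spectrum is subtracted analytically (it contributes `F(0) D`, diagonal only,
and the diagonal is discarded since self-synapses do not exist), after which
the integrand decays like `w^-5` and the truncated tail is negligible. An
accuracy study against a 4x finer grid gave relative errors ~1e-9; the
independent time-domain oracle (FFT of the spectrum, then direct overlap with
`F`) agrees to better than 1e-4 relative and is kept as a cross-check in the
test suite.

**Fast path.** Per evaluation the resolvents are diagonalized once:
`(I - a~W)^{-1} = V diag(1/(1 - a~ lambda_k)) V^{-1}`, which turns the
frequency integral into a single complex matrix product (O(N^2 n_w) instead
of O(N^3 n_w)). If `V` is ill-conditioned (defective `W`), dense per-frequency
solves are used instead. Both paths are exercised by the oracle test.

**Motif expansion.** Expanding the resolvents in powers of `W` writes the
drift as a sum over structural motifs {alpha, beta} (source neuron reaching
post through alpha synapses and pre through beta), weighted by coefficients
`f_ab = (1/2pi) int F~(-w) a~(w)^a a~(-w)^b dw`, equivalently the overlap of
`F` with the (alpha, beta)-fold kernel convolution `c_ab(t)`. Both routes are
implemented (frequency-domain by default for tables; time-domain sampled at
0.05 ms as the definitional route) and agree to 1e-3 relative, which is
enforced in the acceptance tests for all three window families up to total
order 5. The truncated drift uses `W^0 = I`, so the first-order terms reduce
to the familiar local rules `f10 r_j W_ij + f01 r_i W_ji`.

## Full plasticity dynamics

    dW_ij/dt = eta * ( Delta_STDP_ij - psi (Din_i + Dout_j) - mu W_ij + gamma ),

clipped to `[0, w_max]` elementwise after every step. `Din/Dout` are the
amounts by which row sums (total input) and column sums (total output) exceed
`W_max = M w_max` — heterosynaptic competition; `mu` is self-depression,
`gamma` constant growth. **All terms share the learning-rate scale eta**: the
self-depression rate is `eta*mu` (this is what makes mu = 300b ~ 4.5e3 1/s
comparable to the STDP drift at eta = 1e-8 and gives the hours-scale
convergence the stochastic runs reproduce). A config switch
(`slow_terms_scaled_by_eta=False`) restores the variant with unscaled slow
terms for completeness. The Heaviside convention theta(0)=1 is used in the
competition terms; it is immaterial because the excess is zero at equality.

**Weight-bound convention.** The experiment presets use
`w_max = 0.85/M` or `0.9/M` (so `W_max = M w_max = 0.85` or `0.9`). This is
the only reading consistent with the model's own stability requirement (all
eigenvalues of `W` below one: a saturated group of M inputs then carries a
row sum of 0.85–0.9) and with the unit synaptic gain convention.

**Deterministic integrator.** Adaptive Euler: the step is chosen so the
largest single weight change equals `step_cap` (experiment-dependent, 0.0001 to
0.02). Convergence: the elementwise change stayed below `e^-15 ~ 3.06e-7`
for 10 consecutive iterations. Near the competition constraint the dynamics
are non-smooth and can chatter at the cap scale without formally converging;
structure scores saturate long before, so runs are also bounded by an
iteration cap. The drift is recomputed from the current weights every step,
with effective connectivity `W = W_ex + W_in` (balanced inhibition,
`W_in[i,k] = -(1/N) sum_l W_ex[i,l]`, making every row of `W` sum to zero and
pinning the rates at `b`). Plasticity updates apply to `W_ex` only.

**Stochastic integrator.** Stochastic Euler at `dt = 0.25 ms`: per step each
neuron fires a Bernoulli spike with `p = clip(lambda dt, 0, 1)` (at most one
spike per neuron per step; negative intensities are floored at zero — the
model itself does not say how formally negative rates should be realized).
The filtered history is kept as exact exponential state variables (two decaying
traces per neuron; the latency is a delay line), so no history truncation is
involved. STDP is applied pair by pair through per-neuron exponential traces
of the window branches, in O(total spikes x N); for the Gaussian-type window
a ring buffer of recent spikes over the window support is used instead. The
O(n^2) all-pairs loop is retained as a test oracle at 1e-6 agreement. Slow
terms are applied every step scaled by `dt` (no other update schedule is
specified by the model).

**Motif-selection runs.** The motif-selection experiments prescribe a handful
of coefficients directly instead of deriving them from a window. Their
presets have zero external drive, under which every term of the expansion
carries a factor of zero rate; the package therefore sets the rate factors to
one in these runs (`unit_rates=True`), i.e. the rate scale is absorbed into
the prescribed coefficients. This affects only the artificial-coefficient
presets.

## Structure score

Neurons are clustered by k-means (scikit-learn, squared Euclidean, 10 seeded
restarts) on the concatenation of their input and output weight vectors (2N
dims). For chain scoring, groups are ordered greedily by the largest
group-to-group input, trying every group as the head (a deterministic
strengthening of choosing the head at random — it can only raise the score);
ties break toward the lowest group index. The ordered matrix `A` is compared
to the ideal binary matrix `B`:

    score = 1 - ||A/max(A) - B||_F^2 / ||B||_F^2,   clipped to [0, 1],

maximized over group counts k (default 2..N/2). The normalizer is a
calibration choice: it makes an ideal
chain with equal weights scores exactly 1 and random matrices score near 0
(the empirical-null separation is tested).

**Rings.** Under constant growth every neuron's outputs saturate, so perfect
emergent chains close into rings: a perfect k-group ring scores exactly
`1 - 1/(k-1)` against the open-chain ideal and 1 against the wrapped ideal
(last group feeding the first). The wrap-around block is therefore enabled
when scoring emergent connectivity in the experiment presets, and disabled by
default in the score API and in the explicit ideal-matrix calibration.

## What the generator/presets emulate — and what they do not

Initial connectivities are i.i.d. uniform on `[0, scale * w_max * M/N]`
(scale 1 or 1.5 by experiment family), zero diagonal — unstructured networks
with no input correlations, which is the point of the self-organization
claims. The presets encode N = 20 (24 for one assembly experiment), M = 4–5,
b = 15 Hz (5 Hz for assemblies), psi = 2e3–1e5 1/s, gamma = 0 or 225 1/s,
mu = 0–600b, eta = 2.5e-9–4e-7. None of this emulates biological
heterogeneity: rates, kernels, and windows are identical across neurons and
synapses, structural connectivity is all-to-all (an adjacency mask exists in
the API but no experiment uses it), and inhibition is a single global balance
term rather than interneurons. Passing tests therefore demonstrate the
mechanism — high-order motifs steering self-organization — not a fit to any
recorded data.

## Reduced problem sizes in the test suite

The regime and collapse checks run at sizes chosen for a desk machine:

- emergence regime: 3 random initial conditions per operating point (the
  full-scale sweeps average 10), 1500 exact-drift iterations (structure locks
  in well before; verified by checkpoint traces), comparison points
  (d = 6 ms, mu = 300b) inside vs (d = 0, mu = 0) outside the permissive
  window;
- stochastic/deterministic collapse: learning rates 1e-7 and 2e-7, run to
  `eta*t = 1e-3` (about a seventh of full convergence at `eta*t ~ 7e-3`),
  3 seeds per rate, scored every `eta*t = 2e-4`. The tolerance is two
  combined across-seed standard deviations plus a 0.05 floor for the
  score-estimator granularity (clustering restarts, spike-count noise).
- stochastic drift consistency: one fixed random network, windows of 600 s
  and 3600 s of biological time; the residual variance ratio is checked
  against the expected 1/T scaling within a factor of two.

## Known limitations

- The deterministic integrator's convergence criterion can fail to trigger at
  constraint-chattering fixed points (see above); use the iteration cap and
  the structure score to decide termination in practice.
- `correlation_time` carries a localized ~1% Nyquist-truncation artifact at
  kink points of the correlation function (e.g. tau = 0 for a zero-latency
  kernel); it shrinks with the internal `dt` and does not affect the drift
  integrals (the window vanishes or is smooth there).
- The stochastic engine assumes a scalar external drive shared by all neurons
  (the presets never use anything else); the theory modules accept vectors.
- Exact drift requires a diagonalizable effective connectivity for the fast
  path; defective matrices fall back to dense solves, which are ~N times
  slower.
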
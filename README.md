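# stdpnet

Exact theory and simulation of spike-timing-dependent plasticity (STDP) in
recurrent networks of linear Poisson (Hawkes-type) spiking neurons — and of
the self-organization it drives: wide synfire chains and self-connected cell
assemblies emerging from unstructured random connectivity, with no structured
input.

**Who it is for.** Computational neuroscientists studying how local pair-based
plasticity rules shape global network architecture, and anyone who needs
exact spike cross-correlation functions or STDP drift fields for Hawkes-type
networks.

## The model in brief

Neuron *i* fires as an inhomogeneous Poisson process with intensity
`lambda_i(t) = sum_k W_ik (a * S_k)(t) + b_i`, where `a(t)` is a unit-area
post-synaptic current kernel with latency *d*. Because the dynamics are
linear, the spike correlation spectrum is exact:

    C~(w) = 2*pi*delta(w) r r^T + (I - a~(w)W)^{-1} D (I - a~(-w)W^T)^{-1}

with stationary rates `r = (I - W)^{-1} b` and `D = diag(r)`. For all-to-all
pair STDP with window `F(tau)` the mean drift of each synapse is

    Delta_ij = f0 r_i r_j
             + (1/2pi) int dw F~(-w) [(I - a~(w)W)^{-1} D (I - a~(-w)W^T)^{-1}]_ij

and expanding the resolvents in powers of `W` decomposes it into structural
motifs {alpha, beta} — a source neuron reaching the post-synaptic neuron via
alpha synapses and the pre-synaptic neuron via beta synapses:

    Delta_ij = f0 r_i r_j + sum_{a,b} f_{a,b} * sum_k (W^a)_ik r_k (W^b)_jk .

The motif coefficients `f_{a,b}` are overlap integrals of the STDP window
with kernel convolutions; biophysical parameters (synaptic latency, window
shape) reshape them and thereby select which global structure self-organizes.
The full weight dynamics combine the STDP drift with heterosynaptic
competition (row/column sums capped at `W_max = M*w_max`), self-depression,
constant growth, and hard bounds `[0, w_max]`; a stochastic mode applies STDP
spike pair by spike pair in a 0.25 ms Euler simulation. A clustering-based
chain/assembly score quantifies the emerged structure (1 = perfect).

See `docs/methods.md` for the numerical choices and limitations.

## Worked example

Motif coefficients at 6 ms synaptic latency, then self-organization of a
random 20-neuron network into a synfire chain under the full dynamics:

```python
import numpy as np
from stdpnet import (PlasticityConfig, chain_score, coefficient_table,
                     generate_initial_weights, make_alpha_kernel, make_stdp,
                     run_deterministic)

kernel = make_alpha_kernel(tau1=5e-3, tau2=1.0, latency_d=6e-3)
F = make_stdp("antisymmetric")

table = coefficient_table(F, kernel, max_order=3)
for ab in [(1, 0), (0, 1), (2, 0), (1, 1), (2, 1)]:
    print(f"f_{ab[0]}{ab[1]} = {table.get(*ab):8.2f}")

cfg = PlasticityConfig(n=20, eta=1e-8, psi=5e4, mu=300.0 * 15, gamma=225.0,
                       M=5, w_max=0.9 / 5, b=15.0, kernel=kernel, stdp=F,
                       drift_mode="exact", step_cap=0.02, max_iters=1500)
W0 = generate_initial_weights(20, 5, 0.9 / 5, scale=1.5, seed=0)
print(f"initial score: {chain_score(W0.W_ex, seeds=(0,), wrap_around=True).score:.3f}")
traj = run_deterministic(W0, cfg)
res = chain_score(traj.final_state.W_ex, seeds=(0,), wrap_around=True)
print(f"final score: {res.score:.3f}  groups: {res.best_k}")
```

Output:

```
f_10 =   247.44
f_01 =  -247.44
f_20 =     9.42
f_11 =    -0.00
f_21 =   215.87
initial score: 0.463
final score: 1.000  groups: 4
```

Reading: at 6 ms latency the first-order coefficient f_10 has dropped from
~704 to ~247 while the third-order common-drive coefficient f_21 is nearly
unchanged (~216) — the regime in which the {2,1} motif dominates and the
dynamics converge from a random start (score 0.46) to a perfect wide synfire
chain of four groups of five neurons (score 1.0). The chain closes into a
ring, which the wrapped ideal accounts for.

A command-line interface mirrors the library:

```
stdpnet coeffs --family antisymmetric --latency 0.006 --max-order 3 --out coeffs.txt
stdpnet run-deterministic --config cfg.yaml --seed 0 --out final.txt
stdpnet score --matrix final.txt
stdpnet sweep --figure latency_sweep --n-inits 3 --out sweep.tsv
```

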
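# sptstates

Bayesian inference of diffusive-state mixtures from short single-particle
tracking (SPT) trajectories.

## The problem

Live-cell sptPALM experiments on fast-diffusing proteins produce large
collections of very short trajectories: emitters photobleach within tens
of milliseconds and diffuse out of the thin focal slab within a few
frames, so a typical dataset holds 10³–10⁵ fragments of 2–10
localizations each. Each measured position also carries localization
error whose variance σ²loc is comparable to the diffusive displacement
per frame. Recovering the underlying *distribution of diffusing states* —
how much of the population is chromatin-bound versus freely diffusing,
and at what diffusion coefficients — from such data requires dealing
with three coupled problems:

1. **Short trajectories.** No single trajectory constrains its diffusion
   coefficient well; information must be pooled across thousands.
2. **Localization error.** Measured jumps of a Brownian particle with
   positional noise ("RBME") are correlated: the jump covariance is
   tridiagonal, with variance 2(DΔt + σ²loc) and lag-1 covariance −σ²loc.
3. **Defocalization.** Fast particles leave the focal slab quickly, so
   slow states are overrepresented among observed jumps.

## The methods

**State arrays (SA).** A finite mixture over a fixed dense grid of
candidate states θk = (D, σ²loc) (by default 101 log-spaced D ∈
[10⁻², 10²] μm²s⁻¹ × 36 linear σloc ∈ [0, 0.06] μm), with occupations
τ ~ Dirichlet(α/K, …, α/K). The factorized variational posterior
q(Z)q(τ) is found by iterating

    n_k  = α/K + Σᵢ Lᵢ r_ik
    r_ik = A_ik e^{ψ(n_k)} / Σⱼ A_ij e^{ψ(n_j)}

where A_ik is the RBME likelihood of trajectory i under vertex k, Lᵢ its
jump count and ψ the digamma function. The posterior mean E[τk] =
nk/Σnj is marginalized over σloc and corrected for defocalization by
dividing each state's occupation by its one-frame in-focus fraction

    η(D) = ∫ T(z) (f₀ ∗ g_{2DΔt})(z) dz,

with f₀ uniform on the slab and T the slab transmission function.

**Dirichlet process mixture (DPMM).** A nonparametric mixture over the
1D parameter φ = log[4(DΔt + σ²loc)] using the marginal (gamma)
likelihood log p(X|φ) = −S e^{−φ} − Lφ, sampled by a
Chinese-restaurant-process Gibbs sweep with auxiliary uniform candidates
and Metropolis–Hastings nudges. It requires a separate global estimate
of σ²loc (from the negative covariance of sequential jumps) and degrades
when localization error varies between states — the regime where state
arrays shine.

**Simulator.** A stroboscopic SPT simulator provides ground truth:
particles photoactivate uniformly in a 5 μm sphere, diffuse with
specular reflection (Brownian, two-state switching, or fractional
Brownian motion), photobleach at 14 Hz, and are observed through a
0.7 μm focal slab at 7.48 ms frame intervals, with iid Gaussian
localization error added to each recorded position.

## Worked example

```bash
sptstates simulate --preset three-state --n-trajectories 12800 --seed 1 -o sim
sptstates sa sim.trajectories.csv --units um -o sa_out
```

The first command simulates the standard three-state benchmark
(D = 0.02, 0.5, 5.0 μm²s⁻¹ at 20/30/50% occupation) and prints

```
wrote 12800 trajectories (realized occupations: [0.1992, 0.302, 0.4988])
```

— the realized occupations differ from 20/30/50 because the state of
each simulated particle is a multinomial draw. The second command runs
the state array and prints

```
N=19698 jumps=53915 iterations=500 converged=False
immobile fraction (D < 0.05): 0.2173
mean free diffusion coefficient: 3.1648 um^2/s
```

(`N` counts trajectory segments after splitting into ≤4-jump pieces; the
`converged` flag refers to a strict 10⁻⁸ fixed-point criterion that the
slowly-sharpening EM does not reach — integrated occupations are stable
long before the iteration cap.) The immobile fraction is the corrected
occupation below 0.05 μm²s⁻¹; here it is dominated by the D = 0.02
state. `sa_out.profile.csv` holds the full posterior occupation profile
over the diffusion grid: integrating it over 0–0.08, 0.08–1.5 and
1.5–40 μm²s⁻¹ gives (0.217, 0.312, 0.471), each within ~2 percentage
points of the realized truth above.

The same analyses are available in Python:

```python
from sptstates import StateArray, read_trajectories
ds = read_trajectories("sim.trajectories.csv")
sa = StateArray().fit(ds)
sa.profile_          # defocalization-corrected occupations over D
sa.predict_proba()   # per-trajectory state responsibilities
```

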
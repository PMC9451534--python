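# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `sptstates`. Notation: Δt is the frame interval (s), D a
diffusion coefficient (μm²s⁻¹), σ²loc the per-axis localization-error
variance (μm²), Lᵢ the number of jumps (frame-to-frame displacements) of
trajectory i and Sᵢ its summed squared 2D jump length (μm²).

## Trajectory model and likelihoods

**RBME.** A Brownian particle measured at consecutive frames with iid
mean-zero Gaussian positional error. The per-axis jump vector is
mean-zero Gaussian with tridiagonal covariance Γ: Γii = 2(DΔt + σ²loc),
Γi,i±1 = −σ²loc. The same error enters consecutive jumps with opposite
sign, which is why jumps are non-Markov unless σ²loc = 0, and why the
lag-1 jump covariance provides an estimator of −σ²loc. The 2D density is
the product of the two axis densities, i.e. a 2L-dimensional Gaussian
with covariance diag(Γ, Γ) and normalizer (2π)^L det Γ.

Grid evaluation exploits the tridiagonal structure with an LDLᵀ
recurrence (δ₁ = a, δⱼ = a − b²/δⱼ₋₁ with a the diagonal and −b the
off-diagonal), giving the log-determinant and quadratic forms in O(L)
per vertex, vectorized over all grid vertices and all trajectories of
equal length. Everything is computed in log space and shifted by the
per-row maximum before exponentiation; rows are normalized (the
normalization cancels in all posteriors). Vertices whose covariance is
not positive definite (e.g. a custom grid containing D = σloc = 0)
receive zero likelihood and a warning.

**FBME.** Fractional Brownian motion with localization error. The
increment covariance is S Δt^{2H}(|i−j+1|^{2H} + |i−j−1|^{2H} −
2|i−j|^{2H}) plus the same localization-error terms as RBME. We
parameterize by the *modified* scaling coefficient S̄ = S Δt^{2H−1}, so
the one-frame jump variance is 2S̄Δt regardless of the Hurst parameter;
S̄ is Δt-specific and must be converted back to S for comparisons across
frame intervals. H = 1/2 reduces FBME to RBME exactly. The default FBME
grid is 31 log-spaced S̄ × 19 linear H ∈ (0.05, 0.95) × 13 linear σloc;
the H and S̄ ranges are our choice (the method fixes only that
0 < H < 1).

**Marginal (gamma) likelihood.** Dropping the off-diagonal
(localization-error) terms of Γ makes the jumps iid, and the likelihood
depends on the data only through (Sᵢ, Lᵢ):
log p(X|φ) ∝ −Sᵢe^{−φ} − Lᵢφ with φ = log[4(DΔt + σ²loc)]. This is the
1D parameterization used by the DPMM.

## State arrays

The state array replaces model selection over the number of states with
a fixed dense grid of K candidate states and a sparsity-inducing
Dirichlet prior τ ~ Dir(α/K, …, α/K). Variational inference alternates
the two closed-form updates given in the package docstrings; the
contribution of each trajectory to the occupation update is weighted by
its jump count, which treats jumps rather than trajectories as the unit
of evidence and makes the estimate robust to trajectory fragmentation.
Because the grid is fixed, the N×K likelihood matrix is computed once
and cached for the whole inference.

Numerical/design choices, with rationale:

- **Prior strength.** Default α/K = 0.01 pseudocounts per vertex. The
  posterior mean E[τ] = n/Σn includes the prior mass αK/(α + ΣLᵢ); with
  K ≈ 3600 vertices, a full pseudocount per vertex would contribute
  ~6% of the posterior as a uniform background at typical sample sizes
  (5×10⁴ jumps) and visibly dilute occupations, while 0.01 keeps the
  background under 0.1% yet leaves ψ(n_k) finite at empty vertices.
  Results are insensitive over α/K ∈ [0.1, 2] at the percent level
  (covered by a test).
- **Stopping.** The maximum per-iteration change of E[τ] decays roughly
  like 1/t (measured ≈6×10⁻⁵ at iteration 1000 on the benchmark), so a
  small fixed-point tolerance is not reachable in practice; the default
  budget is max_iter = 500, past the point where range-integrated
  occupations change by <0.1 percentage point. The `converged` flag
  records whether the formal tol = 10⁻⁸ criterion was met and is
  informational.
- **Trajectory segmentation.** Before inference, trajectories are split
  into segments of at most 4 jumps (`split_size`, configurable). Slow
  states produce long trajectories whose responsibilities are nearly
  one-hot, while fast states produce 1–2-jump fragments with diffuse
  responsibilities; without balancing, this asymmetry systematically
  transfers jump mass from fast to slow states (≈3 percentage points on
  the three-state benchmark). Splitting discards only the lag-1
  error correlation across cut points. Measured effect: maximum
  occupation error 3.5 → 2.9 points (seed 1), 3.0 → 2.6 (seed 2).
- **Postprocessing order.** Marginalize σloc first, then apply the
  defocalization correction to the 1D profile; the correction depends
  only on D, so the order is immaterial and fixed for reproducibility.
- **Naive estimate.** The jump-weighted average of row-normalized
  likelihoods (the zero-iteration posterior) serves as a cheap per-cell
  profile; it gets the same postprocessing.

## Dirichlet process mixture

Gibbs sampling over assignments with auxiliary uniform candidates for
new states, plus per-state Metropolis–Hastings nudges φ′ ~ N(φ, ν²)
restricted to [φmin, φmax] with the truncated-proposal correction
Φ((φmax−φ)/ν) − Φ((φmin−φ)/ν) in the acceptance ratio. Existing states
are selected with probability ∝ n_k·p(Xᵢ|φ_k) where n_k counts jumps
already assigned; the existing/new split uses trajectory counts,
(N−1)/(α+N−1) versus α/(α+N−1). New-state candidates are accepted by a
softmax over the m₀ candidates' likelihoods. Empty states are removed
each sweep. The acceptance rule is the standard Metropolis rule (accept
φ′ when u < r, u ~ U(0,1)). Defaults — α = 5, m₀ = 20, ν = 0.1,
n_iter = 2000, burn_in = 500, φ support mapped from D ∈ [10⁻², 10²] at
the dataset's Δt — are our choices, validated by recovery of known
single- and two-state mixtures; all are configurable. The sweep is
compiled with numba; one seeded generator drives every stochastic choice
in algorithm order, so traces are exactly reproducible.

The posterior over D is a jump-weighted histogram of post-burn-in φ
samples converted via D = (e^φ/4 − σ²loc)/Δt with σ²loc estimated from
the mean negative sequential-jump covariance (pooled over trajectories
and both axes); samples implying D below the grid minimum (including
e^φ/4 < σ²loc) are clamped to the slowest vertex and counted. This
single-global-σ²loc shortcut is the DPMM's structural weakness: when
error varies between states, its error distribution is misattributed to
diffusion, which the class-3 benchmark quantifies.

## Defocalization correction

The fraction of a state's particles remaining in the focal slab after
one frame, η(D), is computed by propagating a unit-mass uniform axial
profile through one convolution–transmission step on a regular grid.
Grid spacing is min(Δz/200, σ_z/8) with σ_z = √(2DΔt), chosen so the
slab half-depth is an integer number of cells: slab edges then fall on
cell boundaries and the quadrature is second order (validated against
an erf-form quadrature oracle to ~10⁻⁵ and against Monte Carlo within
3 standard deviations on random parameter triples). For σ_z < 10⁻⁴ Δz
the mass loss is below ~10⁻⁴ and η is taken as 1. Occupations are
corrected as τ′_k ∝ τ_k/η_k and renormalized; a corrected profile
refuses re-correction. Multi-frame η (n iterated steps) is available
for diagnostics; the correction applied to posteriors always uses
n = 1, matching the one-frame observation bias on jumps. FBME states
are corrected using D_eff = S̄, since the first increment is Gaussian
with variance 2S̄Δt — an approximation for the multi-frame geometry of
fBm paths.

## Simulator

The generator emulates the observation process of sptPALM: uniform
photoactivation in a sphere (radius 5 μm), Euler–Maruyama diffusion with
specular reflection at the boundary (10 substeps per frame so
reflections are resolved; the radial overshoot is reflected about the
surface, iterated until inside), exponential photobleaching (14 Hz),
and detection only on frames whose true axial position lies within the
0.7 μm slab bisecting the sphere. Contiguous in-slab frame runs become
separate trajectories (gapless tracking); runs with a single detection
are excluded from inference but counted. Localization error is added as
iid Gaussian noise per recorded position, per state. Particle states
are multinomial draws from the nominal occupations; the realized
fractions are returned as the ground truth, as they are what a finite
experiment actually contains. Two-state switching uses a symmetric
Markov chain discretized at 100 subframes per frame. FBM paths are
sampled exactly (Cholesky for short paths, circulant embedding for
long) and observed through the slab *without* boundary reflection —
specular reflection is not defined for a non-Markov process; the slab
sits 4.65 μm from the sphere wall, so the approximation is mild.

Default conditions (sphere, slab, Δt = 7.48 ms, 14 Hz bleaching,
12,800 trajectories per replicate, σloc = 0.035 μm unless a benchmark
varies it per state) reproduce the fragmentation regime the method
targets: the mean transit length, counting single-detection passes, is
3.6 frames for the three-state benchmark. Counting only trajectories
with ≥1 jump (the inference input), the mean is ≈5 frames.

What the simulator does **not** emulate: camera noise, motion blur,
defocus-dependent per-emitter localization error, detection and linking
errors, or gap closing. Tests passing on simulated data therefore show
correctness of the inference given the RBME/FBME observation model, not
robustness to tracking artifacts.

## Benchmarks and problem sizes

The standard benchmarks (in `sptstates.benchmarks`) use the three-state
mixture D = (0.02, 0.5, 5.0) μm²s⁻¹ at occupations (0.2, 0.3, 0.5) with
12,800 trajectories per replicate. Occupations are scored by
integrating the corrected posterior over (0–0.08, 0.08–1.5, 1.5–40)
μm²s⁻¹ against the realized truth. The state-dependent-error ("class
3") variant assigns σloc = (0.02, 0.06, 0.04) μm per state — placing
the middle state near DΔt ≈ σ²loc, the hardest regime for the marginal
likelihood — and scores the RMSD between estimated and true occupation
CDFs over the diffusion grid. The acceptance script runs 5 seeds of the
former and 2 replicates of the latter; the test suite mirrors these at
the same sample sizes.

## Known limitations

- Neither SA nor DPMM models state transitions. Two-state switching
  with mean dwell ≫ Δt leaves both modes resolved; dwell ≪ Δt collapses
  them into a single intermediate mode (covered by a test). Dwell times
  within ~an order of magnitude of Δt produce intermediate artifacts.
- The grid bounds the inferable range: states slower than 10⁻² μm²s⁻¹
  pile up at the slowest vertex (by design; the immobile fraction
  aggregates them), faster than 10² at the fastest.
- Credible intervals from q(τ) are available
  (`StateArrayPosterior.occupation_variance`) but underestimate
  uncertainty, as variational factorizations do.
- The defocalization model assumes an ideal slab transmission function;
  Gaussian detection profiles would require extending the enum.
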
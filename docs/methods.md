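# Methods

## The model

Glioblastoma cells appear to divide only while stationary and to migrate
only while not dividing ("go or grow").  `gogrow` models a population of
such cells on a d-dimensional cubic lattice (d ∈ {1,2,3}) with at most one
cell per site.  Each cell is proliferative (P) or migratory (M) and evolves
as an independent continuous-time Markov process with five rates, all per
cell cycle (~24 h):

| rate | event | default |
|------|-------|---------|
| α    | P-cell divides; daughter placed uniformly in an empty von Neumann neighbour site; fails if fully enclosed | 1 (defines the time unit) |
| ν    | M-cell attempts a jump in a uniformly chosen axis direction; wasted if the target is occupied or off-lattice | 5 (≈ 5 cell diameters/cycle burst motility, inside the experimentally observed range for glioma cells) |
| μ    | apoptosis, either phenotype; the cell is removed instantly | 0.01 (death slow compared to division) |
| k_p  | switching M → P | varied |
| k_m  | switching P → M | varied |

Lengths are in cell diameters (lattice spacing a = 1).  Switching faster
than roughly once per hour has not been observed, so `validate` warns (but
does not fail) for k_p or k_m above 24 per cycle, and the switching-rate
optimisation searches inside (0, 24].

The whole lattice is a Markov chain on 3^(L^d) configurations.  Three
computational layers treat it at increasing levels of approximation:

1. **Exact simulation** (`gogrow.ib`): the Gillespie algorithm over the
   per-cell propensities.  Because rates are per-cell constants, blocked
   jumps and fully-enclosed divisions consume their event without effect and
   the total propensity is always n_P(μ+k_m+α) + n_M(μ+k_p+ν).  For L = 3 in
   1-D the chain is small enough to treat exactly by matrix exponential
   (`gogrow.ctmc`), which is the simulator's strongest correctness oracle:
   every event rule enters the generator, and the ensemble frequency of each
   of the 27 configurations is compared against the exact distribution.

2. **Master equations** (`gogrow.continuum`): writing p_i, m_i for the
   probabilities of finding a P- resp. M-cell at site i and *assuming
   neighbouring sites independent*,

       dp_i/dt = (α/2)(1−p_i−m_i)(p_{i−1}+p_{i+1}) − (μ+k_m)p_i + k_p m_i
       dm_i/dt = (ν/2)[(1−p_i−m_i)(m_{i−1}+m_{i+1})
                       − m_i((1−p_{i−1}−m_{i−1}) + (1−p_{i+1}−m_{i+1}))]
                 − (μ+k_p)m_i + k_m p_i

   Via the discrete Laplacian Δf_i = f_{i−1} − 2f_i + f_{i+1} the p-equation
   is density-modulated diffusion plus logistic growth, and the m-equation
   the cross-diffusion form typical of two-species exclusion.  These lattice
   equations — not a re-discretised PDE — are what the solver integrates:
   they are the object the stochastic model actually coarse-grains to, and
   division-driven spread has no sensible a → 0 limit at fixed rates.

3. **Wave-speed analysis** (`gogrow.waves`): the PDE approximation (formally
   Δ/a² → ∂²/∂x²) with per-axis diffusion constants D_α = α/(2d),
   D_ν = ν/(2d) admits travelling fronts p(x−ct), m(x−ct).  Linearising the
   travelling-wave ODE system about the healthy state gives a 4-D Jacobian
   whose eigenvalues solve

       F(λ) = (D_α λ² + cλ + (α−μ−k_m))(D_ν λ² + cλ − (μ+k_p)) − k_p k_m = 0.

   For c below the minimal speed some roots are complex (the front would
   spiral into negative occupancies); c* is the smallest c with an all-real
   spectrum.  This is the linear ("pulled") front speed; no pushed-front
   detection is attempted, consistent with the standard marginal-stability
   picture for compactly supported initial data.

## Numerical choices

- **c\* scan**: coarse ascending scan in steps of 0.01, then bisection to a
  width of 10⁻⁶ by default (10⁻⁸ or 10⁻⁹ where closed-form comparisons or
  near-critical fits need it; each extra decade costs ~3 root evaluations).
  Roots come from the companion matrix (`numpy.roots`) plus one Newton
  polishing step; a root is "real" if |Im λ| ≤ 10⁻⁹.  The classification is
  robust because near the defining root coalescence the imaginary part grows
  like √(c*−c): at the bisection resolution it is ~10⁻³, far above
  eigensolver noise.  With ν = 0 the quartic degenerates to a cubic and only
  the finite roots are reported.
- **Invadability**: c* = 0 is returned when the homogeneous linearisation
  [[α−μ−k_m, k_p],[k_m, −(μ+k_p)]] has a non-positive leading eigenvalue
  (μ ≥ μ_c).  The eigenvalue itself is used rather than the determinant
  condition (α−μ−k_m)(μ+k_p) + k_p k_m > 0, which is equivalent except in
  the degenerate μ = k_p = 0 case.
- **μ_c and β**: μ_c is the positive root of the determinant condition,
  μ_c = ½[(α−k_m−k_p) + √((α−k_m−k_p)² + 4αk_p)].  The critical exponent is
  fitted as the log-log slope of c*(μ) at μ = μ_c(1−ε), ε log-spaced over
  10⁻¹..10⁻⁴ (4 points per decade).
- **Time integration**: method of lines with LSODA (stiffness grows with ν),
  rtol 10⁻⁸ / atol 10⁻¹⁰, state interleaved (p₀, m₀, p₁, m₁, …) so the
  Jacobian is banded with bandwidth 3.  Occupancy violations below 10⁻⁹ are
  clipped; anything larger raises.
- **No-flux boundaries**: ghost sites mirrored across the boundary *face*
  (zero-gradient copies, f₋₁ = f₀).  Mirroring across the boundary site
  (f₋₁ = f₁) does not conserve mass for the bilinear exclusion-transport
  terms; the face convention conserves exactly (transport telescopes, so
  d/dt Σ(p+m) equals growth minus death) and matches the closed-boundary
  simulator, where off-lattice attempts simply fail.
- **Front tracking**: the reference point is the outermost downward crossing
  of p+m through 0.5 (configurable), linearly interpolated between sites.
  Speeds are least-squares slopes of x_ref(t); the default window t ∈
  [25, 50] excludes the relaxation transient, and the default domain of 600
  sites keeps the front out of the last 10% of the domain (a truncation
  warning fires otherwise).  Checkpoints are every cell cycle.
- **Event conventions**: jumps use the per-direction "attempt" rule (rate
  ν/(2d) per direction, blocked attempts wasted) — this is exactly what the
  master-equation transport terms count.  Division places the daughter
  uniformly among *empty* neighbours ("empty_only"), failing only when fully
  enclosed; the master equations instead correspond to per-direction
  division attempts.  Both rules are switchable (`move_rule`,
  `division_rule`) for sensitivity checks; the defaults follow the cell-level
  event description, and the difference only matters at high density behind
  the front, not for the front speed.
- **Randomness**: one root seed; replicate streams are spawned with
  `numpy.random.SeedSequence.spawn`, so ensembles are reproducible
  bit-for-bit and replicates are independent.

## Lattice versus continuum asymptotics

The spectral c* belongs to the PDE, while the integrated model is the
lattice master equation.  For the decoupled proliferation-only case the
lattice dispersion relation is c(λ) = (α cosh λ − μ)/λ, whose minimum
(≈ 1.5005 for α = 1, μ = 0.01) exceeds the PDE value 2√(D_α(α−μ)) ≈ 1.407
by about 7%, because the selected decay rate λ* ≈ 1.2 is too steep for the
quadratic (continuum) approximation of cosh.  Finite-time fits approach
these asymptotes slowly from below (the universal ~3/(2λ*t) logarithmic-
front correction): over t ∈ [25, 50] the proliferation-only front measures
≈ 1.47, over t ∈ [150, 200] ≈ 1.494, within 0.5% of the lattice closed
form.  For motile parameter sets λ* is smaller, the discreteness error
shrinks, and the spectral prediction matches the master-equation front to
within a few percent at long times (verified on randomised parameter sets
in the acceptance suite with a t ∈ [200, 400] window on 1000 sites).

Against the stochastic model the analysis carries a second approximation:
site independence.  It fails worst in 1-D and for proliferation-dominated
parameters (exclusion builds correlations that migration would break up); a
1-D proliferation-only tumour advances at speed ≈ α, not 1.48, because only
the edge cell can divide outward.  Comparisons against simulation are
therefore made in 2-D with the per-axis diffusion rescaling (tangential
motion does not advance the front), where agreement at desk scale is ~15%
and improves with k_m and with simulation time.

## Desk-scale study conditions

Everything in the test-suite and the acceptance script is sized for a
single CPU: 600–1000-site 1-D domains; 2-D lattices of 81² (front
comparison at t ≤ 28, 12 replicates) and 21² (mass sweeps); 10⁵ replicates
for the exact-chain comparison (every one of the 27 configuration
frequencies within 3 Monte-Carlo standard errors); 10⁴/3·10³ replicates for
the 1-D/2-D single-cell diffusion checks; a 40×40 log-spaced grid with
Nelder–Mead refinement for the switching optimisation.  Randomised
parameter sets for the analytic-versus-continuum check are drawn once from
the motile-glioma regime (α = 1, ν ∈ [3, 8], μ ∈ [0.005, 0.05], k_p ∈
[0.5, 4], k_m ∈ [1, 8], log-uniform in the switching rates), which is the
regime the independence approximation is built for.

What passing these checks shows: the simulator realises the specified
Markov chain exactly; the master equations are the correct mean-field of
those rules; the spectral speed is the correct front speed of the master
equations.  What they do not show: fidelity to real gliomas.  The model
ignores tissue heterogeneity (grey/white matter), vasculature and
angiogenesis, cell–cell adhesion and pushing, phenotypic heterogeneity
beyond the two states, and any feedback of the microenvironment on the
switching rates; parameters are order-of-magnitude biological, not fitted.

## Known limitations

- The switching-speed surface near its maximum is a very flat ridge
  (c varies by < 10⁻⁶ along it at the baseline), so the *location* of the
  optimal (k_p, k_m) is ill-conditioned even though the optimal ratio
  (min/max ≈ 0.59 at baseline, the ~1:2 trade-off) and the maximal speed are
  stable.
- Constant-speed radial waves do not exist in d ≥ 2 (curvature corrections
  decay like 1/t); 2-D comparisons at t ≤ 28 carry both this and the
  logarithmic front transient, hence the loose 20% band.
- The continuum solver is 1-D only, matching its analytical use; the
  simulator covers d ∈ {1,2,3} but 3-D runs are demonstrations, not
  clinical-scale tumours.
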
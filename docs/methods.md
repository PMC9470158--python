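# Methods

## Model

A clonal life cycle is a fragmentation pattern κ: a partition of m + 1 with
at least two parts (fragmentation is instantaneous and lossless, so the
parts sum to the size at which the group splits).  The state of a population
executing κ is the vector x of group abundances on sizes 1..m, with dynamics

    dx/dt = A x − diag(K x) x.

The projection matrix A has −i·bᵢ − dᵢ on the diagonal (growth out of size i
plus spontaneous death), (i−1)·b_{i−1} on the lower subdiagonal (growth in),
and m·b_m·πᵢ(κ) added to column m (fragmentation births, πᵢ the offspring
count of size i).  The competition kernel K is an arbitrary nonnegative
matrix: group sizes interact through the load vector (K x)ᵢ, a
frequency-dependent death rate.

With r life cycles sharing the habitat, the composite state concatenates the
per-life-cycle vectors padded to the common size n = max m(j); the composite
projection matrix is block diagonal and the composite kernel is the r × r
tiling of K, so only the competition load couples subpopulations.

**Padding convention.**  For a block with m(j) < n, the rows above m(j) keep
their growth/death diagonal and subdiagonal terms except the (m+1, m) entry,
which is zero: growth out of size m feeds fragmentation, never size m + 1.
Any other choice would populate sizes the life cycle can never occupy; with
this convention the above-maturity entries are exactly invariant at zero,
which the tests assert.

**Invasions from rare.**  A resident R at equilibrium x(R)* (solving
A x = diag(K x) x) exerts a fixed competition load on a rare invader I,
whose linearized dynamics is governed by A(I,R) = A(I) − diag(K x(R)*) on
the invader's own sizes 1..m(I).  These matrices are Metzler (nonnegative
off-diagonal), so the spectral bound is a real eigenvalue and the verdict —
invade iff the leading eigenvalue is positive — is independent of the
invader's initial demography.  The self-invasion matrix A(R,R) has a zero
eigenvalue with eigenvector x(R)*; both facts are used as runtime checks.

Special kernels admit closed forms, used both as API and as cross-checks of
the generic machinery:

* killer kernel K₍ᵢⱼ₎ = kⱼ: the load is scalar, the stationary state is the
  leading eigenvector of A scaled so Σ kⱼ xⱼ* equals the growth rate, and
  competition reduces to growth-rate selection;
* victim kernel K₍ᵢⱼ₎ = kᵢ: the stationary total N* equals the leading
  eigenvalue of A·diag(1/k) — the projection matrix with rates bᵢ/kᵢ, dᵢ/kᵢ —
  and selection maximizes carrying capacity.  (A·diag(1/k) and diag(1/k)·A
  are similar, so either form gives the same N*.)
* unicellular resident: its equilibrium is the logistic carrying capacity
  (b₁−d₁)/K₁₁, and the invasion eigenvalue of a multicellular κ(M) equals
  the growth rate of κ(M) under modified death rates
  dᵢ′ = dᵢ + K_{i,1}(b₁−d₁)/K₁₁.  The reverse invasion is the scalar
  b₁ − d₁ − Σᵢ K_{1,i} xᵢ(M)*.

## Parameters

| parameter | meaning | units | default in censuses |
|---|---|---|---|
| bᵢ | per-cell division rate in groups of size i | 1/time | Exp(1) draw |
| dᵢ | spontaneous group death rate | 1/time | 0 |
| K₍ᵢⱼ₎ | competitive death rate of size i per size-j abundance | 1/(time·abundance) | Exp(1) draw |
| extinction threshold | survivor cut on relative abundance | — | 10⁻³ |
| ε (neutrality band) | eigenvalues within ±ε are flagged, not classified | 1/time | 10⁻⁷ |

Death rates default to zero in both randomized censuses.  This is a
deliberate calibration: with dᵢ ~ Exp(1) the large-maturity life cycles used
in the triplet censuses are non-viable on their own in most draws (the
projection matrix's leading eigenvalue is negative), and no treatment of
those draws — exclusion or empty-resident equilibria — reproduces the
published pattern statistics, whereas drawing only b and K does, exactly
(all 64 patterns, hierarchical ≈ 77%, cyclic ≈ 0.015%).  With d = 0 every
life cycle is viable alone, so the censuses lose no draws.  Sampling d is
available via `sample_death_rates=True` for sensitivity analyses; non-viable
residents are then excluded and counted.

## What the generators emulate

`sample_parameters` draws i.i.d. unit-rate exponential division rates and
competition entries — the "random ecology" ensemble over which outcome
frequencies are measured.  `sample_initial_state` draws i.i.d. Exp(1)
abundances for every size a life cycle can pass through (1..m(j)); the
replicates of a parameter set differ only in these initial conditions.  The
ensemble is a theoretical device, not an empirical one: real competition
kernels are expected to be size-structured (larger groups both exert more
pressure and resist it better), rates are correlated across sizes, and real
populations are finite and stochastic.  Passing censuses therefore validate
the model's mathematics, not any particular organism.

## Numerics

* ODE integration: `scipy.integrate.solve_ivp`.  Single-system trajectories
  use LSODA with an analytic Jacobian, rtol 1e-8 / atol 1e-10.  Census
  replicates are integrated in stacked batches with RK45 at rtol 1e-5 /
  atol 1e-10 (classification needs three decades of resolution, not eight).
  Abundances more negative than −1e-12 raise; smaller negatives are clipped.
* Stationary states: integrate-to-convergence (‖dx/dt‖∞ < 1e-9·max(1,‖x‖∞),
  horizon doubling from t = 100 to 1e5) followed by a damped-Newton polish of
  A x = diag(K x) x.
* Census equilibria (fast path): damped Newton started from the scaled
  leading eigenvector of A, batched over draws; accepted only if the
  residual is < 1e-8, the state is nonnegative, and the full Jacobian
  A − diag(Kx) − diag(x)K is locally stable.  Reducible projection matrices
  (life cycles whose smallest offspring exceeds one cell, e.g. 5+3, never
  occupy the smallest sizes) sometimes lead Newton to an unstable boundary
  equilibrium; those draws (≈ 2%) fall back to short batched integrations
  interleaved with polishing.  The batch route is asserted against the
  scalar route in the tests.
* Outcome-census stopping rule: each replicate integrates to a soft horizon
  t = 2500 with early stop on the derivative criterion (< 1e-8·scale), then
  continues only while some life cycle's relative abundance lies in the
  ambiguous band (10⁻⁶, 0.05), up to a hard cap t = 12000.  Rationale: the
  slowest processes are near-neutral exponential decays of losing life
  cycles; a strict global convergence requirement would run a third of all
  parameter sets to the cap and excluding them would bias the frequencies
  toward fast, clear-cut outcomes.  Replicates still ambiguous at the cap
  are classified as they stand and the parameter set is reported in
  `n_unresolved_sets` (about 5% of sets).  Subpopulations below 10⁻⁹ of the
  total are zeroed between chunks, which shortens decay tails; the survivor
  threshold (10⁻³) sits three decades above the clip.
* Survivor rule: the primary cut is relative abundance > 10⁻³.  Sets that
  contain a constrained triplet (notably 1+1 / 2+1 / 1+1+1) can converge onto
  a continuum of neutrally stable coexistence states, and on some manifold
  points a member's share drifts below any fixed cut without the member
  decaying.  The outcome census therefore also counts a sub-threshold member
  (above 10⁻⁸ relative) as surviving when its invasion eigenvalue against
  the final community exceeds −10⁻³ — a persistence test rather than a tuned
  constant: surviving-but-rare members sit within ~10⁻⁵ of zero while
  genuinely extinct ones are at eigenvalues of order −1, five decades away.
* Tie-breaks and degenerate inputs: the all-zero state is a valid degenerate
  equilibrium and is flagged, not raised; non-viable residents return an
  empty flagged equilibrium; invasion eigenvalues within ±1e-7 of zero are
  flagged neutral and excluded from pattern counts (a handful per 40 000
  draws).

## Census design and scale

* Outcome census (`run_multi_lc_study`): all seven life cycles with
  maturity ≤ 3, by default 500 parameter sets × 30 replicates — the desk
  scale at which the four reference frequencies (single ≈ 0.75,
  two-cycle coexistence ≈ 0.12, three-cycle coexistence ≈ 0.044, two-state
  multistability ≈ 0.065) are resolved within three binomial standard
  errors.  Larger runs are a config change (`StudyConfig(n_sets=...,
  n_replicates=...)`).  Parameter sets get independent child seeds from a
  `SeedSequence` spawn, so sets are independent tasks and results are
  reproducible bit-for-bit for a given master seed regardless of execution
  order.
* Triplet censuses (`run_triplet_census`): 40 000 draws for the
  unconstrained triplet 5+3 / 4+4 / 4+2+2 and 20 000 for the constrained
  2+2 / 4+4 / 4+2+2.  The two rarest patterns of each census occur at
  ~10⁻⁴–10⁻⁵ frequency; `ensure_distinct` extends the census in 20 000-draw
  batches (continuing the same RNG stream) until the expected number of
  distinct patterns has been observed, capped at 120 000 draws.

## Design choices where the design was open

* Unordered constraining pairs: the two constraining life cycles of a
  constrained triplet play symmetric roles, so
  `FragmentationPattern.constraining_pairs` returns unordered pairs and
  sub-multiset enumeration deduplicates by value.
* The alternative constraint rule relevant to costly fragmentation (two
  different offspring subsets of equal combined size) is documented but not
  implemented; in the costless model it identifies no additional triplets.
* The pattern code packs the six ordered-pair verdicts lexicographically by
  (invader, resident) — bit k of the code is `invades(ORDERED_PAIRS[k])` —
  so census tables are comparable across runs and platforms.
* Replicate classification treats empty survivor sets as excluded with a
  warning; a parameter set needs at least two surviving replicates to be
  classified.

## Known limitations

* Finite-time censuses misclassify parameter sets whose slowest eigenvalue
  is below ~10⁻³ in magnitude; these surface as the small excess of
  `other_composite` outcomes relative to the reference table.
* No finite-population (demographic-noise) dynamics, no time-varying rates,
  no spatial structure, no fragmentation cost or cell loss.
* Basins of attraction for bistable pairs are probed only through sampled
  initial conditions, not mapped.
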
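# Methods

## Model and estimators

Observations x₁,…,x_n ∈ ℝᵖ are modelled as i.i.d. N(0, Σ) with precision
matrix Ω = Σ⁻¹.  After centering by the sample mean m, the sample
covariance is S = (1/n)Σᵢ(xᵢ−m)(xᵢ−m)ᵀ (maximum-likelihood divisor n).
All estimators minimize the Gaussian loss ℓ(Ω) = −logdet Ω + tr(ΩS) plus a
sparsity term over positive definite matrices:

* **graphical lasso** — λ‖vec(Ω)‖₁ over all p² entries, diagonal included;
* **adaptive lasso** — element-wise weights λ/|ω̃_jk|^γ from a pilot
  Ω̃ = S⁻¹ (γ = 0.5 default);
* **SCAD** — the three-piece folded-concave penalty with shape a = 3.7;
* **DC (cardinality)** — the penalty η(‖vec(Ω)‖₁ − |||vec(Ω)|||_K), an
  exact difference-of-convex rewriting of the budget ‖vec(Ω)‖₀ ≤ K.

## Graphical lasso core

The solver is the classic block coordinate-descent scheme: with working
covariance Σ̂ initialized at S + Λ∘I (diagonal penalized, so
diag(Σ̂) = S_jj + λ_jj stays fixed), each column j solves the lasso

    min_β  ½ βᵀΣ̂₋ⱼβ − βᵀs_j + Σ_k λ_jk|β_k|

by cyclic coordinate descent with soft-thresholding, then
σ_j ← Σ̂₋ⱼβ, ω_jj ← 1/(σ_jj − σ_jᵀβ), ω_j ← −β·ω_jj.  Sweeps are in fixed
ascending column order (deterministic runs) and stop when the squared
Frobenius change of Ω over a full sweep falls below ε.  Zeros are exact
(produced by the soft-threshold, never by rounding), which is what the
edge-recovery metrics read.  The kernels are numba-compiled; a p = 400
problem solves in well under a second.

Numerical choices:

* defaults ε = 1e-4, inner tolerance 1e-6 (max coordinate change),
  max 200 outer sweeps, 1000 inner passes;
* the objective is recorded per sweep but per-sweep monotonicity is *not*
  asserted — this scheme is known not to decrease the objective
  monotonically; the tests instead check the final objective does not
  exceed the initialization's and that the KKT system
  −Ω̂⁻¹ + S + ΛΓ(Ω̂) = 0 holds at 1e-4;
* final symmetrization averages Ω̂ with its transpose only where both
  partners are nonzero and zeroes both otherwise, so tolerance-level
  column asymmetry is removed without destroying exact zeros or support
  symmetry;
* the input needs only S + Λ∘I invertible, not S ≻ 0 — the DC subproblems
  pass shifted matrices S − ηV that may be indefinite, and singular S from
  n < p is acceptable when λ > 0.

An independent proximal-gradient (ISTA with backtracking) solver of the
same objective lives in the test suite; on random instances the two agree
in objective value to ~1e-13.  scikit-learn's graphical lasso is *not* used
as an oracle because it penalizes only off-diagonal entries and thus solves
a different objective.

## DC algorithm

Each outer iteration, at incumbent Ω_t:

1. build the subgradient sign matrix V: unit diagonal always (diagonal
   entries of a PD matrix are nonzero, hence always in the support), then
   the (K−p)/2 largest off-diagonal magnitudes selected in symmetric
   pairs, ties broken by lowest (row, column) index; an odd last slot is
   dropped so V stays symmetric;
2. find η: starting from λ_min(S), repeatedly multiply by α = 0.5 until
   λ_min(S − ηV) > 1e-10 (strict definiteness is not numerically
   testable).  Every smallest-eigenvalue evaluation — including the
   initial λ_min(S), recomputed each outer iteration — increments the
   eigenvalue counter reported in the trace;
3. solve the subproblem with the *same* graphical-lasso code path on input
   S − ηV and scalar penalty η, giving Ω_{t+1};
4. stop when ‖Ω_{t+1} − Ω_t‖²_F < ε = 1e-4.

Initial point Ω₀ = (S + I)⁻¹; caps of 50 outer iterations and 60 η
shrinks.  No projection onto Ω ⪰ δI is performed: positive definiteness
of the converged subproblem solution is a property of the graphical lasso
and is asserted post hoc (λ_min(Ω̂) > 0) rather than enforced.

Because the penalized form relaxes the hard budget, the final support can
exceed K (the trace records the support size of every iterate).  On p = 4,
K = 8 instances the final DC objective never exceeded the exhaustive
support-enumeration maximum-likelihood optimum (gap ≤ 0 on 20 seeds, i.e.
the penalized optimum sits at or below the constrained optimum, as it
must); the regression test allows a 1e-6 solver tolerance.

The requirement λ_min(S) > 0 is real: for n < p the raw S is singular and
the η search fails with a message directing the user to covariance
shrinkage.

## Synthetic benchmarks

* **random graph** — A₂ = (A₁+A₁ᵀ)/2 with standard-normal A₁; exactly
  n_edges uniformly chosen off-diagonal pairs are retained (the rest zeroed
  symmetrically; the diagonal is kept as drawn); a ridge η_rnd·I shifts the
  spectrum so λ_min = 1 exactly, guaranteeing positive definiteness with no
  retry logic.
* **chain graph** — the banded matrix (1 on the diagonal, 0.5 at lag 1,
  0.25 at lag 2); band pairs are zeroed symmetrically until n_edges remain,
  and the zero pattern is redrawn (up to 100 times) if definiteness is
  lost, which the shift trick cannot rule out here.

Data are i.i.d. N(0, (Ω⋆)⁻¹) via a Cholesky factor; all draws flow through
`numpy.random.default_rng(seed)` and are bit-reproducible.  Benchmark
defaults follow the study conditions: 30 true edges, replicate grids over
p ∈ {50,100,200,400} and n ∈ {p/2, p, 2p}, 30 replicates with means and
95% normal-approximation confidence intervals.

**Shrinkage.**  S ← ζD_S + (1−ζ)S with D_S the diagonal of S.  The default
intensity is *estimated* from the data by the analytic diagonal-target
formula ζ* = Σ_{j≠k} Var̂(s_jk) / Σ_{j≠k} s_jk² (clipped to [0,1]) — the
standard shrinkage-estimation approach for this target.  A fixed ζ is
accepted everywhere for users who want one, but the estimate is the
default because it adapts to the n/p regime (ζ* ≈ 0.97 at p=100, n=50;
≈ 0.5 at p=50, n=100) and is required anyway for the DC method whenever
n < p.  Cross-validation re-estimates ζ on each training fold, mirroring
the generation protocol; the held-out fold is scored unshrunk with its own
mean and divisor.

What the generators do *not* emulate: heavy tails, missing data,
dependent observations, scale heterogeneity across variables, and hub- or
scale-free topologies.  Passing benchmarks here shows correct recovery
under exactly-Gaussian, exactly-sparse truths, not performance on real
omics data.

## Model selection and evaluation

Edge metrics are computed over unordered off-diagonal pairs with
exact-zero support reading; F1 = 2TP/(2TP+FP+FN), defined as 0 when
precision + recall = 0.  The K grid is 100 equally spaced values in
[p+2, p²] rounded and deduplicated; the λ grid is 100 equally spaced
values in [0, max_{j≠k}|S_jk|], whose upper end provably empties the
ℓ1 support.  CV ties prefer the sparser model (smaller K, larger λ);
fold assignment is a seeded uniform partition.

## Problem sizes in the shipped checks

The test suite exercises the full iteration-count benchmark (30
replicates per cell, including both p = 400 cells, ~2 minutes total),
solver optimality on 50 random instances with p ≤ 10, the p = 4
enumeration oracle on 20 seeds, edge recovery at (p, n) = (50, 100), and
CV selection at (p, n) = (20, 200) over a 10-point K grid — sizes chosen
so the whole suite runs in about two minutes while still covering every
benchmark regime.  The edge-recovery regression floor is mean F1 ≥ 0.6
over 10 pinned seeds: the measured mean is ≈ 0.63 with the budget at the
true edge count (and ≈ 0.71–0.74 for every estimator under
output-calibrated budgets), so the floor pins current behavior; it is an
implementation regression threshold, not a published value.

## Known limitations

* The hard budget is enforced only through the penalty; the support of the
  returned estimate can exceed (K−p)/2 edges, and K then acts as a
  sparsity dial rather than an exact count.
* η is tied to λ_min(S); heavily shrunk, well-conditioned inputs give
  larger η and sparser, more stable fits, while barely-PD inputs give a
  weak penalty and denser fits.
* The SCAD solver is a 5-round local linear approximation around a plain
  ℓ1 fit, an implementation choice — folded-concave problems have no
  canonical global solver.
* The adaptive-lasso pilot S⁻¹ is ridge-stabilized ((S + 1e-3·I)⁻¹) when
  S is singular; zero pilot entries receive a capped weight of 1e12,
  effectively forbidding those edges.
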
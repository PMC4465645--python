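# Methods

## Model

Given n non-negative values x₁…xₙ describing the importance, weight or
effect of n items, sort them decreasingly and form the effort/yield pairs
Eᵢ = i/n and Yᵢ = Σₖ≤ᵢ x₍ₖ₎ / Σ x₍ₖ₎. The ABC curve interpolates
(0,0), (E₁,Y₁), …, (1,1) and, for non-negative data, is non-decreasing and
concave inside the unit square. Its derivative dABC = dY/dE (profit gain) is
non-increasing; values above 1 mean over-proportional return per unit of
effort. The curve is invariant under scaling of the data (x → c·x leaves
every Yᵢ unchanged) but not under shifts: x → x + c flattens the curve
toward the diagonal, which is why the only standardization the package
offers is division by the standard deviation (`preprocess(...,
unit_variance=True)`); centering is rejected by construction.

ABC curves are dual to Lorenz curves, ABC(p) = 1 − L(1−p), and for a
continuous distribution with quantile function icdf and mean μ,

    ABC(p) = (1/μ) ∫_{1−p}^{1} icdf(u) du,     dABC(p) = icdf(1−p) / μ.

## Set limits

Three characteristic points partition the items:

* Pareto point A: argmin over the curve of the Euclidean distance to (0,1).
  Minimizing the Manhattan distance E + (1 − ABC) instead would land exactly
  on the slope-1 point, leaving set A with no gains strictly above 1; it is
  therefore documented but not used.
* BreakEven point B: the slope-1 crossing of the non-increasing derivative,
  found by bisection (|Δp| < 1e−9). If the gain exceeds 1 everywhere the
  point is placed at effort 1; below 1 everywhere, at effort 0; a gain
  identically 1 (equality-like data) returns the plateau's left endpoint.
  All three cases are flagged degenerate rather than raised.
* SubMarginal point C: argmin of the distance to (Bₓ, 1), searched on
  [Bₓ, 1].

t_AB = min(Aₓ, Bₓ); when Aₓ > Bₓ the points exchange roles (swap rule) and
the SubMarginal anchor becomes max(Aₓ, Bₓ), which preserves t_AB ≤ t_BC and
keeps the profit gain ≥ 1 throughout set A. Membership is decided on ranks:
rank i ≤ ⌊n·t_AB + 1e−9⌋ → A, rank i > ⌊n·t_BC + 1e−9⌋ → C, else B. Rank
thresholds (rather than value thresholds) are the only reading under which
tied values cannot produce overlapping sets and set A always contains the
largest values.

### Optimizer domains: analytic vs empirical curves

For closed-form and quantile-based curves the two distance minimizations run
a deterministic dense-grid scan (step 1e−4) followed by golden-section
refinement on the bracketing interval; no stochastic search is involved. On
the uniform curve ABC(p) = −p² + 2p this places the Pareto point at
p = 0.41025 (root of 2p − 4(1−p)³), the BreakEven point at 0.5 and the
SubMarginal point at 0.61454 (root of 4q³ + 2q − 1 with q = 1−p), so set A
holds 41.0% of items with a limit gain of 1.179 and set C holds 38.5% with a
limit gain of 0.771.

For curves fitted to empirical data the Pareto and SubMarginal candidates
are restricted to the n realizable curve points (Eᵢ, Yᵢ): an effort between
two ranks does not correspond to any selectable subset of items, so the
limit is chosen among the selections that actually exist. For large n the
two conventions coincide to within 1/n; for small n the discrete choice is
what makes the partition well-defined (on the 8-eigenvalue example in the
README it places the SubMarginal point exactly on the 4th eigenvalue,
giving |C| = 4). The BreakEven point remains the continuous slope-1
crossing of the spline derivative in both cases.

## Spline interpolation

The empirical curve uses a monotone, concavity-preserving piecewise-
quadratic interpolant. Knot slopes are the mean of the adjacent secants
(always inside the secant bracket for concave data); each interval is a
single quadratic when that reproduces the interval's yield mass, otherwise
it is split into a quadratic plus a linear sub-piece. The resulting
derivative is continuous, piecewise linear and non-increasing, so
interpolation can never violate the curve properties (unit square,
monotonicity, concavity) that the limit definitions rely on. The one
exception is forced by the data itself: a run of zero values after positive
ones creates a genuine kink where the derivative jumps. Equal values
reproduce the diagonal exactly.

## Theoretical curves

Closed forms: equality p; exponential p − p·ln p (rate-free); Pareto
p^((α−1)/α) for α > 1 (finite mean required); uniform[a, a+b]
((a+b)p − bp²/2)/(a + b/2). Families without an elementary form use exact
tail-expectation identities instead of quadrature, so there is no
integration error: Normal(μ, σ): p + (σ/μ)·φ(z_p) with z_p = Φ⁻¹(1−p);
LogNormal(m, s): Φ(s − z_p) (depends only on s); χ²(k):
SF_{k+2}(PPF_k(1−p)). The Gaussian is supported on the whole line while ABC
curves require x ≥ 0; the curve is computed as-is only when μ ≥ 4σ
(negative mass ≤ 3.2e−5, negligible at the optimizer's 1e−4 grid), and a
parameter error demands truncation otherwise. Pareto calibration inverts
the closed form: α = 1/(1 − ln y / ln e) puts the curve through (e, y); the
Juran 20/80 point gives α = 1.16096 ≈ 1.16.

## Sampling

`generate_sample` draws from numpy's `default_rng` (PCG64), fixed as the
generator so that (family, parameters, n, seed) reproduces bit-identical
vectors across platforms. Gaussian draws are clipped at zero with a warning
counting the clipped values. Synthetic samples emulate i.i.d. draws from the
named families only; real data may carry ties, measurement error,
truncation or dependence that these fixtures do not, so passing tests
demonstrate correctness of the curve/limit machinery, not robustness to
every empirical artifact.

## Defaults and problem sizes

* Optimizer grid 1e−4, golden-section bracket tolerance 1e−9, slope
  tolerance at degeneracy checks 1e−6, rank-threshold guard 1e−9: all
  absolute, on the unit square.
* Curve-invariant assertions run on a 1e−3 grid at tolerance 1e−9.
* Simulated checks use n = 10,000 for distribution-level results (the
  break-even and set fractions stabilize to ±1 point at this size) and
  n = 100,000 for empirical-to-analytic convergence (sup-norm < 0.01);
  these sizes make every check run in seconds.

## Known limitations

* For n < 3 no curve is fitted (interpolation undefined); callers get the
  discrete points only.
* Equality-like data has no meaningful partition (gain ≡ 1 everywhere); the
  result is flagged degenerate and the boundary conventions above apply.
* Weighted items are out of scope: every item contributes effort 1/n.
* The exact A/B split on very small inputs depends on the BreakEven
  location on the interpolated curve between ranks; the A∪B boundary
  (t_BC), which drives retention decisions, sits on a realizable rank by
  construction.
* Published reference values for the uniform set-C fraction/limit gain and
  the chi-squared set-A fraction are rounded inconsistently with the exact
  optima of the defining objectives; the package reports the exact computed
  values (38.55%, 0.771, ~28%) — see the acceptance test notes.
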
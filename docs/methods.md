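# Methods

## The question being simulated

A hypothesis test is *valid* at level α if it rejects a true null
hypothesis with probability at most α.  When the test is not applied to
the sensitive data itself but to a differentially private synthetic
version of it, the synthesis mechanism interposes a random transformation
between the data and the test, and validity is no longer guaranteed: the
noise that protects privacy can itself create systematic group
differences (inflating Type I error) or erase real ones (inflating Type
II error).  The package measures both effects by Monte-Carlo simulation
on generators whose ground truth is known exactly.

## Privacy model

All mechanisms satisfy (ε, δ)-differential privacy under *replace-one*
adjacency: datasets are neighbors when they differ in exactly one row.
Under this adjacency a histogram of fixed total has L1 sensitivity 2 (one
record leaves a cell and enters another), which is why the perturbed
histogram uses discrete-Laplace noise at scale 2/ε, and an indicator
counting query has sensitivity 1.  Testing synthetic data is
post-processing, so whatever is computed from a released synthetic
dataset inherits its budget unchanged.

## Mechanisms

**Discrete Laplace sampler.**  P(k) ∝ exp(−|k|/b) on the integers,
implemented exactly as the difference of two i.i.d. geometric variables
with success probability 1 − e^(−1/b).  No continuous rounding is
involved, so noisy counts are integers by construction and the only
post-processing is clipping negatives to zero.

**Perturbed histogram.**  Independent discrete-Laplace noise at scale 2/ε
on each of the 2 × n_bins counts; negatives clipped; records emitted at
bin centers.  The synthetic size is the sum of clipped noisy counts, so
it is only approximately the original size — and for sparse histograms
the clipping asymmetry biases the size upward.  This mechanism keeps per-
cell structure, which is exactly why at small ε its noise manufactures
spurious group differences.

**Smoothed histogram.**  m records drawn i.i.d. from p_i ∝ c_i + 2m/ε
over all (group, bin) cells.  The additive pseudo-count 2m/ε is the
privacy mechanism; as m grows or ε shrinks the distribution flattens
toward uniform over the *joint* domain, so both synthetic groups approach
the same distribution regardless of the data.  That is why the method is
valid at every budget (an exchangeable null is approached from any
input), and also why it loses power first among the methods.  The
intended regime is m ≪ n; the implementation warns (but does not refuse)
when m > n/10.

**MWEM.**  Starting from the uniform distribution A over domain cells,
each of T iterations (i) selects a workload query by the exponential
mechanism with utility |q(D) − q(n·A)| and budget ε/(2T), (ii) measures
the selected query with Laplace noise at scale 2T/ε, and (iii) fits A to
the measurement trace by iterating the multiplicative-weights update
A(x) ← A(x)·exp(q(x)(m_t − q(n·A))/(2n)) with renormalization.  The
update loop is pure post-processing; the data are touched once per
iteration by each budget half.  Defaults are T = 30 iterations with 20
update sweeps per iteration, the default hyperparameters of the dominant
open-source MWEM implementation; both are configurable.  The sweep loop
matters scientifically: it makes the synthetic distribution actually fit
the noisy measurements — noise included — which is the mechanism behind
MWEM's Type I inflation even at weak privacy (ε = 10).  A variant that
applies only one update per measurement barely moves the uniform initial
distribution at these budgets and, misleadingly, looks valid.

The default workload contains every one-way and two-way marginal
indicator query of the domain.  For the bivariate Gaussian problem that
is the 2-cell group marginal, the 100-cell bin marginal, and the 200
joint cells.

## The DP Mann–Whitney U test

The baseline for achievable power *without* synthetic data.  With budget
split f = 0.65:

1. ε₁ = f·ε and δ privatize the smaller group size with a single Laplace
   release ñ_raw = n_small + Laplace(1/ε₁), from which two post-processed
   quantities are derived: a conservative bound
   ñ_sens = ⌈ñ_raw + ln(1/(2δ))/ε₁⌉ whose offset makes
   P(ñ_sens < n_small) ≤ δ, and an unbiased rounded estimate
   ñ_ref = round(ñ_raw); both are clamped to [1, n − 1].
2. ε₂ = (1 − f)·ε adds Laplace(ñ_sens/ε₂) noise to
   U = #{x_i < y_j} + ½·#{x_i = y_j} computed between the smaller and the
   larger group (one replaced record shifts U by at most the smaller
   group size, which ñ_sens bounds except with probability δ).  The total
   size is treated as public.
3. The p-value is Monte-Carlo: the reference distribution draws U on
   uniformly random splits of ranks 1..n into groups of sizes ñ_ref and
   n − ñ_ref, each plus fresh Laplace(ñ_sens/ε₂) noise; the two-sided
   p-value is 2·min(lower, upper tail) with the add-one correction
   (r+1)/(reps+1), capped at 1.  Add-one Monte-Carlo p-values are
   super-uniform under the null, so the test is valid by construction.
   The split of roles matters: using the *offset* estimate for the
   reference group sizes would shift the reference mean n₁n₂/2 away from
   the truth whenever the offset is comparable to the group size
   (small n or small ε), measurably inflating Type I error at n = 100,
   while the unbiased estimate keeps the reference centered; the offset
   estimate is still the right choice for the noise scale, where only an
   upper bound preserves the privacy guarantee, and overestimating the
   scale merely widens both the noise and the reference (conservative).

Reference distributions are cached by (n₁, n₂, scale, reps); the default
2,000 reference draws bound the attainable two-sided p-value resolution
at 2/2001 ≈ 0.001.

## Non-private tests and feasibility

scipy supplies the distributional machinery.  The MW U test uses the
asymptotic normal approximation with tie and continuity corrections at
*all* sample sizes — no exact-method switching — trading small-sample
exactness for uniformity of behavior across the grid; full enumeration
shows the approximation is within 0.0375 of the exact permutation
p-value at 3v3 and within 0.02 from five per group.  The t-test is the
classic pooled-variance form (a Welch flag exists).  The median test
counts ties as "not above" the grand median and applies the
Yates-corrected chi-squared to the resulting 2×2 table; Yates correction
is also the default for the chi-squared test proper.  The corrected
tests are conservative (they reject *less* often than α under the null);
the calibration tests assert two-sided agreement with α only for the
rank and t tests and an upper bound for the corrected ones.

Every test returns a result object with a feasibility flag instead of
raising on degenerate input (empty group, all values tied, zero table
marginal, groups of size < 2 for the t-test), because DP synthesizers
produce such samples routinely at small ε.  Rejection uses strict
inequality p < α, which is also the natural rule for add-one Monte-Carlo
p-values.

## Data generators

**Gaussian two-group.**  Null: both groups N(50, 2).  Signal: N(51, 1)
vs N(50, 1), i.e. an effect of exactly one population SD.  Group sizes
split round-half-up at ratio 0.5.  For histogram methods the values are
discretized to 100 unit-width bins labeled 1..100 (edges 0.5–100.5, both
tails clipped into the edge bins); at μ = 50 and σ ≤ 2 clipping is a
~10⁻¹⁰⁰ tail event, so the discretization is effectively lossless apart
from rounding to bin centers.

**Gaussian copula patients.**  Five latent standard normals with a fixed
correlation matrix (moderate positive PSA–PIRADS, age–volume, PSA–volume
links of 0.2–0.4) are pushed through marginal transforms: age =
65 + 7·z; PSA = 120·F⁻¹_Beta(1.5, 8)(Φ(z)) (right-skewed, median ≈ 18);
volume = 200·F⁻¹_Beta(2, 6)(Φ(z)); 5-ARI use by thresholding at 20%
prevalence; PI-RADS 1–5 by thresholding at probabilities
(.15, .20, .25, .25, .15).  Signal mode assigns equal class counts and
shifts the high-risk class's latent means (+0.8 PSA, +0.6 PI-RADS,
+0.3 age).  Null mode draws every record from the low-risk parameters
and randomly relabels exactly half — the two groups are then
*exchangeable by construction*, which is the ground truth that makes
Type I error measurable without knowing anything else about the
simulator.  All parameters are synthetic stand-ins: they mimic the
statistical *shape* of a clinical prostate dataset (mixed types,
skewness, correlation, a known null), not any real cohort, and carry no
information about real patients.  Consequently the multivariate results
demonstrate mechanism behavior on realistic structure; they do not
predict effect sizes on any particular real dataset.

For marginal-based synthesis the mixed record is flattened to a single
cell grid (default age 20 × PSA 40 × volume 20 × ARI 2 × PIRADS 5 ×
label 2 = 640,000 cells, capped at 10⁶; the bundled analysis uses a
coarser 4,800-cell grid for speed).  Continuous variables decode to bin
centers, categoricals to their levels.

## Evaluation harness

One grid cell = (generator, mode, synthesizer, ε, n_original,
n_synthetic, test).  Per repetition: fresh original data → synthesis →
test → rejection at α = 0.05.  Repetition seeds are counter-based
substreams (`SeedSequence(master, spawn_key=(crc32(cell_key), rep))`), so
cells are independent, reproducible, and order-insensitive.  Estimates
are conditioned on feasibility, and a cell is flagged "not reported"
when fewer than 50 repetitions were feasible — the same reporting rule
the study design prescribes.  Smoothed-histogram cells follow their
special design: each repetition draws a fresh n = 20,000 original and a
small synthetic sample; the other synthesizers match the original size.

## Problem sizes used

The bundled analyses and the acceptance benchmarks run at the study's
native sizes where that is cheap (n = 20,000 originals, 1,000
repetitions for the smoothed-histogram and DP-MW validity estimates) and
at reduced scale elsewhere as the package's own choice of defaults: 500
repetitions for the MWEM inflation and perturbed-histogram power-trend
estimates, 200 repetitions and two original sizes in the grid scripts,
100 repetitions and a 4,800-cell domain in the multivariate script.
Three binomial standard errors at 1,000 (500) repetitions correspond to
±0.021 (±0.029) around a true proportion of 0.05, which is the slack all
validity assertions use.

## Numerical choices and edge cases

* Bins are half-open [left, right); the last bin absorbs values at or
  above the upper edge only when overflow clipping is on, and
  out-of-range values with clipping off raise an error naming the value.
  Bin "center" is the arithmetic midpoint of the edges.
* The exponential mechanism subtracts the maximum logit before
  exponentiating; selection ties are broken by the RNG through the
  categorical draw.
* MWEM weights are renormalized after every update; the state object
  enforces non-negativity and unit sum to 1e−12.
* The privatized group size is clamped to [1, n − 1] so the reference
  distribution always has two nonempty groups; the clamp binds only for
  tiny groups at tiny ε.
* All mechanisms consume an explicit `numpy.random.Generator`; identical
  seeds give bit-identical outputs.

## Known limitations

* Only two-group, single-test-per-variable designs; no >2-way marginal
  workloads beyond what the flattened multivariate domain encodes.
* Bin specifications are fixed inputs; no automatic or private bin-width
  selection.
* The copula simulator's parameters are invented; nothing here validates
  them against real prostate-cancer data, and conclusions about *which*
  ε preserves *which* effect transfer to real data only qualitatively.
* The smoothed-histogram validity argument relies on its flattening
  behavior; the package verifies the ε-ratio bound exhaustively only on
  small enumerable domains (2 cells, m ≤ 2), with the general case
  following the same algebra.
* MWEM privacy is argued by budget accounting (selection + measurement
  per iteration), not by outcome enumeration.
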
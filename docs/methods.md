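# Methods

## Model and assumptions

Each of m hypothesis pairs `(H_i1, H_i2)` carries two p-values, assumed
continuous and mutually independent across the whole m×2 table. Null
p-values are standard uniform; non-null p-values have CDF `F` with strictly
decreasing density. The package parameterizes `F` as the one-sided p-value
law of a unit-variance Gaussian statistic with mean shift `snr ≥ 0`:
`F(u) = Φ(snr − Φ⁻¹(1 − u))`. Pairs come in three types — (0,0) both
components true, (0,1)/(1,0) exactly one false, (1,1) both false — with
integer counts `(m0, m1, m2)` stored in `MixtureModel` (never proportions,
so there is no rounding ambiguity).

A union hypothesis `H_i = H_i1 ∪ H_i2` is rejected only when both
components show signal; the two-stage procedure screens on the row minimum
`p̲_i` at threshold c and Bonferroni-tests the row maximum `p̄_i` of the
`|S|` survivors at `α/|S|`.

## Finite-sample machinery

* `cond_cdf_mixed(u, c, F)` and `cond_cdf_doublenull(u, c)` are the exact
  CDFs of `p̄_i` conditional on selection for one-false and both-null pairs.
  Evaluated at the testing threshold, the one-false version is the
  post-selection null level `P0(u, c)`; it can exceed `u` for small c and
  moderate snr, which is the root cause of finite-sample FWER inflation.
* `selection_size_pmf` gives the exact law of `|S(c)|` as the convolution
  of three binomials (one per pair type). The FWER functional
  `fwer_bound(model, c, α) = Σ_{s≥1} P(|S|=s)·(1 − (1 − P0(α/s, c))^s)` is
  evaluated exactly over that law; it is the exact FWER when every pair is
  one-false (π1 = 1) and an upper bound otherwise.
* `conditional_power(s, c, α, F)` is the joint probability that a (1,1)
  pair is selected and its maximum clears `α/s`:
  `2F(c)F(α/s) − F(c)²` when `c·s ≤ α`, else `F(α/s)²`; `s` may be real,
  which the expected-size approximations exploit.
* `power_exact` averages the conditional power over the law of `|S|`. The
  default convention (`focal="shifted"`) sets the pair under test aside and
  decomposes `|S| = 1 + S_rest`, because the rejection event already
  contains that pair's own selection; this is exact under independence and
  agrees with brute-force simulation. The alternative `focal="marginal"`
  reads the formula at the law of the full-table `|S|`; it slightly
  double-counts the focal selection and overestimates power at small m
  (the two agree as m grows — both are implemented and cross-checked in
  the tests).

## Threshold solvers

* `oracle_threshold` solves the constrained problem "maximize approximate
  power subject to approximate FWER ≤ α" by returning the smallest feasible
  threshold on the **principal feasibility branch**: scan 400 log-spaced
  points in `[α/(10m), α]`, locate the largest infeasible point, and bisect
  the crossing to 1e-10. The approximate FWER curve can dip below α again
  at extremely small c (where `E|S| → 0`); that sliver carries negligible
  power, so it is not a meaningful solution of the power maximization and
  is deliberately skipped. When the constraint holds on the whole scan the
  floor is returned with `constraint_binding=False`. `full_output=True`
  adds diagnostics, including whether the approximate power is indeed
  maximal at the returned threshold over the feasible scan points.
* `approx_oracle_threshold` solves `c·E|S(c)| = α` by Brent's method; the
  left side is strictly increasing in c (property-tested), so the root is
  unique. If the root would exceed α the threshold is capped at α with a
  warning — it cannot exceed the testing level.
* The data-dependent **adaptive threshold** replaces `E|S(c)|` by the
  observed `|S(c)|`: `γ = max{c ∈ {α/j, j = m..1} : c·|S(c)| ≤ α}`. The
  grid point `α/j` is feasible iff `|S(α/j)| ≤ j`, i.e. iff the (j+1)-th
  order statistic of `p̲` exceeds `α/j`, which is how both the scalar and
  the vectorized implementations evaluate it; `j = m` is always feasible,
  so γ is well defined. The same construction with budget k (grid points
  capped at 1; any capped point is feasible only when m ≤ k) yields the
  PFER threshold `c_k` with `E(V) ≤ k`.

## Procedure conventions

* Selection uses a closed comparison (`p̲_i ≤ c`); p-values of exactly 0
  or 1 are accepted as input (0 always passes a screen, 1 never rejects).
* An empty selection is not an error: all adjusted p-values are 1 and
  nothing is rejected.
* The adaptive and PFER procedures use one threshold for both stages and
  decide by `p̄_i ≤ γ` (resp. `c_k`). Their reported adjusted p-values
  `min(|S|·p̄_i, 1)` are a reporting convenience only — the rejection
  decision is the threshold comparison, and the adjusted values carry no
  separate guarantee.
* Output rows preserve input order; the report header also lists the sorted
  selected set, the thresholds, and the counts.

## Synthetic-data generator

`screenmin.simulate` draws test statistics `N(0,1)` (true component) or
`N(snr_j, 1)` (false component in column j), converts them by
`p = 1 − Φ(z)`, and assembles tables with the configured `(m0, m1, m2)`
layout. For one-false pairs the false column is randomized per pair and
replicate (seed-controlled). Optional positive dependence uses a
compound-symmetry correlation ρ among the m statistics *within* each
column, columns independent — the reading consistent with two separately
fitted models per candidate; a `joint_cs` variant couples all 2m statistics
for sensitivity analysis. The default benchmark (`replicate_table1`) is the
worst case for the default threshold: m = 200, every pair one-false
(π1 = 1), snr 3.1–3.9, α = 0.05, 20,000 replicates, which resolves FWER to
a Monte-Carlo standard error of about 0.15 percentage points.

The generator emulates independent (or equicorrelated) Gaussian tests with
a common signal size per column. It does not emulate heterogeneous effect
sizes within a column, conservative or discrete p-values, or dependence
*between* the two columns; passing tests therefore demonstrate correctness
under the stated model, not robustness to those departures. Conservative
component p-values would make every procedure conservative in turn.

Under unequal column shifts the oracle solver follows the misspecified
single-snr convention: one user-supplied snr (default: the smaller of the
two shifts) is used for `F`.

## Numerical choices

* `1 − (1 − p)^s` with real s is computed as `−expm1(s·log1p(−p))`.
* Oracle scan: 400 log-spaced points, bisection to 1e-10 (both
  configurable); Brent root to 1e-14.
* Monte-Carlo comparisons in the tests use 3 binomial standard errors; the
  harness processes replicates in chunks of at most 4·10⁶/m tables to keep
  memory flat, and all methods share each chunk (common random numbers).
* Determinism: a `(seed, rep_index)` pair reproduces a single table; a
  `(config, seed)` pair reproduces a whole summary bit-for-bit.

## Known limitations

* All guarantees assume independence of the 2m p-values; under
  equicorrelation the procedures are observed (here and in the harness
  tests) to stay conservative, but the conditional-CDF identities no longer
  hold exactly.
* The oracle threshold optimizes the *approximate* criterion; at large snr
  it can exceed the nominal level slightly (visible in the benchmark as
  oracle FWER a hair above 5%).
* No estimation of `(π0, π1, π2)` or `F` from data is provided; the
  adaptive threshold is the recommended data-dependent choice precisely
  because it needs neither.
* FDR-style two-stage procedures and step-down (Holm) variants are out of
  scope.
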
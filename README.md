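# screenmin

Two-stage multiple testing of **union hypotheses** — with fixed, adaptive,
oracle and PFER-controlling screening thresholds — plus the exact
finite-sample theory behind them and a Monte-Carlo benchmark harness.

## The problem

In high-dimensional mediation screening, replicability analysis and similar
settings, each of m candidate findings is a *pair* of null hypotheses
`H_i = H_i1 ∪ H_i2`: the union null is true if at least one component is
true, and rejecting it asserts both components are false (the candidate is
associated with both exposure and outcome; the finding replicates in both
studies). The maximum of the two component p-values, `p̄_i = max(p_i1, p_i2)`,
is a valid p-value for `H_i`, but applying Bonferroni to all m maxima is
very conservative, because for most pairs both components are null and
`p̄_i` is the maximum of two uniforms.

The two-stage **ScreenMin** procedure recovers power by screening on the
minimum p-value `p̲_i = min(p_i1, p_i2)`:

1. **Screen:** select `S(c) = {i : p̲_i ≤ c}` at a threshold `c`;
2. **Test:** reject `H_i` for `i ∈ S` when `p̄_i ≤ α/|S|`.

Screening changes the null distribution of `p̄_i`, however. Conditional on
selection, the maximum p-value of a true union hypothesis with one false
component has CDF

```
P0(u, c) = u F(u) / D                      for u ≤ c
         = (c F(u) + u F(c) − c F(c)) / D  for u ≥ c,    D = F(c) + c − c F(c)
```

where `F` is the CDF of the non-null p-value (here: one-sided p-value of a
N(snr, 1) Gaussian statistic). `P0(u, c)` can exceed `u`, so for some
thresholds the familywise error rate (FWER) exceeds α in finite samples —
with m = 10 one-false pairs at snr 2 and the default `c = α/m`, the exact
FWER is 0.055 at α = 0.05. This package implements the exact FWER and power
expressions, the **oracle threshold** (smallest c satisfying the FWER
constraint, which maximizes power), its large-m approximation (the root of
`c·E|S(c)| = α`), and the data-dependent **adaptive threshold**

```
γ = max{ c ∈ {α/m, …, α/2, α} : c·|S(c)| ≤ α }
```

used for both screening and testing, which restores finite-sample FWER
control because `P0(c, c) ≤ c` for all c. The same construction with a
budget k instead of α bounds the **per-family error rate** E(V) ≤ k.

## Worked example

The packaged example table holds p-value pairs for 22 circulating
metabolites — candidates for mediating a protective effect of fish intake
on colorectal adenoma risk — the subset of a 149-candidate screen that
passes the adaptive threshold:

```python
>>> import screenmin as sm
>>> table = sm.load_navy_metabolites()
>>> sel = sm.screen(table, c=0.05 / 149)        # default threshold, full family
>>> sel.n_selected
13
>>> decision = sm.screenmin_adjust(table, c=0.05 / 149, alpha=0.05)
>>> decision.n_rejected
0
>>> round(table.pmax[decision.selected].min(), 4)   # best max-p among selected
0.0083
>>> round(sm.pfer_estimate(sel), 5)             # estimated E(false rejections)
0.00436
```

The default threshold 0.05/149 selects 13 metabolites, but the smallest
maximum p-value among them (0.0083, docosahexaenoate/DHA) exceeds the
testing threshold 0.05/13 ≈ 0.0038, so nothing is rejected at the 5% level
— while the estimated number of false positives among the 13 selected is
only 0.004. Under the more lenient per-family error criterion at budget
k = 1 (threshold 0.022 on the full 149-row family), three of the printed
metabolites are rejected.

The procedures are scikit-learn style estimators, so the same analysis is

```python
>>> est = sm.ScreenMin(alpha=0.05, c=0.05 / 149).fit(table)
>>> est.n_selected_, est.n_rejected_
(13, 0)
```

and `AdaptiveScreenMin`, `PferScreenMin` and `MaxPBonferroni` follow the
same pattern. A command-line interface covers the same ground:

```bash
screenmin run --input pvalues.tsv --method adaptive --alpha 0.05 --output out.tsv
screenmin oracle --m1 10 --snr 2 --alpha 0.05
screenmin simulate --config scenario.yaml --reps 1000 --seed 1 --output summary.csv
```

## Theory and simulation

```python
>>> model = sm.MixtureModel(m0=0, m1=10, m2=0, nonnull=sm.GaussianShift(2.0))
>>> round(sm.fwer_bound(model, c=0.005, alpha=0.05), 3)   # exact when pi1 = 1
0.055
>>> round(sm.oracle_threshold(model, alpha=0.05), 4)      # smallest feasible c
0.0113
```

`screenmin.simulate` generates synthetic p-value tables under the Gaussian
mean-shift model (optionally with equicorrelated statistics) and estimates
FWER and power for all procedures on common replicates;
`replicate_table1()` runs the worst-case benchmark (m = 200, every pair
with exactly one false component, snr 3.1–3.9).

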
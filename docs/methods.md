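# Methods

## Model

Each iteration of a simulation represents one experiment in a research
field. A true effect size ES is drawn from a two-component normal mixture
`(1−w_B)·N(0, SD_A) + w_B·N(μ_B, SD_B)` on the standardized
mean-difference (Cohen's *d*) scale; a component with SD = 0 is an exact
point mass, so the dichotomous world is a degenerate member of the same
family rather than a special code path. A control sample of size *n* is
drawn from N(0, 1) and a treatment sample from N(ES, 1); the two are
compared with a two-tailed pooled-variance Student's t-test (both arms
share unit SD, so pooling is exact, and the raw mean difference is the
effect-size estimate on the *d* scale).

Publication is significance-driven. If p < α (strict) the result is
published as-is. Otherwise, with probability 1−b it is shelved; with
probability b — the bias parameter — the experiment is re-drawn with the
same true effect and sample size until a result passes, and only that
final passing result enters the literature, with its re-run count
recorded. Repetition stands in for the wider family of practices
(p-hacking, analytic flexibility, selective reporting) that convert
negative results into publishable positives. A variant rule
(`significance_and_magnitude`) additionally requires the published
estimate to exceed the minimum effect of interest.

The loop continues until the literature holds a target number of
published findings (5,000 in headline runs). Every drawn effect, published
or not, is counted so the realized prevalence of true effects among
attempted experiments can be compared with the analytic mixture mass.

## Truth, classification and metrics

An effect is *true* when |ES| strictly exceeds the minimum effect of
interest *m* (default 0.5 — a medium effect; equality counts as false, a
measure-zero convention for continuous models). A published finding is a
true positive only if its true effect is true *and* its estimate has the
correct sign; wrong-sign findings are false positives regardless of
magnitude.

* PPV = TP / published.
* Type S rate = share of published findings with sign(estimate) ≠
  sign(ES), over all published findings. It is undefined when ES = 0
  exactly, so the dichotomous model raises rather than returning a
  number.
* Type M (exaggeration) = estimate / ES over correctly-signed findings
  only (wrong-sign findings are excluded, not folded by absolute value);
  reported as median and IQR with linear-interpolation quantiles, since
  the ratio's distribution is heavy-tailed when small effects are pushed
  past the significance threshold.
* p-curves bin published p-values on (0, α] with default width 0.005
  (10 bins at α = 0.05, configurable).

## Prevalence control and achievability

The prevalence of true effects P(|ES| > m) is controlled by w_B for
two-component models — prevalence is linear in w_B, so the solve
`w_B = (target − p_A)/(p_B − p_A)` from the components' two-tailed masses
is exact — and by SD_A for the single normal, where
`SD_A = m / Φ⁻¹(1 − target/2)` in closed form. Both solvers round-trip
through the analytic prevalence to 10⁻¹⁰.

Each model can only reach prevalences between its components' tail
masses. The wide component N(0, 1) of `two_normals` has two-tailed mass
2(1−Φ(0.5)) ≈ 0.617 beyond 0.5, so a 66.7%-prevalence scenario is
unreachable; the `overlapping_peaks` floor 2(1−Φ(0.5/0.3)) ≈ 0.0956 makes
a 0.1%-prevalence scenario unreachable. The scenario-table builder treats
unachievability as data: such cells become skip records carrying the
achievable interval. Targets within half a percentage point of the
interval (the 1:10-odds scenarios, prevalence 9.09%, against the
overlapping-peaks floor of 9.56%) are instead clamped to the boundary and
flagged, since a field's odds are only ever approximated by the
distribution's parameters; the realized prevalence is reported per cell.

## Power and sample size

Sample size is resolved once per scenario — fields size their studies for
a typical effect, not per hypothesis — as the smallest integer n per
group whose exact two-sample power meets the target. Power uses the
noncentral t distribution with df = 2n−2 and noncentrality ES·√(n/2); the
ceiling convention means achieved power sits slightly above nominal and
is reported alongside every run. The default reference effect is the
typical true effect E[|ES| given |ES| > m], computed analytically from
truncated-normal partial moments (a Monte-Carlo path with 100,000 draws
exists for cross-validation; the two agree within Monte-Carlo error). The
absolute conditional mean is used because symmetric models have signed
conditional mean zero, against which power would be undefined. Fixed
references (m or 2m) are available to decouple sizing from the
distribution's shape; for the single normal the typical effect grows with
prevalence (larger SD), so nominal power then refers to a larger effect.

## Randomness and reproducibility

One numpy `Generator` per simulation, seeded from the configuration,
consumed in a fixed order (effect draws, first-run samples, bias coins,
repeat rounds, chunk by chunk): identical seeds give byte-identical
finding tables. Experiments run in vectorized chunks; bias-selected
failures are re-run as a shrinking batch. A repeat cap (default 10⁶)
turns an almost-surely-unsatisfiable publication rule into an informative
error instead of a hang. Batch runners (scenario table, sweeps) derive
per-cell seeds via `SeedSequence(master_seed, cell indices)`, so cells
are independent and individually re-runnable; Python's `hash` is avoided
because it is not stable across processes.

## What the simulations do and do not show

The generator *is* the model under study: runs characterize the behaviour
of an idealized field with full publication bias, a fixed significance
threshold, one test per paper, equal-variance normal samples, and bias
modeled as repetition until significance. Passing tests show the
implementation reproduces that model's mathematics (closed-form PPV,
tail masses, power) and its published simulated behaviour — not that any
real literature has these error rates. Real fields publish some negative
results, replicate, vary designs and analysis methods, and have unknown
effect-size distributions; none of that is modeled here, and varying
prevalence in continuous models necessarily moves other distribution
features with it, so prevalence is not an isolated dial.

## Numerical and design choices

* Strict inequalities throughout: significance is p < α, truth is
  |ES| > m.
* Headline simulations use 5,000 published findings per cell (binomial
  SE on a PPV of 0.85 ≈ 0.5 percentage points); qualitative and
  structural tests use 1,000–2,000 findings, which keeps directional
  checks sharp while the full suite stays fast.
* The analytic scenario column is always the closed form, never a
  simulation; agreement between the two for the dichotomous model is a
  correctness check of the whole pipeline.
* YAML configs are flat key-value documents with unknown keys rejected;
  outputs are CSV plus a JSON manifest sufficient to reproduce the run.

## Known limitations

* Bias is a single mechanism (repeat until significant); partial
  publication of negative results, replication, meta-analytic
  aggregation and between-lab variation are out of scope.
* Effect sizes are standardized mean differences from two-sample
  t-tests; other designs (correlations, regressions) are not modeled,
  though standardized effects are broadly interconvertible.
* The minimum effect of interest is a sharp, arbitrary threshold; the
  sign/magnitude error metrics exist precisely because that dichotomy is
  artificial.
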
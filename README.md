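# litsim

Simulated scientific literatures under null-hypothesis significance
testing and publication bias, with **continuous effect-size
distributions**.

Diagnostic-screening arguments about the reliability of published
research ("most published findings are false") traditionally assume
hypotheses are dichotomously true or false. `litsim` replaces that
assumption: each simulated experiment draws its true effect from a
two-component normal mixture on the Cohen's *d* scale, runs a two-group
Student's t-test at a sample size set by power analysis, and publishes
only significant results — with a bias parameter that pushes a fraction
of negative results to significance by re-running them. The generated
literature is then scored by:

- **PPV** — fraction of published findings whose true effect exceeds the
  minimum effect of interest (0.5 by default) *and* is estimated with the
  correct sign;
- **type S error rate** — published estimates with the wrong sign;
- **type M error** — the exaggeration factor (estimate / true effect)
  among correctly-signed findings, median and IQR;
- **p-curves** — the distribution of published p-values on (0, 0.05].

The package is aimed at metascience researchers and methods teachers who
want a reproducible, scriptable version of these arguments.

## The model

True effects follow the mixture `(1−w_B)·N(0, SD_A) + w_B·N(μ_B, SD_B)`.
Five named models span the range from the classic dichotomy to a single
zero-centered normal (SD = 0 denotes a point mass):

| model | SD_A | μ_B | SD_B | prevalence controlled by |
|---|---|---|---|---|
| `dichotomous` | 0 | 1 | 0 | w_B |
| `two_peaks` | 0.1 | 1 | 0.1 | w_B |
| `overlapping_peaks` | 0.3 | 1 | 0.3 | w_B |
| `two_normals` | 0.1 | 0 | 1 | w_B |
| `single_normal` | free | — | — | SD_A (w_B = 0) |

An effect is *true* when |ES| > 0.5. Both experimental groups have unit
SD; group sizes come from inverting the exact noncentral-t power function
at the "typical" true effect E[|ES| given |ES| > 0.5]. A non-significant
experiment is shelved with probability 1−b, or (probability b) re-run
until significant and then published.

The closed-form benchmark, recovered exactly by the dichotomous model, is
the bias-adjusted screening PPV with pre-study odds R, power 1−β, bias u:

    PPV = ((1−β)R + uβR) / (R + α − βR + u − uα + uβR)

## Worked example

```python
import litsim as ls

config = ls.SimulationConfig(
    distribution=ls.distribution_for_prevalence("two_peaks", 0.5),
    power_spec=ls.PowerSpec(power=0.8),
    bias=0.1,
    n_published_target=5000,
    seed=2023,
)
lit = ls.simulate_literature(config)
s = ls.summarize(lit)
```

Running `python examples/single_literature.py` (the same configuration)
prints:

```
sample size per group: 17 (achieved power 0.807)
experiments run:       10060 to publish 5000 findings
achieved prevalence:   0.508
PPV:                   0.838  (4192 TP / 808 FP)
type S error rate:     0.0472
type M (exaggeration): median 1.13, IQR [0.93, 1.40]
median published p:    0.0048
```

That is: with 80% power to detect the typical true effect (d ≈ 1, so 17
per group), 50% prevalence and 10% bias, about 84% of published findings
are true positives; under 5% of published estimates have the wrong sign;
the median published estimate overstates its true effect by 13%.

Other entry points, one per capability, live in `examples/`:
distribution mathematics and achievable-prevalence intervals, the
nine-scenario table with its analytic column and skipped cells, parameter
sweeps, p-curves, and the magnitude-gated publication / fixed
power-reference variants. A thin CLI wraps the same library calls:

```bash
litsim run config.yaml -o out/      # one literature from a YAML config
litsim table1 -o out/ --seed 1      # the full scenario table
litsim sweep sweep.yaml -o out/     # a power x bias x prevalence grid
```

Outputs are plain CSV plus a JSON manifest that records the resolved
configuration and seed; re-running from a manifest reproduces the files
byte for byte.

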
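"""p-curves: the shape of published p-values diagnoses the literature.

Compares two extreme literatures. In a null-effects field kept alive by
bias, published p-values are uniform on (0, 0.05) — a flat p-curve. In a
high-power, high-prevalence field the p-curve is steeply right-skewed:
most published p-values are tiny.
"""

import numpy as np

import litsim as ls

null_field = ls.SimulationConfig(
    distribution=ls.make_distribution("dichotomous", w_b=0.0),
    power_spec=ls.PowerSpec(power=0.8, reference="min_effect"),
    bias=1.0,
    n_published_target=2000,
    seed=5,
)
healthy_field = ls.SimulationConfig(
    distribution=ls.distribution_for_prevalence("two_peaks", 0.9),
    power_spec=ls.PowerSpec(power=0.8),
    bias=0.0,
    n_published_target=2000,
    seed=5,
)

for label, config in [("all-null field, full bias", null_field),
                      ("90% true effects, no bias", healthy_field)]:
    lit = ls.simulate_literature(config)
    counts, edges, median_p = ls.p_curve(lit)
    print(f"\n{label}: median published p = {median_p:.4f}")
    for lo, hi, c in zip(edges[:-1], edges[1:], counts):
        bar = "#" * int(np.round(60 * c / counts.max()))
        print(f"  ({lo:.3f}, {hi:.3f}] {c:5d} {bar}")

print(
    "\nA flat histogram signals selection on significance without real\n"
    "effects; right-skew signals evidential value. The median published\n"
    "p-value falls as the PPV rises."
)
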
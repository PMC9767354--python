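"""Variant rules: magnitude-gated publication and fixed power references.

Two robustness switches of the framework:

* ``significance_and_magnitude`` — results are only published when the
  estimate also exceeds the minimum effect of interest, not just p < 0.05.
* ``power_reference`` — sample sizes computed against the minimum effect
  of interest (or twice it) instead of the distribution's typical true
  effect, decoupling sizing from the distribution's shape.
"""

import litsim as ls


def summarize(rule, reference, power=0.8):
    config = ls.SimulationConfig(
        distribution=ls.distribution_for_prevalence("single_normal", 0.3),
        power_spec=ls.PowerSpec(power=power, reference=reference),
        bias=0.2,
        publication_rule=rule,
        n_published_target=2000,
        seed=31,
    )
    lit = ls.simulate_literature(config)
    s = ls.summarize(lit)
    return s, lit.n_per_group


print("single_normal at 30% prevalence, 80% power, bias 0.2\n")
print(f"{'publication rule':28s} {'power ref':18s} {'n/grp':>5} {'PPV':>7} {'typeM med':>10}")
for rule in ("significance_only", "significance_and_magnitude"):
    for reference in ("typical_true_mean", "min_effect", "twice_min_effect"):
        s, n = summarize(rule, reference)
        print(f"{rule:28s} {reference:18s} {n:>5d} {s.ppv:>7.3f} {s.type_m_median:>10.2f}")

print(
    "\nGating publication on magnitude raises the PPV mainly when power is\n"
    "high (small estimates only reach significance with large samples);\n"
    "sizing against the minimum of interest instead of the typical true\n"
    "effect changes n and, with it, every downstream error rate."
)
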
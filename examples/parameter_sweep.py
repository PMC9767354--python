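"""Sweep prevalence and bias for one model: how the PPV responds.

A small power x bias x prevalence grid for the single_normal model (the
SD is solved per prevalence). PPV rises with prevalence and power, falls
with bias; the sign-error rate and exaggeration move the opposite way.
"""

import litsim as ls

grid = ls.SweepGrid(
    model_name="single_normal",
    powers=(0.2, 0.8),
    biases=(0.0, 0.6),
    prevalences=(0.1, 0.5, 0.9),
    n_published=2000,
)
out = ls.run_sweep(grid, seed=11)

print(f"{'power':>6} {'bias':>5} {'prev':>5} {'PPV':>7} {'typeS':>7} {'typeM med':>10}")
for _, r in out.iterrows():
    print(
        f"{r['power']:>6.1f} {r['bias']:>5.1f} {r['prevalence']:>5.1f} "
        f"{r['ppv']:>7.3f} {r['type_s_rate']:>7.4f} {r['type_m_median']:>10.2f}"
    )

print(
    "\nAt 10% prevalence with heavy bias and low power most published\n"
    "findings are false and medians are exaggerated severalfold; at 90%\n"
    "prevalence the literature is accurate under every bias level shown."
)
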
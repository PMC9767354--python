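"""One simulated experiment: sampling, t-test, and the publication decision.

Each experiment compares a control group drawn from N(0, 1) with a
treatment group drawn from N(ES, 1), both of size ``n_per_group``, using a
two-tailed pooled-variance Student's t-test. Because the within-group SD is
fixed at 1, the raw difference in means is on the Cohen's *d* scale.

Sample size is set once per scenario by inverting the exact noncentral-t
power function at a reference effect (by default the typical true effect of
the field's distribution).

Publication is significance-driven: a significant first result is
published as-is. A non-significant one is either shelved (probability
1 - bias) or — with probability ``bias`` — re-run with fresh samples until
it reaches significance in either direction, and only that final
significant result is published. The bias parameter stands in for the whole
family of practices (p-hacking, flexible analysis, selective reporting)
that turn negative results into publishable positive ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distributions import DEFAULT_MIN_EFFECT, EffectDistribution, typical_true_effect

__all__ = [
    "ExperimentResult",
    "PowerSpec",
    "POWER_REFERENCES",
    "RepeatCapExceeded",
    "power_for_sample_size",
    "sample_size_for_power",
    "resolve_reference_effect",
    "run_experiment",
    "run_experiment_batch",
    "passes_rule",
    "publish_decision",
]

POWER_REFERENCES = ("typical_true_mean", "min_effect", "twice_min_effect")

DEFAULT_REPEAT_CAP = 10**6


class RepeatCapExceeded(RuntimeError):
    """The bias loop failed to reach a publishable result within the cap.

    Signals a publication rule that is (almost surely) unsatisfiable for
    the configuration, e.g. a magnitude gate far beyond what sampling
    error can produce.
    """


@dataclass
class ExperimentResult:
    """Outcome of a single two-group experiment.

    ``repeats`` counts bias-driven re-runs preceding the recorded result
    (0 when the first run was published or the result was shelved).
    """

    true_es: float
    estimate: float
    p_value: float
    n_per_group: int
    repeats: int = 0
    published: bool = False


@dataclass
class PowerSpec:
    """Target power and how the reference effect for sizing is chosen.

    ``reference`` selects the effect the sample size is computed against:
    the mean absolute true effect of the distribution (default), the
    minimum effect of interest itself, or twice the minimum — the latter
    two decouple sizing from the distribution's shape.
    """

    power: float = 0.8
    alpha: float = 0.05
    reference: str = "typical_true_mean"
    reference_effect: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must lie in (0, 1), got {self.power}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.reference not in POWER_REFERENCES:
            raise ValueError(f"reference must be one of {POWER_REFERENCES}, got {self.reference!r}")
        if self.reference_effect is not None and self.reference_effect <= 0:
            raise ValueError("reference_effect must be > 0")


def power_for_sample_size(effect: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided, two-sample pooled-variance t-test.

    With n per group and unit within-group SD the test statistic follows a
    noncentral t with df = 2n - 2 and noncentrality effect * sqrt(n / 2);
    power is the probability of exceeding the central-t critical value in
    either tail.
    """
    n = int(n_per_group)
    if n < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    df = 2 * n - 2
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = effect * np.sqrt(n / 2.0)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def sample_size_for_power(spec: PowerSpec) -> int:
    """Smallest per-group n whose exact power meets the target.

    Power is monotone in n, so an exponential bracket followed by bisection
    finds the minimal integer; the achieved power (slightly above nominal)
    is recoverable via :func:`power_for_sample_size`.
    """
    effect = spec.reference_effect
    if effect is None or effect <= 0:
        raise ValueError("spec.reference_effect must be resolved and > 0")
    lo, hi = 2, 2
    while power_for_sample_size(effect, hi, spec.alpha) < spec.power:
        lo, hi = hi, hi * 2
    while lo < hi:
        mid = (lo + hi) // 2
        if power_for_sample_size(effect, mid, spec.alpha) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def resolve_reference_effect(
    spec: PowerSpec,
    dist: EffectDistribution,
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> PowerSpec:
    """Fill in ``reference_effect`` according to the spec's reference rule."""
    if spec.reference == "typical_true_mean":
        ref = typical_true_effect(dist, min_effect)
    elif spec.reference == "min_effect":
        ref = min_effect
    else:  # twice_min_effect
        ref = 2.0 * min_effect
    return PowerSpec(
        power=spec.power, alpha=spec.alpha, reference=spec.reference, reference_effect=ref
    )


def run_experiment_batch(
    true_es: np.ndarray, n_per_group: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Run many independent experiments at once.

    Returns (estimates, p_values); estimate = mean(treatment) - mean(control).
    """
    n = int(n_per_group)
    if n < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    true_es = np.asarray(true_es, dtype=float)
    control = rng.standard_normal((true_es.size, n))
    treatment = rng.standard_normal((true_es.size, n)) + true_es[:, None]
    res = stats.ttest_ind(treatment, control, axis=1, equal_var=True)
    estimates = treatment.mean(axis=1) - control.mean(axis=1)
    return estimates, np.asarray(res.pvalue)


def run_experiment(true_es: float, n_per_group: int, rng: np.random.Generator) -> ExperimentResult:
    """Run a single experiment (unpublished state)."""
    est, p = run_experiment_batch(np.array([true_es]), n_per_group, rng)
    return ExperimentResult(
        true_es=float(true_es),
        estimate=float(est[0]),
        p_value=float(p[0]),
        n_per_group=int(n_per_group),
    )


def passes_rule(
    p_value: float | np.ndarray,
    estimate: float | np.ndarray,
    rule: str,
    alpha: float,
    min_effect: float,
):
    """Whether a result counts as publishable under the active rule.

    ``significance_only``: p < alpha (strict). ``significance_and_magnitude``
    additionally requires |estimate| > min_effect — the variant where the
    estimated effect size gates publication.
    """
    sig = np.asarray(p_value) < alpha
    if rule == "significance_only":
        return sig
    if rule == "significance_and_magnitude":
        return sig & (np.abs(np.asarray(estimate)) > min_effect)
    raise ValueError(f"unknown publication rule {rule!r}")


def publish_decision(
    first_result: ExperimentResult,
    bias: float,
    rng: np.random.Generator,
    rule: str = "significance_only",
    min_effect: float = DEFAULT_MIN_EFFECT,
    alpha: float = 0.05,
    repeat_cap: int = DEFAULT_REPEAT_CAP,
) -> ExperimentResult:
    """Apply the bias-driven publication decision to a first result.

    A passing first result is published with ``repeats = 0``. A failing one
    is shelved with probability 1 - bias; otherwise the experiment is
    re-run (same true effect, same n, fresh samples) until a result passes,
    and that final result is published with ``repeats`` = number of re-runs.
    """
    if not 0.0 <= bias <= 1.0:
        raise ValueError(f"bias must lie in [0, 1], got {bias}")
    if bool(passes_rule(first_result.p_value, first_result.estimate, rule, alpha, min_effect)):
        first_result.published = True
        first_result.repeats = 0
        return first_result
    if rng.random() >= bias:
        first_result.published = False
        return first_result
    repeats = 0
    while True:
        repeats += 1
        if repeats > repeat_cap:
            raise RepeatCapExceeded(
                f"no publishable result after {repeat_cap} re-runs "
                f"(rule={rule!r}, alpha={alpha}, min_effect={min_effect}, "
                f"true_es={first_result.true_es}, n={first_result.n_per_group})"
            )
        result = run_experiment(first_result.true_es, first_result.n_per_group, rng)
        if bool(passes_rule(result.p_value, result.estimate, rule, alpha, min_effect)):
            result.published = True
            result.repeats = repeats
            return result
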
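"""Simulate a published literature to a fixed number of findings.

The simulation keeps drawing effects, running experiments and applying the
publication decision until the literature holds a target number of
published findings (5,000 in the headline configurations). Every effect
drawn — published or not — is recorded in aggregate, so the achieved
prevalence of true effects among attempted experiments can be compared
with the analytic prevalence of the effect-size distribution.

Classification of a published finding follows the diagnostic-screening
convention: it is a true positive only if the *true* effect exceeds the
minimum of interest in absolute value AND the estimate has the correct
sign; a significant estimate with the wrong sign counts as a false
positive even when the underlying effect is true.

All randomness flows through one numpy Generator seeded from the
configuration, consumed in a fixed order (effect draws, first-run samples,
bias coin flips, then repeat rounds, chunk by chunk), so a run is fully
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import (
    DEFAULT_MIN_EFFECT,
    EffectDistribution,
    sample_effects,
)
from .experiment import (
    DEFAULT_REPEAT_CAP,
    PowerSpec,
    RepeatCapExceeded,
    passes_rule,
    power_for_sample_size,
    resolve_reference_effect,
    run_experiment_batch,
    sample_size_for_power,
)

__all__ = ["SimulationConfig", "PublishedLiterature", "simulate_literature"]

PUBLICATION_RULES = ("significance_only", "significance_and_magnitude")

#: findings-table columns, in output order
FINDING_COLUMNS = [
    "true_es",
    "estimate",
    "p_value",
    "repeats",
    "is_true_effect",
    "sign_correct",
    "classification",
]


@dataclass
class SimulationConfig:
    """Everything needed to simulate one literature."""

    distribution: EffectDistribution
    power_spec: PowerSpec = field(default_factory=PowerSpec)
    bias: float = 0.0
    min_effect: float = DEFAULT_MIN_EFFECT
    publication_rule: str = "significance_only"
    n_published_target: int = 5000
    seed: int = 0
    repeat_cap: int = DEFAULT_REPEAT_CAP
    scenario_name: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError(f"bias must lie in [0, 1], got {self.bias}")
        if self.n_published_target < 1:
            raise ValueError("n_published_target must be >= 1")
        if self.publication_rule not in PUBLICATION_RULES:
            raise ValueError(
                f"publication_rule must be one of {PUBLICATION_RULES}, got {self.publication_rule!r}"
            )
        if self.min_effect <= 0:
            raise ValueError("min_effect must be > 0")


@dataclass
class PublishedLiterature:
    """A simulated literature plus its provenance.

    ``findings`` is a DataFrame with one row per published finding
    (columns ``true_es, estimate, p_value, repeats, is_true_effect,
    sign_correct, classification``), in publication order.
    """

    findings: pd.DataFrame
    n_experiments_total: int
    achieved_prevalence: float
    n_per_group: int
    achieved_power: float
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.findings)


def _classify(
    true_es: np.ndarray, estimate: np.ndarray, min_effect: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(is_true_effect, sign_correct, classification) for published findings."""
    is_true = np.abs(true_es) > min_effect
    sign_correct = true_es * estimate > 0
    classification = np.where(is_true & sign_correct, "TP", "FP")
    return is_true, sign_correct, classification


def simulate_literature(config: SimulationConfig) -> PublishedLiterature:
    """Run the publication loop until the target number of findings.

    The per-group sample size is resolved once from the power target and
    the distribution's typical true effect (or a fixed reference), then
    held constant: the field sizes its studies for the scenario, not for
    each individual effect. Experiments run in vectorized chunks; within a
    chunk, bias-selected non-significant experiments are re-run together
    until each reaches a publishable result.
    """
    dist = config.distribution
    min_effect = config.min_effect
    alpha = config.power_spec.alpha
    spec = config.power_spec
    if spec.reference_effect is None:
        spec = resolve_reference_effect(spec, dist, min_effect)
    try:
        n_per_group = sample_size_for_power(spec)
    except ValueError as exc:
        raise type(exc)(f"{exc} (scenario {config.scenario_name!r})") from exc
    achieved_power = power_for_sample_size(spec.reference_effect, n_per_group, alpha)

    rng = np.random.default_rng(config.seed)
    target = config.n_published_target
    # Chunk sized so most runs finish in a handful of rounds; correctness
    # does not depend on it, only the RNG consumption pattern does.
    chunk = max(256, min(8192, 2 * target))

    pub_rows: list[pd.DataFrame] = []
    n_published = 0
    n_experiments = 0
    n_true_drawn = 0

    while n_published < target:
        es = sample_effects(dist, chunk, rng)
        estimates, pvals = run_experiment_batch(es, n_per_group, rng)
        ok = passes_rule(pvals, estimates, config.publication_rule, alpha, min_effect)
        repeats = np.zeros(chunk, dtype=np.int64)
        published = ok.copy()

        # Bias: a failing experiment is pushed to significance w.p. `bias`.
        failing = ~ok
        coins = rng.random(int(failing.sum())) < config.bias
        pushed = np.flatnonzero(failing)[coins]
        published[pushed] = True
        active = pushed
        while active.size:
            repeats[active] += 1
            if repeats[active].max() > config.repeat_cap:
                raise RepeatCapExceeded(
                    f"no publishable result after {config.repeat_cap} re-runs "
                    f"(rule={config.publication_rule!r}, scenario {config.scenario_name!r})"
                )
            est_r, p_r = run_experiment_batch(es[active], n_per_group, rng)
            done = passes_rule(p_r, est_r, config.publication_rule, alpha, min_effect)
            estimates[active[done]] = est_r[done]
            pvals[active[done]] = p_r[done]
            active = active[~done]

        pub_idx = np.flatnonzero(published)
        needed = target - n_published
        if pub_idx.size > needed:
            # Truncate at the experiment that produced the last needed
            # finding so totals and prevalence stay consistent.
            cutoff = pub_idx[needed - 1] + 1
            pub_idx = pub_idx[:needed]
        else:
            cutoff = chunk
        n_experiments += int(cutoff)
        n_true_drawn += int((np.abs(es[:cutoff]) > min_effect).sum())

        is_true, sign_ok, classification = _classify(
            es[pub_idx], estimates[pub_idx], min_effect
        )
        pub_rows.append(
            pd.DataFrame(
                {
                    "true_es": es[pub_idx],
                    "estimate": estimates[pub_idx],
                    "p_value": pvals[pub_idx],
                    "repeats": repeats[pub_idx],
                    "is_true_effect": is_true,
                    "sign_correct": sign_ok,
                    "classification": classification,
                }
            )
        )
        n_published += pub_idx.size

    findings = pd.concat(pub_rows, ignore_index=True)
    return PublishedLiterature(
        findings=findings,
        n_experiments_total=n_experiments,
        achieved_prevalence=n_true_drawn / n_experiments,
        n_per_group=n_per_group,
        achieved_power=achieved_power,
        config=config,
    )
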
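"""Named scenario presets, the analytic bias-adjusted PPV, and batch runs.

The nine headline scenarios pair a statistical power with pre-study odds
of a true hypothesis and a level of bias — from an adequately powered
randomized trial at 1:1 odds down to discovery-oriented massive testing at
1:1000 odds. Each scenario is crossed with the five effect-size models,
with distribution parameters solved so the prevalence of true effects
matches the scenario's odds. Cells whose prevalence no parameter value can
reach are emitted as explicit skip records, not errors: unachievability is
a property of the model worth reporting.

The analytic benchmark is the diagnostic-screening PPV with bias u,
pre-study odds R, power 1 - beta and level alpha:

    PPV = ((1 - beta) R + u beta R) / (R + alpha - beta R + u - u alpha + u beta R)

which the simulated dichotomous model should reproduce to Monte-Carlo
error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import (
    DEFAULT_MIN_EFFECT,
    EffectDistribution,
    MODEL_NAMES,
    UnachievablePrevalence,
    make_distribution,
    solve_sd_for_prevalence,
    solve_weight_for_prevalence,
    true_prevalence,
)
from .experiment import PowerSpec
from .literature import SimulationConfig, simulate_literature
from .metrics import summarize

__all__ = [
    "ScenarioSpec",
    "ScenarioCell",
    "SweepGrid",
    "TABLE1_SCENARIOS",
    "ioannidis_ppv",
    "distribution_for_prevalence",
    "build_table1_scenarios",
    "run_table1",
    "run_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """One named scenario: power, pre-study odds, bias."""

    name: str
    power: float
    odds_true: float
    bias: float
    alpha: float = 0.05
    n_published_target: int = 5000

    @property
    def prevalence(self) -> float:
        """Prevalence of true hypotheses implied by the odds: R / (R + 1)."""
        return self.odds_true / (1.0 + self.odds_true)


#: The nine headline scenarios (power, odds R, bias u).
TABLE1_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("Adequately powered RCT with little bias and 1:1 pre-study odds", 0.80, 1.0, 0.10),
    ScenarioSpec("Confirmatory meta-analysis of good quality RCTs", 0.95, 2.0, 0.30),
    ScenarioSpec("Meta-analysis of small inconclusive studies", 0.80, 1.0 / 3.0, 0.40),
    ScenarioSpec("Underpowered, but well-performed phase I/II RCT", 0.20, 0.2, 0.20),
    ScenarioSpec("Underpowered, poorly performed phase I/II RCT", 0.20, 0.2, 0.80),
    ScenarioSpec("Adequately powered exploratory epidemiological study", 0.80, 0.1, 0.30),
    ScenarioSpec("Underpowered exploratory epidemiological study", 0.20, 0.1, 0.30),
    ScenarioSpec(
        "Discovery-oriented exploratory research with massive testing", 0.20, 0.001, 0.80
    ),
    ScenarioSpec(
        "Discovery-oriented exploratory research with massive testing, "
        "but with more limited bias (more standardized)",
        0.20,
        0.001,
        0.20,
    ),
)


def ioannidis_ppv(power: float, odds_true: float, bias: float, alpha: float = 0.05) -> float:
    """Closed-form PPV of a field with pre-study odds R, power and bias u.

    With beta = 1 - power, a fraction u of would-be-negative results is
    converted to positives; published positives then comprise true
    positives (1-beta)R + u·beta·R against all positives
    R + alpha - beta·R + u(1 - alpha + beta·R).
    """
    if odds_true <= 0:
        raise ValueError(f"odds_true must be > 0, got {odds_true}")
    if not (0 < power < 1 and 0 <= bias <= 1 and 0 < alpha < 1):
        raise ValueError("power/alpha must lie in (0, 1) and bias in [0, 1]")
    beta = 1.0 - power
    r, u = odds_true, bias
    num = (1.0 - beta) * r + u * beta * r
    den = r + alpha - beta * r + u - u * alpha + u * beta * r
    return num / den


def distribution_for_prevalence(
    model_name: str, prevalence: float, min_effect: float = DEFAULT_MIN_EFFECT
) -> EffectDistribution:
    """Instantiate a named model with its free parameter solved so that the
    prevalence of true effects equals ``prevalence``.

    Raises :class:`UnachievablePrevalence` when no parameter value reaches
    the target (carrying the achievable interval).
    """
    if model_name == "single_normal":
        sd_a = solve_sd_for_prevalence(prevalence, min_effect)
        return make_distribution(model_name, sd_a=sd_a)
    w_b = solve_weight_for_prevalence(model_name, prevalence, min_effect)
    return make_distribution(model_name, w_b=w_b)


#: Targets within half a percentage point of a model's achievable interval
#: are clamped to the boundary (the realized prevalence "approximates" the
#: scenario's odds); farther targets become skip records.
PREVALENCE_CLAMP_TOL = 0.005


@dataclass(frozen=True)
class ScenarioCell:
    """One scenario x model cell: a resolved distribution or a skip record.

    ``clamped`` marks cells whose target prevalence sat just outside the
    model's achievable interval and was moved to the nearest boundary;
    ``realized_prevalence`` is the prevalence actually simulated.
    """

    scenario: ScenarioSpec
    model_name: str
    distribution: EffectDistribution | None = None
    skipped: bool = False
    skip_reason: str | None = None
    achievable_bounds: tuple[float, float] | None = None
    clamped: bool = False
    realized_prevalence: float | None = None


def build_table1_scenarios(
    min_effect: float = DEFAULT_MIN_EFFECT,
    models: tuple[str, ...] = MODEL_NAMES,
    scenarios: tuple[ScenarioSpec, ...] = TABLE1_SCENARIOS,
) -> list[ScenarioCell]:
    """Cross the headline scenarios with the effect-size models.

    Every cell resolves its distribution parameters via the prevalence
    solvers. A target just outside the model's achievable interval (within
    :data:`PREVALENCE_CLAMP_TOL`) is clamped to the boundary, so the cell
    is simulated at an approximating prevalence; targets farther out
    become skip records carrying the achievable interval, mirroring the
    missing entries of the printed table.
    """
    cells: list[ScenarioCell] = []
    for spec in scenarios:
        for model in models:
            target = spec.prevalence
            clamped = False
            try:
                dist = distribution_for_prevalence(model, target, min_effect)
            except UnachievablePrevalence as exc:
                lo, hi = exc.bounds
                boundary = lo if target < lo else hi
                if abs(target - boundary) <= PREVALENCE_CLAMP_TOL:
                    target, clamped = boundary, True
                    dist = distribution_for_prevalence(model, target, min_effect)
                    logger.info(
                        "clamping %s / %s prevalence %.4f -> %.4f",
                        spec.name, model, spec.prevalence, target,
                    )
                else:
                    cells.append(
                        ScenarioCell(
                            scenario=spec,
                            model_name=model,
                            skipped=True,
                            skip_reason=str(exc),
                            achievable_bounds=exc.bounds,
                        )
                    )
                    continue
            realized = true_prevalence(dist, min_effect)
            assert abs(realized - target) < 1e-6
            cells.append(
                ScenarioCell(
                    scenario=spec,
                    model_name=model,
                    distribution=dist,
                    clamped=clamped,
                    realized_prevalence=realized,
                )
            )
    return cells


def _cell_seed(master_seed: int, *indices: int) -> int:
    """Deterministic, independent per-cell seed from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % 2**31)


def _run_cell(
    cell: ScenarioCell,
    seed: int,
    n_published: int,
    min_effect: float,
    publication_rule: str,
    power_reference: str,
) -> dict:
    spec = cell.scenario
    row = {
        "scenario": spec.name,
        "model": cell.model_name,
        "power": spec.power,
        "odds_true": spec.odds_true,
        "prevalence": spec.prevalence,
        "bias": spec.bias,
        "analytic_ppv": ioannidis_ppv(spec.power, spec.odds_true, spec.bias, spec.alpha),
        "skipped": cell.skipped,
        "skip_reason": cell.skip_reason,
        "clamped": cell.clamped,
        "solved_prevalence": cell.realized_prevalence,
    }
    if cell.skipped:
        return row
    config = SimulationConfig(
        distribution=cell.distribution,
        power_spec=PowerSpec(power=spec.power, alpha=spec.alpha, reference=power_reference),
        bias=spec.bias,
        min_effect=min_effect,
        publication_rule=publication_rule,
        n_published_target=n_published,
        seed=seed,
        scenario_name=f"{spec.name} / {cell.model_name}",
    )
    summary = summarize(simulate_literature(config))
    row.update(
        ppv=summary.ppv,
        type_s_rate=summary.type_s_rate,
        type_m_median=summary.type_m_median,
        type_m_q25=summary.type_m_q25,
        type_m_q75=summary.type_m_q75,
        median_p=summary.median_p,
        achieved_prevalence=summary.achieved_prevalence,
        achieved_power=summary.achieved_power,
        n_per_group=summary.n_per_group,
    )
    return row


def run_table1(
    seed: int,
    n_published: int = 5000,
    min_effect: float = DEFAULT_MIN_EFFECT,
    models: tuple[str, ...] = MODEL_NAMES,
    scenarios: tuple[ScenarioSpec, ...] = TABLE1_SCENARIOS,
    publication_rule: str = "significance_only",
    power_reference: str = "typical_true_mean",
) -> pd.DataFrame:
    """Simulate every scenario x model cell; one row each, skips included.

    The analytic PPV column is computed from the closed form, never
    simulated. Sign- and magnitude-error columns are absent (NaN) for the
    dichotomous model, whose null effects are exactly zero.
    """
    cells = build_table1_scenarios(min_effect, models, scenarios)
    rows = []
    for cell in cells:
        si = scenarios.index(cell.scenario)
        mi = models.index(cell.model_name)
        n_pub = n_published if n_published else cell.scenario.n_published_target
        rows.append(
            _run_cell(
                cell,
                _cell_seed(seed, si, mi),
                n_pub,
                min_effect,
                publication_rule,
                power_reference,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepGrid:
    """A power x bias x prevalence grid for one effect-size model."""

    model_name: str
    powers: tuple[float, ...] = (0.2, 0.5, 0.8)
    biases: tuple[float, ...] = (0.0, 0.2, 0.6)
    prevalences: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    alpha: float = 0.05
    n_published: int = 5000
    min_effect: float = DEFAULT_MIN_EFFECT
    publication_rule: str = "significance_only"
    power_reference: str = "typical_true_mean"


def run_sweep(grid: SweepGrid, seed: int) -> pd.DataFrame:
    """One simulated literature per (power, bias, prevalence) grid cell.

    Unachievable prevalences for the grid's model are dropped with a
    logged notice (achievable ranges differ between models). Output is a
    long-format frame sorted by (power, bias, prevalence); each cell gets
    an independent seed derived from the master seed.
    """
    rows = []
    for pi, power in enumerate(sorted(grid.powers)):
        for bi, bias in enumerate(sorted(grid.biases)):
            for vi, prev in enumerate(sorted(grid.prevalences)):
                try:
                    dist = distribution_for_prevalence(grid.model_name, prev, grid.min_effect)
                except UnachievablePrevalence as exc:
                    logger.info("dropping unachievable grid cell: %s", exc)
                    continue
                config = SimulationConfig(
                    distribution=dist,
                    power_spec=PowerSpec(
                        power=power, alpha=grid.alpha, reference=grid.power_reference
                    ),
                    bias=bias,
                    min_effect=grid.min_effect,
                    publication_rule=grid.publication_rule,
                    n_published_target=grid.n_published,
                    seed=_cell_seed(seed, pi, bi, vi),
                    scenario_name=f"{grid.model_name} power={power} bias={bias} prev={prev}",
                )
                summary = summarize(simulate_literature(config))
                rows.append(
                    {
                        "model": grid.model_name,
                        "power": power,
                        "bias": bias,
                        "prevalence": prev,
                        "ppv": summary.ppv,
                        "type_s_rate": summary.type_s_rate,
                        "type_m_median": summary.type_m_median,
                        "type_m_q25": summary.type_m_q25,
                        "type_m_q75": summary.type_m_q75,
                        "median_p": summary.median_p,
                        "achieved_prevalence": summary.achieved_prevalence,
                        "achieved_power": summary.achieved_power,
                        "n_per_group": summary.n_per_group,
                    }
                )
    return pd.DataFrame(rows)
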
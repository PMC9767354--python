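"""Effect-size distributions: two-component normal mixtures.

The population of true effect sizes investigated in a research field is
modeled as a mixture of two normal components on the Cohen's *d* scale:

* component A, centered at 0 with standard deviation ``sd_a``;
* component B, centered at ``mu_b`` with standard deviation ``sd_b``;
* mixture weight ``w_b`` giving the probability of drawing from B.

A standard deviation of exactly 0 denotes a point mass, so the classic
dichotomous world (effects are exactly 0 or exactly 1) is the degenerate
corner of the same parametrization. Five named models span the range from
that dichotomy to a single normal centered at zero:

========================  ======  ======  ======  ==================
model                      sd_a    mu_b    sd_b    prevalence control
========================  ======  ======  ======  ==================
``dichotomous``            0       1       0       ``w_b``
``two_peaks``              0.1     1       0.1     ``w_b``
``overlapping_peaks``      0.3     1       0.3     ``w_b``
``two_normals``            0.1     0       1       ``w_b``
``single_normal``          free    0       0       ``sd_a`` (w_b = 0)
========================  ======  ======  ======  ==================

An effect is *true* when its absolute size exceeds a minimum effect of
interest (default 0.5, a medium effect). The prevalence of true effects is
the mixture mass beyond that threshold on both tails; it is controlled by
``w_b`` for the two-component models and by ``sd_a`` for the single normal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "EffectDistribution",
    "UnachievablePrevalence",
    "DEFAULT_MIN_EFFECT",
    "MODEL_NAMES",
    "make_distribution",
    "sample_effects",
    "true_prevalence",
    "achievable_prevalence_bounds",
    "solve_weight_for_prevalence",
    "solve_sd_for_prevalence",
    "typical_true_effect",
]

DEFAULT_MIN_EFFECT = 0.5

#: (sd_a, mu_b, sd_b) for each named model; None means "set by the caller".
_MODEL_PARAMS: dict[str, tuple[float | None, float, float]] = {
    "dichotomous": (0.0, 1.0, 0.0),
    "two_peaks": (0.1, 1.0, 0.1),
    "overlapping_peaks": (0.3, 1.0, 0.3),
    "two_normals": (0.1, 0.0, 1.0),
    "single_normal": (None, 0.0, 0.0),
}

MODEL_NAMES = tuple(_MODEL_PARAMS)


class UnachievablePrevalence(ValueError):
    """Raised when no mixture weight can reach the requested prevalence.

    Carries the achievable interval so callers can report why a scenario
    cell must be skipped rather than simulated.
    """

    def __init__(self, target: float, bounds: tuple[float, float], model_name: str | None = None):
        self.target = float(target)
        self.bounds = (float(bounds[0]), float(bounds[1]))
        self.model_name = model_name
        label = f" for model {model_name!r}" if model_name else ""
        super().__init__(
            f"prevalence {target:.6g} is unachievable{label}: "
            f"achievable interval is [{self.bounds[0]:.6g}, {self.bounds[1]:.6g}]"
        )


@dataclass(frozen=True)
class EffectDistribution:
    """Two-component normal mixture of true effect sizes (Cohen's d scale)."""

    sd_a: float
    mu_b: float
    sd_b: float
    w_b: float
    model_name: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_b <= 1.0:
            raise ValueError(f"w_b must lie in [0, 1], got {self.w_b}")
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValueError("component standard deviations must be >= 0")
        if self.model_name is not None:
            if self.model_name not in _MODEL_PARAMS:
                raise ValueError(f"unknown model name {self.model_name!r}")
            if self.model_name == "single_normal" and self.w_b != 0.0:
                raise ValueError("single_normal requires w_b = 0")
            if self.model_name == "dichotomous" and (self.sd_a != 0 or self.sd_b != 0):
                raise ValueError("dichotomous requires sd_a = sd_b = 0")


def make_distribution(
    model_name: str,
    *,
    w_b: float | None = None,
    sd_a: float | None = None,
) -> EffectDistribution:
    """Build a named preset, supplying its free parameter.

    Two-component models take ``w_b``; ``single_normal`` takes ``sd_a``.
    """
    if model_name not in _MODEL_PARAMS:
        raise ValueError(f"unknown model name {model_name!r}; choose from {MODEL_NAMES}")
    preset_sd_a, mu_b, sd_b = _MODEL_PARAMS[model_name]
    if model_name == "single_normal":
        if sd_a is None:
            raise ValueError("single_normal requires sd_a")
        if w_b not in (None, 0.0):
            raise ValueError("single_normal fixes w_b = 0")
        return EffectDistribution(sd_a=sd_a, mu_b=mu_b, sd_b=sd_b, w_b=0.0, model_name=model_name)
    if w_b is None:
        raise ValueError(f"{model_name} requires w_b")
    if sd_a is not None and sd_a != preset_sd_a:
        raise ValueError(f"{model_name} fixes sd_a = {preset_sd_a}")
    return EffectDistribution(sd_a=preset_sd_a, mu_b=mu_b, sd_b=sd_b, w_b=w_b, model_name=model_name)


def sample_effects(
    dist: EffectDistribution, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` true effect sizes from the mixture.

    Each draw comes from component B with probability ``w_b``, else from
    component A. Point-mass components (SD = 0) return their mean exactly,
    so the dichotomous model has zero sampling noise in the effect itself.
    """
    count = int(count)
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    from_b = rng.random(count) < dist.w_b
    out = np.empty(count)
    n_b = int(from_b.sum())
    n_a = count - n_b
    if n_a:
        out[~from_b] = 0.0 if dist.sd_a == 0 else rng.normal(0.0, dist.sd_a, n_a)
    if n_b:
        out[from_b] = dist.mu_b if dist.sd_b == 0 else rng.normal(dist.mu_b, dist.sd_b, n_b)
    return out


def _component_tail_mass(mu: float, sd: float, min_effect: float) -> float:
    """P(|X| > min_effect) for X ~ N(mu, sd); exact for point masses."""
    if sd == 0:
        return 1.0 if abs(mu) > min_effect else 0.0
    upper = stats.norm.sf(min_effect, loc=mu, scale=sd)
    lower = stats.norm.cdf(-min_effect, loc=mu, scale=sd)
    return float(upper + lower)


def true_prevalence(dist: EffectDistribution, min_effect: float = DEFAULT_MIN_EFFECT) -> float:
    """P(|ES| > min_effect): the prevalence of true effects in the mixture."""
    _check_min_effect(min_effect)
    p_a = _component_tail_mass(0.0, dist.sd_a, min_effect)
    p_b = _component_tail_mass(dist.mu_b, dist.sd_b, min_effect)
    return (1.0 - dist.w_b) * p_a + dist.w_b * p_b


def achievable_prevalence_bounds(
    model_name: str, min_effect: float = DEFAULT_MIN_EFFECT
) -> tuple[float, float]:
    """Prevalence interval reachable by varying the model's free parameter.

    For two-component models the prevalence is linear in ``w_b``, so the
    interval is spanned by the two component tail masses. For the single
    normal any prevalence in (0, 1) is reachable by scaling the SD.
    """
    _check_min_effect(min_effect)
    if model_name == "single_normal":
        return (0.0, 1.0)
    sd_a, mu_b, sd_b = _MODEL_PARAMS[model_name]
    p_a = _component_tail_mass(0.0, sd_a, min_effect)
    p_b = _component_tail_mass(mu_b, sd_b, min_effect)
    return (min(p_a, p_b), max(p_a, p_b))


def solve_weight_for_prevalence(
    model_name: str, target: float, min_effect: float = DEFAULT_MIN_EFFECT
) -> float:
    """Mixture weight ``w_b`` giving the target prevalence of true effects.

    The prevalence is (1-w)p_A + w·p_B, linear in w, so the solve is exact:
    w = (target - p_A)/(p_B - p_A).

    Raises :class:`UnachievablePrevalence` (with the achievable interval)
    when the target falls outside [min(p_A, p_B), max(p_A, p_B)] — this is
    how scenario cells that no weight can realize are detected.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target prevalence must lie in [0, 1], got {target}")
    if model_name == "single_normal":
        raise ValueError("single_normal controls prevalence via sd_a; use solve_sd_for_prevalence")
    sd_a, mu_b, sd_b = _MODEL_PARAMS[model_name]
    p_a = _component_tail_mass(0.0, sd_a, min_effect)
    p_b = _component_tail_mass(mu_b, sd_b, min_effect)
    lo, hi = min(p_a, p_b), max(p_a, p_b)
    if not lo <= target <= hi:
        raise UnachievablePrevalence(target, (lo, hi), model_name)
    if p_b == p_a:  # any weight works; degenerate but well-defined
        return 0.0
    return (target - p_a) / (p_b - p_a)


def solve_sd_for_prevalence(target: float, min_effect: float = DEFAULT_MIN_EFFECT) -> float:
    """SD of a zero-centered normal with P(|X| > min_effect) = target.

    Closed form: sd = min_effect / Phi^{-1}(1 - target/2). No finite SD
    yields prevalence 0 or 1, so those targets are rejected.
    """
    _check_min_effect(min_effect)
    if not 0.0 < target < 1.0:
        raise ValueError(f"target prevalence must lie strictly in (0, 1), got {target}")
    return min_effect / stats.norm.ppf(1.0 - target / 2.0)


def _truncated_abs_moment(mu: float, sd: float, min_effect: float) -> float:
    """E[|X| · 1{|X| > m}] for X ~ N(mu, sd) (unnormalized partial moment)."""
    if sd == 0:
        return abs(mu) if abs(mu) > min_effect else 0.0
    a = (min_effect - mu) / sd
    b = (-min_effect - mu) / sd
    # E[X 1{X > m}] - E[X 1{X < -m}]; the left tail contributes -X = |X|.
    upper = mu * stats.norm.sf(a) + sd * stats.norm.pdf(a)
    lower = mu * stats.norm.cdf(b) - sd * stats.norm.pdf(b)
    return float(upper - lower)


def typical_true_effect(
    dist: EffectDistribution,
    min_effect: float = DEFAULT_MIN_EFFECT,
    method: str = "analytic",
    rng: np.random.Generator | None = None,
    n_draws: int = 100_000,
) -> float:
    """Mean absolute effect size among true effects: E[|ES| given |ES| > m].

    This is the "typical" true effect a researcher in the field might plan
    a study around, and it is the reference effect for power-based sample
    sizing. ``method='analytic'`` uses truncated-normal partial moments;
    ``method='monte_carlo'`` estimates it from ``n_draws`` samples (100,000
    by default), mirroring how a simulation-only pipeline would obtain it.
    """
    prev = true_prevalence(dist, min_effect)
    if prev <= 0:
        raise ValueError("typical_true_effect undefined: prevalence of true effects is 0")
    if method == "analytic":
        partial = (1.0 - dist.w_b) * _truncated_abs_moment(0.0, dist.sd_a, min_effect)
        partial += dist.w_b * _truncated_abs_moment(dist.mu_b, dist.sd_b, min_effect)
        return partial / prev
    if method == "monte_carlo":
        if rng is None:
            rng = np.random.default_rng()
        draws = sample_effects(dist, n_draws, rng)
        true_mask = np.abs(draws) > min_effect
        if not true_mask.any():
            raise ValueError("no true effects among Monte-Carlo draws; prevalence too low")
        return float(np.abs(draws[true_mask]).mean())
    raise ValueError(f"method must be 'analytic' or 'monte_carlo', got {method!r}")


def with_weight(dist: EffectDistribution, w_b: float) -> EffectDistribution:
    """Copy of ``dist`` with a different mixture weight."""
    return replace(dist, w_b=w_b)


def _check_min_effect(min_effect: float) -> None:
    if min_effect <= 0:
        raise ValueError(f"min_effect must be > 0, got {min_effect}")
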
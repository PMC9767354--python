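"""Accuracy metrics of a simulated published literature.

Four views of how wrong a significance-filtered literature can be:

* **PPV** — the fraction of published findings that are true positives
  (true effect above the minimum of interest, estimate correctly signed).
* **Type S error rate** — the fraction of published estimates whose sign
  is opposite to the true effect's, over all published findings. Undefined
  when a true effect is exactly zero, so the dichotomous model is excluded.
* **Type M error (exaggeration factor)** — estimate / true effect among
  correctly-signed findings, summarized by median and interquartile range.
  Significance filtering inflates this ratio, especially at low power.
* **p-curve** — the distribution of published (hence significant)
  p-values on (0, alpha]; right-skew signals true effects, flatness a
  null-plus-selection literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .literature import PublishedLiterature

__all__ = [
    "LiteratureSummary",
    "ppv",
    "type_s_rate",
    "type_m_summary",
    "p_curve",
    "summarize",
]


@dataclass
class LiteratureSummary:
    """Aggregate metrics of one simulated literature."""

    ppv: float
    n_tp: int
    n_fp: int
    median_p: float
    achieved_prevalence: float
    achieved_power: float
    n_per_group: int
    type_s_rate: float | None = None
    type_m_median: float | None = None
    type_m_q25: float | None = None
    type_m_q75: float | None = None


def ppv(lit: PublishedLiterature) -> float:
    """Positive predictive value: share of published findings that are TP."""
    f = lit.findings
    if f.empty:
        raise ValueError("cannot compute PPV of an empty literature")
    return float((f["classification"] == "TP").mean())


def type_s_rate(lit: PublishedLiterature) -> float:
    """Share of published estimates signed opposite to their true effect.

    Counted over all published findings, regardless of whether the true
    effect clears the minimum of interest.
    """
    f = lit.findings
    if f.empty:
        raise ValueError("cannot compute type S rate of an empty literature")
    if (f["true_es"] == 0).any():
        raise ValueError(
            "type S error is undefined for true effects exactly at zero; "
            "exclude the dichotomous model from sign-error analyses"
        )
    return float((~f["sign_correct"]).mean())


def type_m_summary(lit: PublishedLiterature) -> tuple[float, float, float]:
    """(median, q25, q75) of the exaggeration factor estimate/true_es.

    Computed only over correctly-signed findings (the ratio is then always
    positive); wrong-sign findings are sign errors, not magnitude errors.
    Quantiles use linear interpolation between order statistics.
    """
    f = lit.findings
    correct = f[f["sign_correct"]]
    if correct.empty:
        raise ValueError("no correctly-signed findings: exaggeration factor undefined")
    ratio = correct["estimate"] / correct["true_es"]
    q25, med, q75 = np.quantile(ratio, [0.25, 0.5, 0.75])
    return float(med), float(q25), float(q75)


def p_curve(
    lit: PublishedLiterature, bin_width: float = 0.005
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of published p-values over (0, alpha], plus their median.

    Returns (counts, bin_edges, median_p); counts sum to the literature
    size. Default bin width 0.005 gives 10 bins over (0, 0.05].
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    f = lit.findings
    if f.empty:
        raise ValueError("cannot build a p-curve from an empty literature")
    alpha = lit.config.power_spec.alpha
    n_bins = int(np.ceil(alpha / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(f["p_value"], bins=edges)
    return counts, edges, float(f["p_value"].median())


def summarize(lit: PublishedLiterature) -> LiteratureSummary:
    """All metrics in one record; sign/magnitude errors are skipped (None)
    for literatures containing exactly-zero true effects."""
    f = lit.findings
    n_tp = int((f["classification"] == "TP").sum())
    summary = LiteratureSummary(
        ppv=ppv(lit),
        n_tp=n_tp,
        n_fp=len(f) - n_tp,
        median_p=float(f["p_value"].median()),
        achieved_prevalence=lit.achieved_prevalence,
        achieved_power=lit.achieved_power,
        n_per_group=lit.n_per_group,
    )
    if not (f["true_es"] == 0).any():
        summary.type_s_rate = type_s_rate(lit)
        med, q25, q75 = type_m_summary(lit)
        summary.type_m_median, summary.type_m_q25, summary.type_m_q75 = med, q25, q75
    return summary
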
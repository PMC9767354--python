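"""Configuration loading, result serialization, and run manifests.

Configs are flat YAML key-value documents. Three request kinds are
recognised:

* a single-literature run (``model`` plus ``power``/``bias``/``prevalence``
  or explicit distribution parameters);
* a full scenario-table run (``table: table1``);
* a parameter sweep (``sweep: true`` with list-valued ``powers``,
  ``biases``, ``prevalences``).

Outputs are plain CSV with a header row, written next to a JSON manifest
echoing the resolved configuration and seed so any table can be traced to
— and reproduced from — one manifest.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from .distributions import (
    DEFAULT_MIN_EFFECT,
    EffectDistribution,
    make_distribution,
)
from .experiment import POWER_REFERENCES, PowerSpec
from .literature import PUBLICATION_RULES, PublishedLiterature, SimulationConfig
from .metrics import summarize
from .scenarios import SweepGrid, distribution_for_prevalence

__all__ = ["RunManifest", "load_config", "write_outputs", "config_to_dict"]

_RUN_KEYS = {
    "model",
    "power",
    "bias",
    "prevalence",
    "alpha",
    "min_effect",
    "rule",
    "n_published",
    "seed",
    "w_b",
    "sd_a",
    "power_reference",
}
_SWEEP_KEYS = {
    "sweep",
    "model",
    "powers",
    "biases",
    "prevalences",
    "alpha",
    "min_effect",
    "rule",
    "n_published",
    "seed",
    "power_reference",
}
_TABLE_KEYS = {"table", "n_published", "seed", "min_effect", "rule", "power_reference"}

_DEFAULTS = {
    "alpha": 0.05,
    "min_effect": DEFAULT_MIN_EFFECT,
    "rule": "significance_only",
    "n_published": 5000,
    "seed": 0,
    "power_reference": "typical_true_mean",
}


@dataclass
class RunManifest:
    """Provenance record written alongside every output table."""

    kind: str
    config: dict
    seed: int
    code_version: str
    created_utc: str
    outputs: list[str]


def _package_version() -> str:
    try:
        return version("litsim")
    except PackageNotFoundError:
        return "unknown"


def _check_probability(key: str, value: float, open_interval: bool = False) -> None:
    lo_ok = value > 0 if open_interval else value >= 0
    hi_ok = value < 1 if open_interval else value <= 1
    if not (lo_ok and hi_ok):
        raise ValueError(f"config key {key!r} must be a probability, got {value}")


def load_config(path: str | Path):
    """Parse and validate a YAML config into a runnable request.

    Returns a :class:`SimulationConfig`, a :class:`SweepGrid`, or the
    string ``"table1"`` for a full scenario-table request. Unknown keys
    are rejected; defaults are alpha 0.05, minimum effect 0.5, rule
    ``significance_only``, 5,000 published findings, seed 0.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value document")
    if "table" in raw:
        allowed = _TABLE_KEYS
    elif raw.get("sweep"):
        allowed = _SWEEP_KEYS
    else:
        allowed = _RUN_KEYS
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**_DEFAULTS, **raw}

    for key in ("bias", "prevalence", "alpha", "power"):
        if key in cfg and cfg[key] is not None and not isinstance(cfg[key], (list, tuple)):
            _check_probability(key, float(cfg[key]), open_interval=key in ("alpha", "power"))
    if cfg["rule"] not in PUBLICATION_RULES:
        raise ValueError(f"rule must be one of {PUBLICATION_RULES}, got {cfg['rule']!r}")
    if cfg["power_reference"] not in POWER_REFERENCES:
        raise ValueError(f"power_reference must be one of {POWER_REFERENCES}")

    if "table" in raw:
        if raw["table"] != "table1":
            raise ValueError(f"unknown table request {raw['table']!r}")
        return "table1"

    if raw.get("sweep"):
        return SweepGrid(
            model_name=cfg["model"],
            powers=tuple(cfg.get("powers", (0.2, 0.5, 0.8))),
            biases=tuple(cfg.get("biases", (0.0, 0.2, 0.6))),
            prevalences=tuple(cfg.get("prevalences", (0.1, 0.3, 0.5, 0.7, 0.9))),
            alpha=cfg["alpha"],
            n_published=int(cfg["n_published"]),
            min_effect=cfg["min_effect"],
            publication_rule=cfg["rule"],
            power_reference=cfg["power_reference"],
        )

    if "model" not in cfg:
        raise ValueError("config must name a distribution model")
    dist = _resolve_distribution(cfg)
    return SimulationConfig(
        distribution=dist,
        power_spec=PowerSpec(
            power=float(cfg.get("power", 0.8)),
            alpha=cfg["alpha"],
            reference=cfg["power_reference"],
        ),
        bias=float(cfg.get("bias", 0.0)),
        min_effect=cfg["min_effect"],
        publication_rule=cfg["rule"],
        n_published_target=int(cfg["n_published"]),
        seed=int(cfg["seed"]),
    )


def _resolve_distribution(cfg: dict) -> EffectDistribution:
    model = cfg["model"]
    if "prevalence" in cfg and cfg["prevalence"] is not None:
        return distribution_for_prevalence(model, float(cfg["prevalence"]), cfg["min_effect"])
    if model == "single_normal":
        return make_distribution(model, sd_a=float(cfg["sd_a"]))
    return make_distribution(model, w_b=float(cfg["w_b"]))


def config_to_dict(config: SimulationConfig) -> dict:
    """Flat, YAML/JSON-serializable echo of a simulation configuration."""
    dist = config.distribution
    return {
        "model": dist.model_name,
        "sd_a": dist.sd_a,
        "mu_b": dist.mu_b,
        "sd_b": dist.sd_b,
        "w_b": dist.w_b,
        "min_effect": config.min_effect,
        "power": config.power_spec.power,
        "alpha": config.power_spec.alpha,
        "power_reference": config.power_spec.reference,
        "bias": config.bias,
        "rule": config.publication_rule,
        "n_published": config.n_published_target,
        "seed": config.seed,
    }


def write_outputs(
    result: PublishedLiterature | pd.DataFrame,
    out_dir: str | Path,
    kind: str = "run",
    config: dict | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Write findings/summary CSVs plus a JSON manifest to ``out_dir``.

    A :class:`PublishedLiterature` produces ``findings.csv`` (one row per
    published finding) and ``summary.csv``; a DataFrame (table or sweep
    output) produces ``summary.csv`` alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    if isinstance(result, PublishedLiterature):
        findings_path = out / "findings.csv"
        result.findings.to_csv(findings_path, index=False)
        outputs.append(str(findings_path))
        summary = pd.DataFrame([asdict(summarize(result))])
        config = config or config_to_dict(result.config)
        seed = result.config.seed if seed is None else seed
    else:
        summary = result
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)
    outputs.append(str(summary_path))

    manifest = RunManifest(
        kind=kind,
        config=config or {},
        seed=-1 if seed is None else int(seed),
        code_version=_package_version(),
        created_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=outputs,
    )
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest
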
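"""Declarative run configuration: a versioned YAML schema.

A config file is a mapping with up to five sections — ``rule``,
``feedback``, ``layout``, ``run`` — plus ``schema_version``.  Every key
is optional and falls back to the documented default; unknown keys are
rejected with the offending name.  All module-level parameter
invariants are enforced at load time, so an invalid file fails before
any simulation starts.  Example::

    schema_version: 1
    rule: {k: 0.1, b: 0.5, variant: inertia_adjusted}
    feedback: {f_coeff: 0.8, tie_rule: block}
    layout: {grid_size: 4, cf_prob: 0.5}
    run: {seed: 1, n_trials: 3000, variant: full, l0: 0.5}
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import N_TRIALS_POPULATION, POPULATION_VARIANTS
from .errors import ConfigurationError
from .feedback import FeedbackParams
from .rules import RuleParams
from .schedules import PopulationLayout

__all__ = ["SCHEMA_VERSION", "RunConfig", "load_config", "dump_config", "config_hash"]

SCHEMA_VERSION = 1

_RULE_KEYS = ("k", "b", "variant", "inertia_strength", "eps")
_FEEDBACK_KEYS = ("f_coeff", "tie_rule")
_LAYOUT_KEYS = ("grid_size", "cf_prob")
_RUN_KEYS = ("seed", "n_trials", "variant", "l0")
_TOP_KEYS = ("schema_version", "rule", "feedback", "layout", "run")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for a population run."""

    rule: RuleParams = field(default_factory=lambda: RuleParams(variant="inertia_adjusted"))
    feedback: FeedbackParams = field(default_factory=FeedbackParams)
    layout: PopulationLayout = field(default_factory=PopulationLayout)
    seed: int = 0
    n_trials: int = N_TRIALS_POPULATION
    variant: str = "full"
    l0: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError(f"n_trials must be >= 1; got {self.n_trials}")
        if self.variant not in POPULATION_VARIANTS:
            raise ConfigurationError(
                f"run.variant must be one of {POPULATION_VARIANTS}; got {self.variant!r}"
            )
        if not 0.0 < self.l0 < 1.0:
            raise ConfigurationError(f"l0 must lie in (0, 1); got {self.l0}")


def _check_keys(section: str, mapping: dict, allowed: tuple[str, ...]) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigurationError(
                f"unknown key {key!r} in section {section!r}; allowed: {allowed}"
            )


def from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a plain mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys("<root>", data, _TOP_KEYS)
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported schema_version {version}; this build reads {SCHEMA_VERSION}"
        )
    rule_d = dict(data.get("rule") or {})
    fb_d = dict(data.get("feedback") or {})
    layout_d = dict(data.get("layout") or {})
    run_d = dict(data.get("run") or {})
    _check_keys("rule", rule_d, _RULE_KEYS)
    _check_keys("feedback", fb_d, _FEEDBACK_KEYS)
    _check_keys("layout", layout_d, _LAYOUT_KEYS)
    _check_keys("run", run_d, _RUN_KEYS)
    rule_d.setdefault("variant", "inertia_adjusted")
    return RunConfig(
        rule=RuleParams(**rule_d),
        feedback=FeedbackParams(**fb_d),
        layout=PopulationLayout(**layout_d),
        seed=int(run_d.get("seed", 0)),
        n_trials=int(run_d.get("n_trials", N_TRIALS_POPULATION)),
        variant=str(run_d.get("variant", "full")),
        l0=float(run_d.get("l0", 0.5)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return from_dict(data or {})


def dump_config(cfg: RunConfig) -> dict:
    """Serialise a RunConfig to a plain dict (round-trips via from_dict)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "rule": {
            "k": cfg.rule.k,
            "b": cfg.rule.b,
            "variant": cfg.rule.variant,
            "inertia_strength": cfg.rule.inertia_strength,
            "eps": cfg.rule.eps,
        },
        "feedback": {"f_coeff": cfg.feedback.f_coeff, "tie_rule": cfg.feedback.tie_rule},
        "layout": {"grid_size": cfg.layout.grid_size, "cf_prob": cfg.layout.cf_prob},
        "run": {
            "seed": cfg.seed,
            "n_trials": cfg.n_trials,
            "variant": cfg.variant,
            "l0": cfg.l0,
        },
    }


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the effective configuration."""
    canon = json.dumps(dump_config(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
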
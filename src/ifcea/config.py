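"""YAML run configuration: defaults, validation, round-tripping, digest.

A single config document drives the whole pipeline: base-population
marginals, expansion size, Markov shape rates and calibration targets,
disability weights, discounting, costs, willingness-to-pay, one-way
bounds and PSA distributions, plus seeds. Every random operation takes
its seed from here so reruns are byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["ConfigError", "default_config", "load_config", "save_config", "config_digest"]


class ConfigError(ValueError):
    """A malformed configuration; the message names the offending key."""


def default_config() -> dict:
    """The base-case configuration (study conditions)."""
    return {
        "seed": 42,
        "output_dir": "outputs",
        "population": {
            "n_base": 1707,
            "p_age_band": [469 / 1707, 595 / 1707, 643 / 1707],
            "p_sex": [872 / 1707, 835 / 1707],
            "p_wealth": [299 / 1707, 323 / 1707, 368 / 1707, 403 / 1707, 314 / 1707],
            "p_anaemia_state": [705 / 1707, 410 / 1707, 574 / 1707, 18 / 1707],
            "hb_mean_by_state": [12.0, 10.5, 8.5, 6.0],
            "hb_sd_by_state": [1.0, 0.5, 0.75, 0.5],
            "p_ifc_by_sex": [0.056, 0.043],
        },
        "expansion": {"n": 100000},
        "trajectory": {"n_cycles": 20, "cycle_days": 182.5, "mode": "cohort_fractions"},
        "transitions": {
            "worsening_rates": [0.15, 0.20, 0.01],
            "recovery_rates": [0.30, 0.30, 0.50],
            "anaemic_mix": [410 / 1002, 574 / 1002, 18 / 1002],
            "target_end_prevalence": {"non_ifc": 0.36, "ifc": 0.27},
            # null = use the cohort's empirical prevalence
            "start_prevalence": {"non_ifc": None, "ifc": None},
            # pooled: both arms start from the whole cohort's state
            # fractions (arms share a baseline distribution by design);
            # per_arm: each arm uses its own subgroup's fractions
            "baseline_occupancy": "pooled",
            # null = calibrate the worsening relative risk to the IFC target
            "ifc_relative_risk": None,
        },
        "disability_weights": {"mild": 0.004, "moderate": 0.052, "severe": 0.149},
        "discount": {"annual_rate": 0.03, "grace_years": 1.0},
        "costs": {
            "home_food_per_day": 0.37,
            "ifc_increment_per_day": 0.17,
            "intervention_months": 18,
            "days_per_month": 30.0,
        },
        "wtp": {"gdp_per_capita_per_day": 6.6, "multiplier": 1.0},
        "population_under2": 4058000,
        "cost_per_disability_day_saved": 1.92,
        "one_way": {
            # relative half-widths around base values
            "cost_rel_bound": 0.20,
            "rate_rel_bound": 0.20,
        },
        "psa": {
            "n_runs": 1000,
            "cohort_n": 100000,
            "wtp_grid": {"start": 0.0, "stop": 20.0, "num": 81},
            "distributions": [
                {"name": "home_food_per_day", "kind": "gamma", "mean": 0.37,
                 "ci95_low": 0.296, "ci95_high": 0.444},
                {"name": "ifc_increment_per_day", "kind": "gamma", "mean": 0.17,
                 "ci95_low": 0.13, "ci95_high": 0.21},
                {"name": "dw_mild", "kind": "beta", "mean": 0.004,
                 "ci95_low": 0.001, "ci95_high": 0.008},
                {"name": "dw_moderate", "kind": "beta", "mean": 0.052,
                 "ci95_low": 0.034, "ci95_high": 0.076},
                {"name": "dw_severe", "kind": "beta", "mean": 0.149,
                 "ci95_low": 0.101, "ci95_high": 0.21},
                # mean null = use the value calibrated at fit time, with
                # the stated relative 95% CI half-width
                {"name": "ifc_relative_risk", "kind": "beta", "mean": None,
                 "rel_ci": 0.20},
                {"name": "recovery_multiplier", "kind": "gamma", "mean": None,
                 "rel_ci": 0.20},
            ],
        },
    }


_REQUIRED = [
    "seed",
    "population",
    "population.n_base",
    "population.p_anaemia_state",
    "expansion.n",
    "trajectory.n_cycles",
    "trajectory.cycle_days",
    "transitions.worsening_rates",
    "transitions.recovery_rates",
    "transitions.target_end_prevalence.non_ifc",
    "transitions.target_end_prevalence.ifc",
    "disability_weights.mild",
    "disability_weights.moderate",
    "disability_weights.severe",
    "discount.annual_rate",
    "costs.home_food_per_day",
    "costs.ifc_increment_per_day",
    "costs.intervention_months",
    "wtp.gdp_per_capita_per_day",
]


def _get(cfg: dict, dotted: str):
    node = cfg
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"missing required config key: {dotted!r}")
        node = node[part]
    if node is None:
        raise ConfigError(f"missing required config key: {dotted!r} (null value)")
    return node


def validate_config(cfg: dict) -> dict:
    """Check required keys and basic value sanity; returns the config."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for key in _REQUIRED:
        _get(cfg, key)
    if int(_get(cfg, "expansion.n")) < 1:
        raise ConfigError("config key 'expansion.n' must be >= 1")
    if int(_get(cfg, "trajectory.n_cycles")) < 1:
        raise ConfigError("config key 'trajectory.n_cycles' must be >= 1")
    for key in ("non_ifc", "ifc"):
        v = _get(cfg, f"transitions.target_end_prevalence.{key}")
        if not 0.0 < float(v) < 1.0:
            raise ConfigError(
                f"config key 'transitions.target_end_prevalence.{key}' must lie in (0, 1)"
            )
    rate = float(_get(cfg, "discount.annual_rate"))
    if not 0.0 <= rate < 1.0:
        raise ConfigError("config key 'discount.annual_rate' must lie in [0, 1)")
    for key in ("home_food_per_day", "ifc_increment_per_day"):
        if float(_get(cfg, f"costs.{key}")) < 0:
            raise ConfigError(f"config key 'costs.{key}' must be non-negative")
    return cfg


def merge_defaults(cfg: dict) -> dict:
    """Deep-merge a partial config over the defaults."""

    def merge(base, over):
        out = copy.deepcopy(base)
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(out.get(k), dict):
                out[k] = merge(out[k], v)
            else:
                out[k] = copy.deepcopy(v)
        return out

    return merge(default_config(), cfg or {})


def load_config(path, use_defaults: bool = True) -> dict:
    """Read, (optionally) default-fill and validate a YAML config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    cfg = merge_defaults(raw) if use_defaults else raw
    return validate_config(cfg)


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_digest(cfg: dict) -> str:
    """Stable sha256 digest of the canonical JSON form of a config."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
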
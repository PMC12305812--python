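"""One-way (tornado) and probabilistic sensitivity analysis.

The deterministic pipeline is re-evaluated either at individual
parameter bounds (one-way) or under Monte-Carlo draws of all uncertain
parameters (PSA): gamma distributions for costs, beta distributions for
probabilities, weights and risk ratios, parameterised by method of
moments from a mean and 95% CI (SD = CI width / 3.92, the normal
approximation). PSA output feeds the cost-effectiveness acceptability
curve (CEAC): at each willingness-to-pay the fraction of draws with
non-negative net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cea import net_monetary_benefit

__all__ = [
    "ParamDistribution",
    "OneWayResult",
    "PSAResult",
    "CEACCurve",
    "fit_gamma_from_ci",
    "fit_beta_from_ci",
    "one_way",
    "run_psa",
    "ceac",
]

_Z95_WIDTH = 3.92  # 2 * 1.96


def fit_gamma_from_ci(mean: float, ci95_low: float, ci95_high: float):
    """Method-of-moments gamma (shape, scale) from a mean and 95% CI.

    SD is taken as (high - low)/3.92; shape = mean^2/var, scale =
    var/mean, so the fitted mean equals the input exactly.
    """
    if not (0 < ci95_low < mean < ci95_high):
        raise ValueError(
            f"need 0 < ci95_low < mean < ci95_high, got ({ci95_low}, {mean}, {ci95_high})"
        )
    sd = (ci95_high - ci95_low) / _Z95_WIDTH
    var = sd * sd
    if var <= 0:
        raise ValueError("degenerate CI gives non-positive variance")
    return mean * mean / var, var / mean


def fit_beta_from_ci(mean: float, ci95_low: float, ci95_high: float):
    """Method-of-moments beta (alpha, beta) from a mean and 95% CI."""
    if not 0 < mean < 1:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if not (0 < ci95_low < mean < ci95_high < 1):
        raise ValueError(
            f"need 0 < ci95_low < mean < ci95_high < 1, got ({ci95_low}, {mean}, {ci95_high})"
        )
    sd = (ci95_high - ci95_low) / _Z95_WIDTH
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError(
            f"variance {var:.3g} >= mean(1-mean) = {mean * (1 - mean):.3g}: "
            "no beta distribution matches"
        )
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


@dataclass
class ParamDistribution:
    """Uncertainty specification for one model parameter.

    ``kind`` is "gamma" (costs), "beta" (probabilities/weights/risk
    ratios) or "fixed". For one-way analysis ``low``/``high`` bounds are
    used; if absent they default to the CI bounds.
    """

    name: str
    kind: str
    mean: float
    ci95_low: float | None = None
    ci95_high: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.kind not in ("gamma", "beta", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "gamma" and self.mean <= 0:
            raise ValueError(f"{self.name}: gamma mean must be positive")
        if self.kind == "beta" and not 0 < self.mean < 1:
            raise ValueError(f"{self.name}: beta mean must lie in (0, 1)")
        if self.kind != "fixed":
            if self.ci95_low is None or self.ci95_high is None:
                raise ValueError(f"{self.name}: non-fixed parameters need a 95% CI")
            if not self.ci95_low < self.mean < self.ci95_high:
                raise ValueError(
                    f"{self.name}: CI ({self.ci95_low}, {self.ci95_high}) must bracket "
                    f"the mean {self.mean}"
                )

    def bounds(self) -> tuple[float, float]:
        lo = self.low if self.low is not None else self.ci95_low
        hi = self.high if self.high is not None else self.ci95_high
        if lo is None or hi is None:
            return self.mean, self.mean
        return float(lo), float(hi)

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.kind == "gamma":
            shape, scale = fit_gamma_from_ci(self.mean, self.ci95_low, self.ci95_high)
            return rng.gamma(shape, scale, size=size)
        a, b = fit_beta_from_ci(self.mean, self.ci95_low, self.ci95_high)
        return rng.beta(a, b, size=size)


@dataclass
class OneWayResult:
    """Tornado table: per-parameter ICER at its low/high bound."""

    table: pd.DataFrame  # parameter, low, high, low_icer, base_icer, high_icer, swing
    base_icer: float

    def parameters(self) -> list[str]:
        return list(self.table["parameter"])


def one_way(
    pipeline: Callable[[dict], float],
    base_params: dict,
    bounds: dict[str, tuple[float, float]],
) -> OneWayResult:
    """Vary each parameter to its bounds, all else at base values.

    ``pipeline`` maps a full parameter dict to an ICER. Rows are sorted
    by descending swing = |high_icer - low_icer|.
    """
    base_icer = pipeline(dict(base_params))
    rows = []
    for name, (lo, hi) in bounds.items():
        if name not in base_params:
            raise ValueError(f"unknown parameter {name!r} in one-way bounds")
        base_val = base_params[name]
        if not lo <= base_val <= hi:
            raise ValueError(
                f"{name}: bounds ({lo}, {hi}) do not bracket base value {base_val}"
            )
        if lo < 0 and name.startswith(("home_food", "ifc_", "dw_")):
            raise ValueError(f"{name}: negative bound {lo} is invalid")
        icers = []
        for v in (lo, hi):
            p = dict(base_params)
            p[name] = v
            icers.append(pipeline(p))
        rows.append(
            {
                "parameter": name,
                "low": lo,
                "high": hi,
                "low_icer": icers[0],
                "base_icer": base_icer,
                "high_icer": icers[1],
                "swing": abs(icers[1] - icers[0]),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("swing", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return OneWayResult(table=table, base_icer=base_icer)


@dataclass
class PSAResult:
    """Probabilistic sensitivity analysis draws and summaries."""

    samples: pd.DataFrame  # delta_cost, delta_effect, icer (+ drawn params)
    median_icer: float
    iqr: tuple[float, float]
    n_runs: int
    cohort_n: int
    seed: int
    failures: list = field(default_factory=list)
    by_stratum: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.samples) + len(self.failures) != self.n_runs:
            raise ValueError("samples + failures must account for every run")


def run_psa(
    pipeline: Callable[[dict], tuple[float, float, float]],
    base_params: dict,
    distributions: list[ParamDistribution],
    n_runs: int = 1000,
    cohort_n: int = 100_000,
    seed: int = 0,
) -> PSAResult:
    """Monte-Carlo the pipeline under parameter uncertainty.

    Per run, every non-fixed parameter is drawn from its distribution
    and ``pipeline`` returns (delta_cost, delta_effect, icer); runs
    raising ValueError are recorded as failures and excluded from
    summaries. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    names = [d.name for d in distributions]
    if len(set(names)) != len(names):
        raise ValueError("duplicate parameter names in distributions")
    draws = {d.name: d.sample(rng, size=n_runs) for d in distributions}

    records, failures = [], []
    for i in range(n_runs):
        params = dict(base_params)
        for name in names:
            params[name] = float(draws[name][i])
        try:
            d_cost, d_effect, icer_val = pipeline(params)
        except (ValueError, ZeroDivisionError) as exc:
            failures.append({"run": i, "reason": str(exc)})
            continue
        rec = {"run": i, "delta_cost": d_cost, "delta_effect": d_effect, "icer": icer_val}
        rec.update({name: params[name] for name in names})
        records.append(rec)

    samples = pd.DataFrame(records)
    if len(samples) == 0:
        raise RuntimeError(f"all {n_runs} PSA runs failed; first: {failures[0]}")
    med = float(samples["icer"].median())
    q25, q75 = (float(samples["icer"].quantile(q)) for q in (0.25, 0.75))
    return PSAResult(
        samples=samples,
        median_icer=med,
        iqr=(q25, q75),
        n_runs=n_runs,
        cohort_n=cohort_n,
        seed=seed,
        failures=failures,
    )


@dataclass
class CEACCurve:
    """Acceptability probability as a function of willingness-to-pay."""

    wtp_grid: np.ndarray
    p_cost_effective: np.ndarray

    def __post_init__(self):
        self.wtp_grid = np.asarray(self.wtp_grid, dtype=float)
        self.p_cost_effective = np.asarray(self.p_cost_effective, dtype=float)
        if self.wtp_grid.shape != self.p_cost_effective.shape:
            raise ValueError("grid and probabilities must align")
        if np.any(self.p_cost_effective < 0) or np.any(self.p_cost_effective > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return float(self.p_cost_effective[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp_grid, "p_cost_effective": self.p_cost_effective}
        )


def ceac(psa: PSAResult, wtp_grid) -> CEACCurve:
    """Fraction of PSA draws acceptable (NMB >= 0) at each WTP value.

    ``delta_effect`` in the PSA samples is the health gain (disability
    days averted); when all gains are non-negative the curve is monotone
    non-decreasing in WTP.
    """
    if len(psa.samples) == 0:
        raise ValueError("PSA has no successful runs")
    grid = np.asarray(wtp_grid, dtype=float)
    d_eff = psa.samples["delta_effect"].to_numpy()
    d_cost = psa.samples["delta_cost"].to_numpy()
    probs = np.empty(len(grid))
    for k, lam in enumerate(grid):
        nmb = net_monetary_benefit(d_eff, d_cost, float(lam))
        probs[k] = float((nmb >= 0).mean())
    return CEACCurve(wtp_grid=grid, p_cost_effective=probs)
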
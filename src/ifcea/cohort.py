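"""Synthetic survey-like cohort generation and Monte-Carlo expansion.

Emulates the structure of a national family-health-survey extract of
children aged 6 to <24 months: age band, sex, household wealth quintile,
haemoglobin, anaemia severity and a fortified-infant-cereal (IFC)
consumption flag. Only marginal frequencies are configured; fields are
sampled independently (haemoglobin conditionally on severity state),
reflecting that the source survey reported no significant associations
between the stratification variables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .states import AnaemiaState, HB_INTERVALS, STATE_NAMES, categorize_anaemia_array

__all__ = [
    "AGE_BANDS",
    "SEXES",
    "BasePopulationSpec",
    "Cohort",
    "CohortSummary",
    "sample_base_cohort",
    "expand_cohort",
    "summarize_cohort",
]

AGE_BANDS = ["6-<12", "12-<18", "18-<24"]
SEXES = ["boy", "girl"]

_PROB_TOL = 1e-12


def _check_probvec(p, n, name) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} must sum to 1 within {_PROB_TOL}, got {p.sum()!r}")
    return p


@dataclass(frozen=True)
class BasePopulationSpec:
    """Marginal distributions of the base (survey-like) cohort.

    Defaults reproduce the survey counts of 1,707 children aged 6 to
    <24 months: age bands 469/595/643, sexes 872/835, wealth quintiles
    299/323/368/403/314, anaemia states 705/410/574/18, and IFC
    consumption 5.6% among boys and 4.3% among girls.

    Haemoglobin is drawn from a per-state normal truncated to that
    state's Hb interval, so ``state`` and ``hb`` are always consistent.
    """

    n_base: int = 1707
    p_age_band: tuple = (469 / 1707, 595 / 1707, 643 / 1707)
    p_sex: tuple = (872 / 1707, 835 / 1707)
    p_wealth: tuple = (299 / 1707, 323 / 1707, 368 / 1707, 403 / 1707, 314 / 1707)
    p_anaemia_state: tuple = (705 / 1707, 410 / 1707, 574 / 1707, 18 / 1707)
    hb_mean_by_state: tuple = (12.0, 10.5, 8.5, 6.0)
    hb_sd_by_state: tuple = (1.0, 0.5, 0.75, 0.5)
    p_ifc_by_sex: tuple = (0.056, 0.043)
    seed: int = 0

    def validate(self) -> "BasePopulationSpec":
        if self.n_base < 1:
            raise ValueError("n_base must be >= 1")
        _check_probvec(self.p_age_band, 3, "p_age_band")
        _check_probvec(self.p_sex, 2, "p_sex")
        _check_probvec(self.p_wealth, 5, "p_wealth")
        _check_probvec(self.p_anaemia_state, 4, "p_anaemia_state")
        sd = np.asarray(self.hb_sd_by_state, dtype=float)
        if sd.shape != (4,) or np.any(sd <= 0):
            raise ValueError("hb_sd_by_state must be 4 positive values")
        mu = np.asarray(self.hb_mean_by_state, dtype=float)
        if mu.shape != (4,) or not np.all(np.isfinite(mu)):
            raise ValueError("hb_mean_by_state must be 4 finite values")
        ifc = np.asarray(self.p_ifc_by_sex, dtype=float)
        if ifc.shape != (2,) or np.any(ifc < 0) or np.any(ifc > 1):
            raise ValueError("p_ifc_by_sex must be 2 probabilities")
        return self

    def replace(self, **kw) -> "BasePopulationSpec":
        return replace(self, **kw)


@dataclass
class Cohort:
    """A collection of simulated child records backed by a DataFrame.

    Columns: ``id, age_band, sex, wealth_quintile, hb, state, ifc``.
    ``state`` holds integer severity codes (0=none .. 3=severe).
    """

    df: pd.DataFrame
    seed: int = 0
    provenance: str = ""

    COLUMNS = ["id", "age_band", "sex", "wealth_quintile", "hb", "state", "ifc"]

    def __post_init__(self):
        if len(self.df) == 0:
            raise ValueError("cohort must be non-empty")
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort missing columns: {missing}")
        if self.df["id"].duplicated().any():
            raise ValueError("cohort ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def states(self) -> np.ndarray:
        return self.df["state"].to_numpy()

    def state_fractions(self) -> np.ndarray:
        """Empirical occupancy 4-vector over severity states."""
        counts = np.bincount(self.states, minlength=4).astype(float)
        return counts / counts.sum()

    def arm_state_fractions(self, ifc: bool) -> np.ndarray:
        sub = self.df[self.df["ifc"] == ifc]
        if len(sub) == 0:
            raise ValueError(f"no records in arm ifc={ifc}")
        counts = np.bincount(sub["state"].to_numpy(), minlength=4).astype(float)
        return counts / counts.sum()

    def check_consistency(self) -> None:
        """Assert every hb is consistent with its state under categorisation."""
        got = categorize_anaemia_array(self.df["hb"].to_numpy())
        if not np.array_equal(got, self.states):
            bad = int((got != self.states).sum())
            raise AssertionError(f"{bad} records have hb inconsistent with state")

    def to_csv(self, path) -> None:
        out = self.df.loc[:, self.COLUMNS].copy()
        out["hb"] = out["hb"].map(lambda x: f"{x:.6f}")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = 0, provenance: str = "") -> "Cohort":
        df = pd.read_csv(path)
        df["ifc"] = df["ifc"].astype(bool)
        return cls(df=df, seed=seed, provenance=provenance)


def _truncnorm_hb(rng, states, mu, sd) -> np.ndarray:
    """Sample hb per record from the state-conditional truncated normal."""
    hb = np.empty(len(states), dtype=float)
    for s in AnaemiaState:
        mask = states == s.value
        if not mask.any():
            continue
        lo, hi = HB_INTERVALS[s]
        a = (lo - mu[s]) / sd[s]
        b = (hi - mu[s]) / sd[s]
        dist = stats.truncnorm(a, b, loc=mu[s], scale=sd[s])
        hb[mask] = dist.ppf(rng.random(int(mask.sum())))
        # guard the open upper bound: ppf can return hi to float precision
        hb[mask] = np.clip(hb[mask], lo, np.nextafter(hi, lo))
    return hb


def sample_base_cohort(spec: BasePopulationSpec, seed: int | None = None) -> Cohort:
    """Draw a base cohort of ``spec.n_base`` children from the marginals.

    Fields are independent except haemoglobin, which is drawn from the
    state-conditional truncated normal so severity and Hb agree.
    Deterministic given (spec, seed).
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.n_base

    age = rng.choice(3, size=n, p=np.asarray(spec.p_age_band, dtype=float))
    sex = rng.choice(2, size=n, p=np.asarray(spec.p_sex, dtype=float))
    wealth = rng.choice(5, size=n, p=np.asarray(spec.p_wealth, dtype=float)) + 1
    state = rng.choice(4, size=n, p=np.asarray(spec.p_anaemia_state, dtype=float))
    p_ifc = np.asarray(spec.p_ifc_by_sex, dtype=float)[sex]
    ifc = rng.random(n) < p_ifc
    hb = _truncnorm_hb(
        rng,
        state,
        np.asarray(spec.hb_mean_by_state, dtype=float),
        np.asarray(spec.hb_sd_by_state, dtype=float),
    )

    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "age_band": [AGE_BANDS[a] for a in age],
            "sex": [SEXES[s] for s in sex],
            "wealth_quintile": wealth.astype(np.int64),
            "hb": hb,
            "state": state.astype(np.int64),
            "ifc": ifc,
        }
    )
    cohort = Cohort(df=df, seed=seed, provenance=f"synthetic base cohort, seed={seed}")
    cohort.check_consistency()
    return cohort


def expand_cohort(base: Cohort, n: int, seed: int) -> Cohort:
    """Monte-Carlo expand a base cohort to ``n`` records by resampling.

    Records are drawn with replacement; ids are reassigned 0..n-1. Every
    joint category frequency converges to the base frequency as n grows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(base), size=n)
    df = base.df.iloc[idx].reset_index(drop=True).copy()
    df["id"] = np.arange(n, dtype=np.int64)
    return Cohort(
        df=df,
        seed=seed,
        provenance=f"expanded x{n} from base (seed={seed}); {base.provenance}",
    )


@dataclass
class CohortSummary:
    """Tidy counts/percentages by stratum plus the Hb mean and SD."""

    table: pd.DataFrame  # columns: variable, level, count, percent
    hb_mean: float
    hb_sd: float
    n: int

    def percent(self, variable: str, level) -> float:
        t = self.table
        row = t[(t["variable"] == variable) & (t["level"] == str(level))]
        if len(row) != 1:
            raise KeyError(f"no unique summary row for {variable}={level}")
        return float(row["percent"].iloc[0])

    def to_string(self) -> str:
        buf = io.StringIO()
        buf.write(f"Cohort summary (n={self.n})\n")
        buf.write(self.table.to_string(index=False))
        buf.write(f"\nHaemoglobin (g/dL): {self.hb_mean:.2f} +/- {self.hb_sd:.2f}\n")
        return buf.getvalue()


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Counts and percentages (2 dp) per state, sex, age band, wealth
    quintile and IFC flag, plus Hb mean and SD."""
    df = cohort.df
    n = len(df)
    rows = []

    def add(variable, levels, series):
        for lev in levels:
            count = int((series == lev).sum())
            rows.append(
                {
                    "variable": variable,
                    "level": str(lev),
                    "count": count,
                    "percent": round(100.0 * count / n, 2),
                }
            )

    add("state", list(range(4)), df["state"])
    # relabel states for readability
    for r, name in zip(rows, STATE_NAMES):
        r["level"] = name
    add("sex", SEXES, df["sex"])
    add("age_band", AGE_BANDS, df["age_band"])
    add("wealth_quintile", [1, 2, 3, 4, 5], df["wealth_quintile"])
    add("ifc", [True, False], df["ifc"])

    return CohortSummary(
        table=pd.DataFrame(rows),
        hb_mean=float(df["hb"].mean()),
        hb_sd=float(df["hb"].std(ddof=1)) if n > 1 else 0.0,
        n=n,
    )
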
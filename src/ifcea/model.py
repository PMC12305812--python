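"""Model/Results front end binding cohort, Markov, DALY and CEA stages.

:class:`AnaemiaCEA` is constructed from a virtual cohort and a run
configuration; :meth:`AnaemiaCEA.fit` calibrates the two-arm Markov
chain (recovery-rate level for the comparator arm, worsening relative
risk for the fortified-cereal arm), projects state occupancy over the
horizon, accumulates disability burden and evaluates costs, returning a
:class:`CEAResults` that carries the estimates, diagnostics and a
``summary()`` table, and from which one-way and probabilistic
sensitivity analyses and plots are produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sensitivity as sens
from .cea import CEAResult, CostInputs, WTPThreshold, population_savings, total_food_cost
from .cohort import BasePopulationSpec, Cohort, expand_cohort, sample_base_cohort, summarize_cohort
from .config import merge_defaults, validate_config
from .daly import DisabilityWeights, DiscountSpec, daly_difference, disability_days
from .markov import (
    CalibrationResult,
    StateTrajectory,
    TrajectorySpec,
    TransitionMatrix,
    TransitionShape,
    apply_relative_risk,
    calibrate_relative_risk,
    calibrate_transitions,
    simulate_cohort_fractions,
    simulate_individuals,
)

__all__ = ["AnaemiaCEA", "CEAResults", "ARM_IFC", "ARM_NON_IFC", "simulate_arms_individual"]

logger = logging.getLogger("ifcea")

ARM_IFC = "IFC"
ARM_NON_IFC = "non-IFC"
_ARM_FLAG = {ARM_IFC: True, ARM_NON_IFC: False}


def simulate_arms_individual(
    cohort: Cohort,
    matrices: dict[str, TransitionMatrix],
    spec: TrajectorySpec,
    seed: int,
) -> dict[str, StateTrajectory]:
    """Microsimulate each study arm of a cohort under its own matrix."""
    out = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(matrices))
    for (arm, m), sub_ss in zip(sorted(matrices.items()), child_seeds):
        if arm not in _ARM_FLAG:
            raise ValueError(f"unknown arm label {arm!r}; expected {sorted(_ARM_FLAG)}")
        states0 = cohort.df.loc[cohort.df["ifc"] == _ARM_FLAG[arm], "state"].to_numpy()
        if len(states0) == 0:
            raise ValueError(f"cohort has no children in arm {arm!r}")
        traj = simulate_individuals(
            states0, m, spec, seed=int(sub_ss.generate_state(1)[0] % (2**31))
        )
        traj.arm = arm
        out[arm] = traj
    return out


def _cohort_from_config(cfg: dict) -> Cohort:
    pop = cfg["population"]
    spec = BasePopulationSpec(
        n_base=int(pop["n_base"]),
        p_age_band=tuple(pop["p_age_band"]),
        p_sex=tuple(pop["p_sex"]),
        p_wealth=tuple(pop["p_wealth"]),
        p_anaemia_state=tuple(pop["p_anaemia_state"]),
        hb_mean_by_state=tuple(pop["hb_mean_by_state"]),
        hb_sd_by_state=tuple(pop["hb_sd_by_state"]),
        p_ifc_by_sex=tuple(pop["p_ifc_by_sex"]),
    )
    ss = np.random.SeedSequence(int(cfg["seed"]))
    s_base, s_expand = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    base = sample_base_cohort(spec, seed=s_base)
    n = int(cfg["expansion"]["n"])
    return expand_cohort(base, n, seed=s_expand) if n != len(base) else base


class AnaemiaCEA:
    """Cost-effectiveness model of iron-fortified cereals vs usual feeding.

    Parameters
    ----------
    cohort : Cohort
        Virtual cohort with baseline anaemia states and arm flags.
    config : dict, optional
        Run configuration (see :func:`ifcea.config.default_config`);
        partial configs are merged over the defaults.
    """

    def __init__(self, cohort: Cohort, config: dict | None = None):
        self.config = validate_config(merge_defaults(config or {}))
        self.cohort = cohort

    @classmethod
    def from_config(cls, config: dict | None = None) -> "AnaemiaCEA":
        """Build the model by generating the virtual cohort from config."""
        cfg = validate_config(merge_defaults(config or {}))
        return cls(_cohort_from_config(cfg), cfg)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: dict | None = None) -> "AnaemiaCEA":
        """Build the model from an existing cohort table (CSV columns)."""
        return cls(Cohort(df=df.copy()), config)

    # -- fitting -------------------------------------------------------

    def _arm_baseline(self, arm: str) -> tuple[float, np.ndarray]:
        """(start prevalence, anaemic mix) for one arm.

        An explicit config ``start_prevalence`` wins (with the configured
        anaemic mix); otherwise the cohort's empirical state fractions
        are used, pooled across arms by default since the generator
        draws the IFC flag independently of baseline state and the small
        IFC arm's own fractions are sampling-noise dominated. Set
        ``transitions.baseline_occupancy: per_arm`` for subgroup
        fractions.
        """
        tcfg = self.config["transitions"]
        override = (tcfg.get("start_prevalence") or {}).get(
            "ifc" if arm == ARM_IFC else "non_ifc"
        )
        if override is not None:
            return float(override), np.asarray(tcfg["anaemic_mix"], dtype=float)
        if tcfg.get("baseline_occupancy", "pooled") == "per_arm":
            frac = self.cohort.arm_state_fractions(_ARM_FLAG[arm])
        else:
            frac = self.cohort.state_fractions()
        prev = 1.0 - frac[0]
        mix = frac[1:] / prev if prev > 0 else np.asarray(tcfg["anaemic_mix"], float)
        return float(prev), mix

    def fit(self, mode: str | None = None, seed: int | None = None) -> "CEAResults":
        """Calibrate, project, and evaluate; returns a :class:`CEAResults`.

        Parameters
        ----------
        mode : {"cohort_fractions", "individual_microsim"}, optional
            Projection mode; defaults to the config's trajectory mode.
        seed : int, optional
            Seed for the individual-level microsimulation (ignored in
            deterministic mode); defaults to the config seed.
        """
        cfg = self.config
        tcfg = cfg["transitions"]
        mode = mode or cfg["trajectory"]["mode"]
        spec = TrajectorySpec(
            n_cycles=int(cfg["trajectory"]["n_cycles"]),
            cycle_days=float(cfg["trajectory"]["cycle_days"]),
            mode=mode,
        )
        weights = DisabilityWeights(**cfg["disability_weights"])
        discount = DiscountSpec(**cfg["discount"])
        costs = CostInputs(**cfg["costs"])
        wtp = WTPThreshold(**cfg["wtp"])

        prev_non, mix_non = self._arm_baseline(ARM_NON_IFC)
        prev_ifc, mix_ifc = self._arm_baseline(ARM_IFC)
        shape = TransitionShape(
            worsening_rates=tuple(tcfg["worsening_rates"]),
            recovery_rates=tuple(tcfg["recovery_rates"]),
            anaemic_mix=tuple(mix_non),
            arm=ARM_NON_IFC,
        )
        calib = calibrate_transitions(
            prev_non,
            float(tcfg["target_end_prevalence"]["non_ifc"]),
            spec.n_cycles,
            shape,
        )
        m_non = calib.matrix
        init_non = shape.init_occupancy(prev_non)
        init_ifc = np.concatenate([[1.0 - prev_ifc], prev_ifc * np.asarray(mix_ifc)])

        rr = tcfg.get("ifc_relative_risk")
        if rr is not None:
            rr = float(rr)
            m_ifc = apply_relative_risk(m_non, rr)
            m_ifc.arm = ARM_IFC
        else:
            m_ifc, rr = calibrate_relative_risk(
                m_non,
                init_ifc,
                float(tcfg["target_end_prevalence"]["ifc"]),
                spec.n_cycles,
                arm=ARM_IFC,
            )
        logger.info(
            "calibrated: recovery multiplier %.4f, IFC relative risk %.4f", calib.multiplier, rr
        )

        inits = {ARM_NON_IFC: init_non, ARM_IFC: init_ifc}
        matrices = {ARM_NON_IFC: m_non, ARM_IFC: m_ifc}
        if mode == "individual_microsim":
            sim_seed = int(cfg["seed"]) if seed is None else int(seed)
            trajectories = simulate_arms_individual(self.cohort, matrices, spec, sim_seed)
        else:
            trajectories = {
                arm: simulate_cohort_fractions(inits[arm], matrices[arm], spec)
                for arm in (ARM_NON_IFC, ARM_IFC)
            }

        burden = {
            arm: disability_days(trajectories[arm], weights, spec, discount)
            for arm in (ARM_NON_IFC, ARM_IFC)
        }
        cost = {
            ARM_IFC: total_food_cost(costs, with_ifc=True),
            ARM_NON_IFC: total_food_cost(costs, with_ifc=False),
        }
        cea = CEAResult.evaluate(
            cost[ARM_IFC],
            cost[ARM_NON_IFC],
            burden[ARM_IFC].disability_days,
            burden[ARM_NON_IFC].disability_days,
            wtp,
        )

        params = {
            "home_food_per_day": costs.home_food_per_day,
            "ifc_increment_per_day": costs.ifc_increment_per_day,
            "dw_mild": weights.mild,
            "dw_moderate": weights.moderate,
            "dw_severe": weights.severe,
            "ifc_relative_risk": float(rr),
            "recovery_multiplier": float(calib.multiplier),
        }
        return CEAResults(
            model=self,
            spec=spec,
            weights=weights,
            discount=discount,
            costs=costs,
            wtp=wtp,
            inits=inits,
            matrices=matrices,
            trajectories=trajectories,
            burden=burden,
            arm_costs=cost,
            cea=cea,
            calibration=calib,
            params=params,
            mode=mode,
        )


@dataclass
class CEAResults:
    """Fitted results: trajectories, burden, costs, ICER and diagnostics."""

    model: AnaemiaCEA
    spec: TrajectorySpec
    weights: DisabilityWeights
    discount: DiscountSpec
    costs: CostInputs
    wtp: WTPThreshold
    inits: dict
    matrices: dict
    trajectories: dict
    burden: dict
    arm_costs: dict
    cea: CEAResult
    calibration: CalibrationResult
    params: dict
    mode: str

    @property
    def config(self) -> dict:
        return self.model.config

    @property
    def averted(self):
        return daly_difference(self.burden[ARM_IFC], self.burden[ARM_NON_IFC])

    def end_prevalence(self, arm: str) -> float:
        return float(self.trajectories[arm].prevalence_series()[-1])

    # -- sensitivity pipeline ------------------------------------------

    def _pipeline(self, params: dict, inits: dict | None = None):
        """Recompute (delta_cost, days averted, ICER) at given parameters.

        Matrices are rebuilt from the stored structural worsening rates,
        the drawn recovery multiplier and relative risk; no
        re-calibration happens inside sensitivity analyses.
        """
        inits = inits or self.inits
        tcfg = self.config["transitions"]
        m_non = TransitionMatrix.from_rates(
            tcfg["worsening_rates"],
            params["recovery_multiplier"] * np.asarray(tcfg["recovery_rates"], float),
            arm=ARM_NON_IFC,
        )
        m_ifc = apply_relative_risk(m_non, params["ifc_relative_risk"])
        w = DisabilityWeights(
            mild=params["dw_mild"],
            moderate=params["dw_moderate"],
            severe=params["dw_severe"],
        )
        days = {}
        for arm, m in ((ARM_NON_IFC, m_non), (ARM_IFC, m_ifc)):
            traj = simulate_cohort_fractions(inits[arm], m, self.spec)
            days[arm] = disability_days(traj, w, self.spec, self.discount).disability_days
        c = CostInputs(
            home_food_per_day=params["home_food_per_day"],
            ifc_increment_per_day=params["ifc_increment_per_day"],
            intervention_months=self.costs.intervention_months,
            days_per_month=self.costs.days_per_month,
        )
        d_cost = total_food_cost(c, True) - total_food_cost(c, False)
        d_days = days[ARM_IFC] - days[ARM_NON_IFC]
        if d_days == 0:
            raise ValueError("equal arm effects: ICER undefined for this draw")
        return d_cost, -d_days, d_cost / d_days

    def _icer_pipeline(self, params: dict) -> float:
        return self._pipeline(params)[2]

    def default_one_way_bounds(self) -> dict:
        """Relative bounds around base values: costs at the configured
        cost half-width, weights and rate multipliers at the rate one."""
        ow = self.config["one_way"]
        cost_rel = float(ow["cost_rel_bound"])
        rate_rel = float(ow["rate_rel_bound"])
        bounds = {}
        for name, base in self.params.items():
            rel = cost_rel if name.endswith("per_day") else rate_rel
            lo, hi = base * (1 - rel), base * (1 + rel)
            if name == "ifc_relative_risk":
                hi = min(hi, 0.999)
            bounds[name] = (lo, hi)
        return bounds

    def one_way(self, bounds: dict | None = None) -> sens.OneWayResult:
        """Tornado analysis of the ICER over per-parameter bounds."""
        return sens.one_way(
            self._icer_pipeline, self.params, bounds or self.default_one_way_bounds()
        )

    def psa_distributions(self) -> list[sens.ParamDistribution]:
        """Config PSA distributions with calibrated means filled in."""
        dists = []
        for d in self.config["psa"]["distributions"]:
            d = dict(d)
            if d.get("mean") is None:
                base = self.params[d["name"]]
                rel = float(d.pop("rel_ci", 0.2))
                d["mean"] = base
                d["ci95_low"] = base * (1 - rel)
                d["ci95_high"] = base * (1 + rel)
                if d["kind"] == "beta":
                    d["ci95_high"] = min(d["ci95_high"], 0.5 * (1 + d["mean"]))
            d.pop("rel_ci", None)
            dists.append(sens.ParamDistribution(**d))
        return dists

    def run_psa(
        self,
        n_runs: int | None = None,
        cohort_n: int | None = None,
        seed: int | None = None,
        stratify_by: str | None = None,
        distributions: list | None = None,
    ) -> sens.PSAResult:
        """Probabilistic sensitivity analysis around the fitted base case.

        Each run redraws costs, disability weights and the two
        transition-rate parameters from their gamma/beta distributions
        and re-projects the deterministic pipeline. ``stratify_by``
        ("sex" or "wealth_quintile") additionally reports per-stratum
        median ICERs using stratum-specific baseline occupancies under
        the same parameter draws.
        """
        pcfg = self.config["psa"]
        n_runs = int(pcfg["n_runs"]) if n_runs is None else int(n_runs)
        cohort_n = int(pcfg["cohort_n"]) if cohort_n is None else int(cohort_n)
        seed = int(self.config["seed"]) if seed is None else int(seed)
        dists = distributions if distributions is not None else self.psa_distributions()

        result = sens.run_psa(
            lambda p: self._pipeline(p),
            self.params,
            dists,
            n_runs=n_runs,
            cohort_n=cohort_n,
            seed=seed,
        )
        if stratify_by is not None:
            if stratify_by not in ("sex", "wealth_quintile"):
                raise ValueError(f"cannot stratify by {stratify_by!r}")
            rows = []
            df = self.model.cohort.df
            for level in sorted(df[stratify_by].unique()):
                sub = Cohort(df=df[df[stratify_by] == level].copy())
                inits = {}
                for arm, flag in _ARM_FLAG.items():
                    frac = sub.arm_state_fractions(flag)
                    inits[arm] = frac
                strat = sens.run_psa(
                    lambda p: self._pipeline(p, inits=inits),
                    self.params,
                    dists,
                    n_runs=n_runs,
                    cohort_n=cohort_n,
                    seed=seed,
                )
                rows.append(
                    {
                        "stratum": f"{stratify_by}={level}",
                        "median_icer": strat.median_icer,
                        "iqr_low": strat.iqr[0],
                        "iqr_high": strat.iqr[1],
                        "n_runs": strat.n_runs - len(strat.failures),
                    }
                )
            result.by_stratum = pd.DataFrame(rows)
        return result

    def ceac(self, psa: sens.PSAResult | None = None, wtp_grid=None) -> sens.CEACCurve:
        """Cost-effectiveness acceptability curve from PSA draws."""
        if psa is None:
            psa = self.run_psa()
        if wtp_grid is None:
            g = self.config["psa"]["wtp_grid"]
            wtp_grid = np.linspace(float(g["start"]), float(g["stop"]), int(g["num"]))
        return sens.ceac(psa, wtp_grid)

    # -- reporting -----------------------------------------------------

    def population_savings(self):
        cfg = self.config
        return population_savings(
            float(cfg["cost_per_disability_day_saved"]), float(cfg["population_under2"])
        )

    def cea_frame(self) -> pd.DataFrame:
        """One-row-per-quantity CSV-ready view of the CEA result."""
        r = self.cea
        av = self.averted
        rows = [
            ("cost_ifc_usd", self.arm_costs[ARM_IFC]),
            ("cost_non_ifc_usd", self.arm_costs[ARM_NON_IFC]),
            ("daily_daly_ifc", self.burden[ARM_IFC].daily_daly),
            ("daily_daly_non_ifc", self.burden[ARM_NON_IFC].daily_daly),
            ("disability_days_ifc", self.burden[ARM_IFC].disability_days),
            ("disability_days_non_ifc", self.burden[ARM_NON_IFC].disability_days),
            ("discounted_disability_days_ifc", self.burden[ARM_IFC].discounted_disability_days),
            ("discounted_disability_days_non_ifc", self.burden[ARM_NON_IFC].discounted_disability_days),
            ("disability_days_averted", av.disability_days),
            ("daly_per_day_averted", av.daily_daly),
            ("incremental_cost_usd", r.incremental_cost),
            ("icer_usd_per_disability_day", r.icer_per_disability_day.value),
            ("icer_usd_per_daly", r.icer_per_daly),
            ("nmb_usd", r.nmb),
            ("end_prevalence_ifc", self.end_prevalence(ARM_IFC)),
            ("end_prevalence_non_ifc", self.end_prevalence(ARM_NON_IFC)),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def summary(self) -> str:
        """Human-readable report of the fitted cost-effectiveness analysis."""
        r = self.cea
        av = self.averted
        b_i, b_n = self.burden[ARM_IFC], self.burden[ARM_NON_IFC]
        sav = self.population_savings()
        cohort_summary = summarize_cohort(self.model.cohort)
        lines = [
            "Cost-effectiveness of iron-fortified infant cereals (IFC)",
            "=" * 60,
            f"cohort: n={len(self.model.cohort)} "
            f"(Hb {cohort_summary.hb_mean:.2f} +/- {cohort_summary.hb_sd:.2f} g/dL), "
            f"mode={self.mode}",
            f"horizon: {self.spec.n_cycles} cycles x {self.spec.cycle_days} days"
            f" = {self.spec.horizon_days:.0f} days",
            "",
            "Calibration",
            f"  recovery multiplier: {self.calibration.multiplier:.4f} "
            f"(end prevalence {self.calibration.achieved_end_prevalence:.4f})",
            f"  IFC worsening relative risk: {self.params['ifc_relative_risk']:.4f}",
            f"  anaemia prevalence at t1 -> t{self.spec.n_cycles}: "
            f"IFC {self.trajectories[ARM_IFC].prevalence_series()[0]:.3f} -> "
            f"{self.end_prevalence(ARM_IFC):.3f}; "
            f"non-IFC {self.trajectories[ARM_NON_IFC].prevalence_series()[0]:.3f} -> "
            f"{self.end_prevalence(ARM_NON_IFC):.3f}",
            "",
            "Indicator                                   IFC         non-IFC",
            f"DALY per day (total days, 10 years)  "
            f"{b_i.daily_daly:10.4f} ({b_i.disability_days:5.1f}) "
            f"{b_n.daily_daly:8.4f} ({b_n.disability_days:5.1f})",
            f"Cost of food per day (total, 18 months)  "
            f"{self.costs.home_food_per_day + self.costs.ifc_increment_per_day:6.3f} "
            f"({self.arm_costs[ARM_IFC]:6.1f})  "
            f"{self.costs.home_food_per_day:6.3f} ({self.arm_costs[ARM_NON_IFC]:6.1f}) USD",
            "",
            f"disability days averted over horizon: {av.disability_days:.2f} "
            f"(discounted {av.discounted_disability_days:.2f})",
            f"incremental cost: {r.incremental_cost:.2f} USD",
            f"ICER: {r.icer_per_disability_day.value:.3f} USD per disability day "
            f"[{r.icer_per_disability_day.quadrant}]",
            f"ICER per DALY: {r.icer_per_daly:.1f} USD",
            f"WHO-CHOICE classification at {self.wtp.value:.1f} USD/day: {r.classification}",
            f"net monetary benefit: {r.nmb:.2f} USD",
            f"population savings ({self.config['population_under2']:,} children, "
            f"{self.config['cost_per_disability_day_saved']:.2f} USD/day): "
            f"{sav.millions:.2f} million USD",
        ]
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------

    def plot_prevalence(self, ax=None):
        from . import plots

        return plots.prevalence_trends(self.trajectories, ax=ax)

    def plot_tornado(self, oneway=None, ax=None):
        from . import plots

        return plots.tornado(oneway or self.one_way(), ax=ax)

    def plot_ce_plane(self, psa, ax=None):
        from . import plots

        return plots.ce_plane(psa, wtp=self.wtp.value, ax=ax)

    def plot_ceac(self, curve, ax=None):
        from . import plots

        return plots.ceac_curve(curve, ax=ax)
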